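"""Assembled time-course analysis: simulation driver and report builder.

``simulate_time_course`` runs the full pipeline over a synthetic study
emulating the experimental design: two activator arms (the calcium
ionophore A23187 and the phorbol ester PMA), fixed-time cohorts of cells
imaged as whole-field scenes for morphometry, high-resolution 5 um membrane
patches for roughness spectra, 6 x 5 um sections for fragment counting, and
1.5 um scans for NET granules.

``build_report`` turns the per-cell/per-section tables into the study's
readout tables (type distributions, morphometrics, spectral summaries,
fragment and granule statistics, and the height-spectrum regression block)
written as CSV + JSON + a run log.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from scipy import stats as sps

from . import morphometry, particles, spectral, stats
from .heightmap import crop_region
from .synthetic import SceneParams, make_scene, scene_from_preset

__all__ = ["TIME_COURSE", "simulate_time_course", "build_report"]


def _tc(type_fracs, S_I, S_II, band1_period, band2_period, fragments):
    return {"type_fracs": type_fracs, "S_I": S_I, "S_II": S_II,
            "band1_period": band1_period, "band2_period": band2_period,
            "fragments": fragments}


#: study calibration: cohort composition and spectral/particle levels per
#: activator arm and exposure time (min)
TIME_COURSE = {
    "A23187": _tc(
        type_fracs={0: {1: 0.96, 2: 0.04}, 30: {2: 0.92, 3: 0.08},
                    60: {2: 0.52, 3: 0.48}, 120: {3: 0.75, 4: 0.25},
                    240: {3: 0.42, 4: 0.58}},
        S_I={0: 1620.0, 30: 450.0, 60: 120.0, 120: 15.0, 240: 12.0},
        S_II={0: 5.3, 30: 4.53, 60: 2.0, 120: 0.6, 240: 0.5},
        band1_period={0: 1000.0, 30: 1000.0, 60: 800.0, 120: 650.0, 240: 650.0},
        band2_period={0: 200.0, 30: 180.0, 60: 150.0, 120: 130.0, 240: 110.0},
        fragments={30: dict(n=26, mixture=[(1.0, 330.0, 150.0)],
                            height=(16.0, 4.0)),
                   60: dict(n=40, mixture=[(1.0, 400.0, 190.0)],
                            height=(35.0, 8.0)),
                   120: dict(n=58, mixture=[(0.5, 250.0, 60.0),
                                            (0.5, 810.0, 120.0)],
                             height=(61.0, 13.0))},
    ),
    "PMA": _tc(
        type_fracs={0: {1: 0.96, 2: 0.04}, 30: {2: 0.86, 3: 0.14},
                    60: {2: 0.46, 3: 0.54}, 120: {3: 0.84, 4: 0.16},
                    180: {3: 0.22, 4: 0.78}},
        S_I={0: 1800.0, 30: 500.0, 60: 120.0, 120: 10.0, 180: 10.0},
        S_II={0: 3.0, 30: 2.5, 60: 1.8, 120: 1.0, 180: 1.0},
        band1_period={0: 1000.0, 30: 1000.0, 60: 800.0, 120: 650.0, 180: 650.0},
        band2_period={0: 160.0, 30: 150.0, 60: 140.0, 120: 130.0, 180: 125.0},
        fragments={},   # the PMA arm shows no fragment halo in this size range
    ),
}

#: per-type morphometric sampling: (height mean, sd, clip) nm and lobes
_TYPE_HEIGHTS = {
    1: dict(h=(1200.0, 360.0), clip=(950.0, 2200.0), lobes=(0, 0),
            d=(9800.0, 740.0)),
    2: dict(h=(638.0, 114.0), clip=(250.0, 880.0), lobes=(2, 4),
            d=(16500.0, 1200.0)),
    3: dict(h=(300.0, 80.0), clip=(170.0, 880.0), lobes=(0, 1),
            d=(16500.0, 1200.0)),
    4: dict(h=(100.0, 25.0), clip=(40.0, 140.0), lobes=(0, 0),
            d=(16500.0, 1500.0)),
}


def _trunc_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(sps.truncnorm.mean(a, b, loc=mu, scale=sd))


def _sample_cell_params(cell_type: int, cal: dict, t: float,
                        rng: np.random.Generator, grid_points: int) -> SceneParams:
    spec = _TYPE_HEIGHTS[cell_type]
    lo, hi = spec["clip"]
    while True:
        h = rng.normal(*spec["h"])
        if lo <= h <= hi:
            break
    d = float(np.clip(rng.normal(*spec["d"]), 6000.0, 26000.0))
    lobes = int(rng.integers(spec["lobes"][0], spec["lobes"][1] + 1))
    if cell_type == 4:
        # disrupted cells always shed a dense, tall halo of fused material
        frag_cfg = dict(n=58, mixture=[(0.5, 250.0, 60.0), (0.5, 810.0, 120.0)],
                        height=(61.0, 13.0))
    else:
        frag_cfg = cal["fragments"].get(t)
    kwargs = dict(
        grid_points=grid_points, field_size_nm=30000.0,
        cell_height_nm=round(h, 3), cell_diameter_nm=round(d, 3),
        n_lobes=lobes, lobe_height_nm=200.0,
        band1_amplitude_nm=0.0, band2_amplitude_nm=0.0,
        seed=int(rng.integers(2 ** 31)),
    )
    if frag_cfg and cell_type in (2, 3, 4):
        kwargs.update(
            n_fragments=frag_cfg["n"],
            fragment_size_mixture=frag_cfg["mixture"],
            fragment_height_mean_nm=frag_cfg["height"][0],
            fragment_height_sd_nm=frag_cfg["height"][1],
            fragment_min_height_nm=20.0 if cell_type == 4 else 5.0,
            fragment_separation_factor=0.5
            if len(frag_cfg["mixture"]) > 1 else 1.0,
        )
    return SceneParams(**kwargs)


def simulate_time_course(seed: int = 0, n_cells: int = 10,
                         n_sections: int = 3, n_mesh_scans: int = 2,
                         scene_grid: int = 512, patch_grid: int = 256):
    """Run the pipeline over a full synthetic study.

    Returns a dict of tidy DataFrames: ``cells`` (per-cell morphometrics and
    type), ``spectra`` (per-cell patch spectral summaries for both orders),
    ``fragments`` (per-section particle detections), ``fragment_sizes``
    (pooled per-time size samples), ``granules`` (per-scan granule
    statistics).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2024)))
    cell_rows, spec_rows, frag_rows, size_rows, gran_rows = [], [], [], [], []

    for activator, cal in TIME_COURSE.items():
        for t, fracs in cal["type_fracs"].items():
            types = list(fracs)
            probs = np.array([fracs[k] for k in types])
            probs = probs / probs.sum()
            # expected height among spectra-contributing (intact) types,
            # accounting for the clipping of the per-type height draws
            intact = [(k, p) for k, p in zip(types, probs) if k != 4]
            w = sum(p for _, p in intact) or 1.0
            mean_h = sum(
                _trunc_mean(*_TYPE_HEIGHTS[k]["h"], *_TYPE_HEIGHTS[k]["clip"]) * p
                for k, p in intact) / w
            for i in range(n_cells):
                ct = int(rng.choice(types, p=probs))
                params = _sample_cell_params(ct, cal, t, rng, scene_grid)
                hmap, truth = make_scene(params)
                feats = morphometry.measure_cell(hmap)
                cell_rows.append(dict(
                    activator=activator, time_min=t, cell_id=i,
                    h_max_nm=feats.h_max_nm, diameter_um=feats.diameter_um,
                    area_um2=feats.area_um2, n_lobes=feats.n_lobes,
                    solidity=feats.solidity, type=feats.type_label,
                    true_type=truth.true_type,
                    true_h_nm=truth.true_cell_height_nm,
                    true_diameter_um=truth.true_diameter_nm / 1000.0))
                # membrane patch spectra for intact membranes (types 1-3);
                # spectral registration stops once the membrane is disrupted
                if ct == 4:
                    continue
                jitter = float(np.exp(rng.normal(0.0, 0.1)))
                s1 = cal["S_I"][t] * (params.cell_height_nm / mean_h) * jitter
                s2 = cal["S_II"][t] * (params.cell_height_nm / mean_h) * jitter
                patch_params = SceneParams(
                    grid_points=patch_grid, field_size_nm=5000.0,
                    cell_height_nm=0.0,
                    band1_period_nm=cal["band1_period"][t],
                    band1_amplitude_nm=float(np.sqrt(s1)),
                    band2_period_nm=cal["band2_period"][t],
                    band2_amplitude_nm=float(np.sqrt(s2)),
                    substrate_noise_sd_nm=0.5,
                    seed=int(rng.integers(2 ** 31)))
                patch, _ = make_scene(patch_params)
                _, summaries = spectral.cell_patch_spectrum(patch, None, 5000.0)
                for label, summ in summaries.items():
                    if summ is None:
                        continue
                    spec_rows.append(dict(
                        activator=activator, time_min=t, cell_id=i,
                        order=label, S_max_nm2=summ.S_max_nm2,
                        nu_max_per_nm=summ.nu_max_per_nm,
                        L_max_nm=summ.L_max_nm,
                        h_max_nm=feats.h_max_nm))

            # fragment halo sections, 6 x 5 um each
            frag_cfg = cal["fragments"].get(t)
            if frag_cfg:
                pooled = []
                for s in range(n_sections):
                    sp = SceneParams(
                        grid_points=300, field_size_nm=6000.0,
                        cell_height_nm=0.0, band1_amplitude_nm=0.0,
                        band2_amplitude_nm=0.0,
                        n_fragments=int(np.clip(
                            rng.normal(frag_cfg["n"], frag_cfg["n"] / 6),
                            4, frag_cfg["n"] + 6)),
                        # dense late-time halos fuse; relax the separation
                        fragment_separation_factor=0.5
                        if len(frag_cfg["mixture"]) > 1 else 1.0,
                        fragment_size_mixture=frag_cfg["mixture"],
                        fragment_height_mean_nm=frag_cfg["height"][0],
                        fragment_height_sd_nm=frag_cfg["height"][1],
                        fragment_min_height_nm=14.0,
                        seed=int(rng.integers(2 ** 31)))
                    sec_map, sec_truth = make_scene(sp)
                    section = crop_region(
                        sec_map, center_nm=(3000.0, 2500.0),
                        width_nm=6000.0, height_nm=5000.0)
                    bg = morphometry.estimate_background(section)
                    pset = particles.detect_particles(
                        section, None, bg, "fragment",
                        region=f"{activator}-{t}-{s}")
                    if len(pset) == 0:
                        continue
                    st = particles.particle_stats(pset)
                    frag_rows.append(dict(activator=activator, time_min=t,
                                          section=s, **st))
                    pooled.extend(pset.sizes().tolist())
                for sz in pooled:
                    size_rows.append(dict(activator=activator, time_min=t,
                                          size_nm=sz))

        # NET granule scans at the final time point
        t_last = max(cal["type_fracs"])
        gsize = (50.0, 20.0) if activator == "A23187" else (30.0, 10.0)
        n_chains = 4 if activator == "A23187" else 8
        for s in range(n_mesh_scans):
            mp = scene_from_preset(
                "net_mesh", seed=int(rng.integers(2 ** 31)),
                granule_size_mean_nm=gsize[0], granule_size_sd_nm=gsize[1],
                n_granule_chains=n_chains)
            scan, truth = make_scene(mp)
            bg = morphometry.estimate_background(scan)
            pset = particles.detect_particles(scan, None, bg, "granule",
                                              region=f"{activator}-mesh-{s}")
            if len(pset) == 0:
                continue
            st = particles.particle_stats(pset)
            gran_rows.append(dict(activator=activator, time_min=t_last,
                                  scan=s, true_n=len(truth.granules), **st))

    return {
        "cells": pd.DataFrame(cell_rows),
        "spectra": pd.DataFrame(spec_rows),
        "fragments": pd.DataFrame(frag_rows),
        "fragment_sizes": pd.DataFrame(size_rows),
        "granules": pd.DataFrame(gran_rows),
    }


def _check_labels(cells: pd.DataFrame, other: pd.DataFrame, what: str) -> None:
    have = set(map(tuple, cells[["activator", "time_min"]].drop_duplicates()
                   .itertuples(index=False)))
    want = set(map(tuple, other[["activator", "time_min"]].drop_duplicates()
                   .itertuples(index=False)))
    orphans = want - have
    if orphans:
        raise ValueError(f"{what}: activator/time labels {sorted(orphans)} "
                         f"absent from the cells table")


def build_report(cells, spectra, fragments=None, fragment_sizes=None,
                 granules=None, config: dict | None = None,
                 out_dir=None) -> dict:
    """Assemble the study readout tables.

    Parameters may be DataFrames or CSV paths. Writes ``types.csv``,
    ``morphometrics.csv``, ``spectra_summary.csv``, ``fragments.csv``,
    ``granules.csv``, ``regression.json`` and ``run.log`` into ``out_dir``
    when given; always returns the bundle as a dict. Output is byte-stable
    for identical inputs (no timestamps).
    """
    def _load(x):
        if x is None:
            return None
        return pd.read_csv(x) if isinstance(x, (str, Path)) else x

    cells, spectra = _load(cells), _load(spectra)
    fragments, fragment_sizes = _load(fragments), _load(fragment_sizes)
    granules = _load(granules)
    log: list[str] = ["time-course report"]

    _check_labels(cells, spectra, "spectra")

    # 1. type distribution per activator/time
    types_tbl = (cells.groupby(["activator", "time_min", "type"])
                 .size().rename("count").reset_index())
    types_tbl["pct"] = types_tbl.groupby(["activator", "time_min"])["count"] \
        .transform(lambda c: 100.0 * c / c.sum())

    # 2. height/diameter summary stats (boxplot-style)
    def _box(g):
        return pd.Series({
            "n": len(g),
            "h_mean_nm": g.h_max_nm.mean(), "h_sd_nm": g.h_max_nm.std(ddof=1),
            "h_median_nm": g.h_max_nm.median(),
            "d_mean_um": g.diameter_um.mean(),
            "d_sd_um": g.diameter_um.std(ddof=1),
            "d_median_um": g.diameter_um.median()})
    morph_tbl = (cells.groupby(["activator", "time_min"])
                 .apply(_box, include_groups=False).reset_index())

    # 3. spectral summaries per order/time
    spec_tbl = (spectra.groupby(["activator", "time_min", "order"])
                .agg(n=("S_max_nm2", "size"),
                     S_max_mean_nm2=("S_max_nm2", "mean"),
                     S_max_sd_nm2=("S_max_nm2", "std"),
                     L_max_mean_nm=("L_max_nm", "mean"))
                .reset_index())

    # 4. fragment statistics and modality per time
    frag_tbl = None
    if fragments is not None and len(fragments):
        _check_labels(cells, fragments, "fragments")
        frag_tbl = (fragments.groupby(["activator", "time_min"])
                    .agg(n_sections=("count", "size"),
                         count_mean=("count", "mean"),
                         count_sd=("count", "std"),
                         size_mean_nm=("size_mean_nm", "mean"),
                         height_mean_nm=("height_mean_nm", "mean"))
                    .reset_index())
        modal = []
        if fragment_sizes is not None and len(fragment_sizes):
            for (act, t), g in fragment_sizes.groupby(["activator", "time_min"]):
                if len(g) >= 8:
                    m = particles.modality_test(g.size_nm.to_numpy())
                    modal.append(dict(activator=act, time_min=t,
                                      n_modes=m.n_modes,
                                      modes_nm=[round(x, 1)
                                                for x in m.mode_positions_nm]))
        frag_modal = pd.DataFrame(modal) if modal else None
    else:
        frag_modal = None
        log.append("gap: no fragment input; fragment tables omitted")

    # 5. granule statistics per arm
    gran_tbl = None
    if granules is not None and len(granules):
        gran_tbl = (granules.groupby("activator")
                    .agg(n_scans=("count", "size"),
                         total_count=("count", "sum"),
                         size_mean_nm=("size_mean_nm", "mean"),
                         height_mean_nm=("height_mean_nm", "mean"))
                    .reset_index())
    else:
        log.append("gap: no granule input; granule table omitted")

    # 6. height-spectrum correlation and regression per arm/order
    regression: dict = {}
    for (act, order), g in spectra.groupby(["activator", "order"]):
        if len(g) < 3 or g.h_max_nm.nunique() < 2:
            continue
        res = stats.correlate_height_spectrum(
            g[["h_max_nm", "S_max_nm2"]].to_numpy(), order=order, activator=act)
        regression[f"{act}/{order}"] = dict(
            r=round(res.r, 3), b_nm=round(res.b_nm, 4),
            intercept_nm2=round(res.intercept_nm2, 2), n=res.n)
    for order in ("order_I", "order_II"):
        ka, kp = f"A23187/{order}", f"PMA/{order}"
        if ka in regression and kp in regression \
                and regression[kp]["b_nm"] != 0:
            regression[f"b_ratio_A23187_over_PMA/{order}"] = \
                stats.coefficient_ratio(regression[ka]["b_nm"],
                                        regression[kp]["b_nm"])
    # spectral fold-changes control -> last registered time per arm/order
    for (act, order), g in spec_tbl.groupby(["activator", "order"]):
        g = g.sort_values("time_min")
        s0 = g.S_max_mean_nm2.iloc[0]
        s1 = g.S_max_mean_nm2.iloc[-1]
        if s0 > 0 and s1 > 0:
            regression[f"fold_change/{act}/{order}"] = stats.fold_change(s0, s1)

    bundle = {"types": types_tbl, "morphometrics": morph_tbl,
              "spectra_summary": spec_tbl, "fragments": frag_tbl,
              "fragment_modality": frag_modal, "granules": gran_tbl,
              "regression": regression, "log": log}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("types", "morphometrics", "spectra_summary",
                     "fragments", "granules"):
            tbl = bundle[name]
            if tbl is not None:
                tbl.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
        if frag_modal is not None:
            frag_modal.to_csv(out / "fragment_modality.csv", index=False)
        (out / "regression.json").write_text(
            json.dumps(regression, sort_keys=True, indent=1))
        (out / "run.log").write_text("\n".join(
            log + [f"config: {json.dumps(config or {}, sort_keys=True)}"]) + "\n")
    return bundle
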