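"""Seeded synthetic AFM scenes with known ground truth.

Real AFM topographies of activating neutrophils are emulated so that every
downstream stage (spectra, morphometry, particle statistics) can be tested
against a known answer. A scene is the pixel-wise sum of independent
components: substrate noise, a super-Gaussian cell cap with optional nuclear
lobes, band-limited spongiform roughness confined to the cell footprint, a
halo of paraboloid sub-micron fragments, and optional NET granule chains.

Each component draws from its own named RNG stream derived from the single
scene seed, so regenerating any single component is reproducible. All
lengths are nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from io import StringIO

import numpy as np
import yaml

from .heightmap import HeightMap

__all__ = [
    "SceneParams", "GroundTruth", "PlacementError",
    "make_roughness_field", "make_cell_body", "scatter_fragments",
    "make_net_mesh", "make_scene", "PRESETS", "scene_from_preset",
]

#: height (nm) of the basal contour at which the cell diameter is defined
CONTACT_HEIGHT_NM = 20.0
#: relative half-width of the roughness annulus around its centre frequency;
#: narrow enough that the band stays inside its order window (the first-order
#: window edge sits at exactly 1.2x the 1000 nm period) while still wide
#: enough to look spongiform
ANNULUS_HALF_WIDTH = 0.15

_STREAMS = ("noise", "cell", "band1", "band2", "fragments", "mesh")


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all requested particles."""

    def __init__(self, requested: int, placed: int):
        self.requested = requested
        self.placed = placed
        super().__init__(
            f"placed only {placed} of {requested} fragments without overlap")


@dataclass
class SceneParams:
    """Full parameterisation of one synthetic scene.

    Defaults describe an unactivated (control) neutrophil: a 1.2 um tall,
    9.8 um wide spherical cap carrying first-order roughness of period
    1000 nm and amplitude 40 nm (spectral intensity 1600 nm^2) and
    second-order roughness of period 150 nm with intensity ~5 nm^2, on a
    1 nm RMS substrate.
    """

    grid_points: int = 512
    field_size_nm: float = 5000.0
    cell_height_nm: float = 1200.0
    cell_diameter_nm: float = 9800.0
    n_lobes: int = 0
    lobe_height_nm: float = 200.0
    cap_exponent: int = 3
    band1_period_nm: float = 1000.0
    band1_amplitude_nm: float = 40.0
    band2_period_nm: float = 150.0
    band2_amplitude_nm: float = 2.3
    n_fragments: int = 0
    fragment_size_mixture: list = field(
        default_factory=lambda: [(1.0, 330.0, 150.0)])
    fragment_min_size_nm: float = 150.0
    fragment_height_mean_nm: float = 16.0
    fragment_height_sd_nm: float = 4.0
    fragment_min_height_nm: float = 5.0
    #: 1.0 keeps fragments strictly disjoint; lower values let dense late-
    #: time fragments partially overlap and fuse into larger structures
    fragment_separation_factor: float = 1.0
    granule_size_mean_nm: float = 50.0
    granule_size_sd_nm: float = 20.0
    n_granule_chains: int = 0
    granules_per_chain: int = 20
    substrate_noise_sd_nm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_points < 64:
            raise ValueError("grid_points must be >= 64")
        for name in ("field_size_nm",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cell_height_nm", "cell_diameter_nm", "lobe_height_nm",
                     "substrate_noise_sd_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.n_lobes <= 4:
            raise ValueError("n_lobes must be in 0..4")
        if not 0.3 <= self.fragment_separation_factor <= 1.0:
            raise ValueError("fragment_separation_factor must be in [0.3, 1]")
        if self.fragment_size_mixture:
            w = sum(c[0] for c in self.fragment_size_mixture)
            if abs(w - 1.0) > 1e-9:
                raise ValueError("fragment mixture weights must sum to 1")
        if self.band1_amplitude_nm > 0 and not 600 <= self.band1_period_nm <= 1200:
            raise ValueError("band1 period must lie in the 600-1200 nm window")
        if self.band2_amplitude_nm > 0 and not 50 <= self.band2_period_nm <= 300:
            raise ValueError("band2 period must lie in the 50-300 nm window")

    @property
    def pixel_size_nm(self) -> float:
        return self.field_size_nm / self.grid_points

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent, named RNG stream per scene component."""
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss)
                for name, ss in zip(_STREAMS, children)}

    def to_yaml(self) -> str:
        d = asdict(self)
        d["fragment_size_mixture"] = [list(c) for c in d["fragment_size_mixture"]]
        return yaml.safe_dump({"scene": d}, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SceneParams":
        d = yaml.safe_load(StringIO(text))["scene"]
        d["fragment_size_mixture"] = [tuple(c) for c in d["fragment_size_mixture"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that the estimators must recover."""

    true_cell_height_nm: float
    true_diameter_nm: float
    true_type: int
    true_n_lobes: int
    band_periods_nm: tuple[float, float]
    band_amplitudes_nm: tuple[float, float]
    fragments: list          # dicts: center_nm (x, y), size_nm, height_nm
    granules: list           # dicts: center_nm (x, y), size_nm
    seed: int

    def __post_init__(self):
        for name in ("true_cell_height_nm", "true_diameter_nm"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["band_periods_nm"] = tuple(d["band_periods_nm"])
        d["band_amplitudes_nm"] = tuple(d["band_amplitudes_nm"])
        return cls(**d)


def make_roughness_field(grid_points: int, field_size_nm: float,
                         period_nm: float, amplitude_nm: float,
                         seed) -> HeightMap:
    """Isotropic band-limited roughness of one spatial period.

    Seeded white noise is band-limited in the frequency domain to a narrow
    one-sided annulus [1/period, 1.3/period] and rescaled so that the
    dominant peak of the row-averaged 1-D profile spectrum equals
    amplitude^2; the peak sits at 1/period because the 1-D marginal of an
    isotropic ring is maximal at the ring's lowest frequency. The field is
    zero-mean and deterministic given the seed.
    """
    px = field_size_nm / grid_points
    if not (2 * px < period_nm < field_size_nm / 2):
        raise ValueError(
            f"period {period_nm} nm outside representable range "
            f"({2 * px:.3g} .. {field_size_nm / 2:.3g} nm)")
    if amplitude_nm < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude_nm == 0:
        return HeightMap(np.zeros((grid_points, grid_points)), px)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    white = rng.standard_normal((grid_points, grid_points))
    f = np.fft.fftfreq(grid_points, d=px)
    rad = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    nu0 = 1.0 / period_nm
    # one-sided annulus [nu0, (1 + 2 hw) nu0]: the 1-D marginal of an
    # isotropic ring peaks at the ring's lowest frequency, so anchoring the
    # ring at 1/period makes the dominant recovered period equal period_nm
    mask = (rad >= nu0 * (1.0 - 1e-9)) & \
           (rad <= nu0 * (1.0 + 2.0 * ANNULUS_HALF_WIDTH))
    mask[0, 0] = False
    fieldc = np.real(np.fft.ifft2(np.fft.fft2(white) * mask))
    fieldc -= fieldc.mean()
    # rescale so the dominant peak of the row-averaged profile spectrum
    # (the maximum over the annulus band) equals amplitude^2
    from .spectral import _spectrum_of_rows
    rows = fieldc - fieldc.mean(axis=1, keepdims=True)
    spec = _spectrum_of_rows(rows, px)
    band = (spec.frequencies >= nu0 * (1.0 - ANNULUS_HALF_WIDTH)) & \
           (spec.frequencies <= nu0 * (1.0 + 2.0 * ANNULUS_HALF_WIDTH))
    if not band.any():
        band = np.abs(spec.frequencies - nu0) == np.min(
            np.abs(spec.frequencies - nu0))
    peak = float(spec.intensities[band].max())
    fieldc *= amplitude_nm / np.sqrt(peak)
    return HeightMap(fieldc, px)


def _cap_profile(r: np.ndarray, height: float, diameter: float,
                 exponent: int) -> np.ndarray:
    """Super-Gaussian cap; the basal contour at CONTACT_HEIGHT_NM has the
    stated diameter."""
    beta = np.log(height / CONTACT_HEIGHT_NM)
    return height * np.exp(-beta * (2.0 * r / diameter) ** (2 * exponent))


def make_cell_body(params: SceneParams) -> HeightMap:
    """Smooth cell cap with optional nuclear-lobe bumps.

    The cap is a super-Gaussian dome of maximum height ``cell_height_nm``
    whose contour at the 20 nm contact height has diameter
    ``cell_diameter_nm``; the exponent controls how flat-topped (spread) the
    cell is. ``n_lobes`` Gaussian bumps emulate the topographic signature of
    nuclear segments; the whole field is rescaled so its maximum equals the
    requested cell height.
    """
    n, px = params.grid_points, params.pixel_size_nm
    H, D = params.cell_height_nm, params.cell_diameter_nm
    if H == 0:
        return HeightMap(np.zeros((n, n)), px)
    if H <= CONTACT_HEIGHT_NM:
        raise ValueError(
            f"cell height must exceed the {CONTACT_HEIGHT_NM} nm contact height")
    if D * 1.1 > params.field_size_nm:
        raise ValueError("cell must fit in the field with a 10% margin")
    c = (n - 1) / 2.0 * px
    y, x = np.mgrid[0:n, 0:n].astype(float) * px
    r = np.hypot(x - c, y - c)
    body = _cap_profile(r, H, D, params.cap_exponent)
    if params.n_lobes > 0:
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, 17)))
        ring = 0.35 * D / 2.0
        sigma = max(700.0, 4 * px)
        if params.n_lobes == 1:
            ring = 0.0
        angles = (2 * np.pi * np.arange(params.n_lobes) / max(params.n_lobes, 1)
                  + rng.uniform(0, 2 * np.pi))
        for a in angles:
            lx, ly = c + ring * np.cos(a), c + ring * np.sin(a)
            body += params.lobe_height_nm * np.exp(
                -((x - lx) ** 2 + (y - ly) ** 2) / (2 * sigma ** 2))
    body *= H / body.max()
    return HeightMap(body, px)


def _draw_mixture_sizes(rng: np.random.Generator, n: int, mixture,
                        min_size: float) -> np.ndarray:
    weights = np.array([c[0] for c in mixture])
    sizes = np.empty(n)
    for i in range(n):
        while True:
            k = rng.choice(len(mixture), p=weights)
            s = rng.normal(mixture[k][1], mixture[k][2])
            if s >= min_size:
                sizes[i] = s
                break
    return sizes


def scatter_fragments(params: SceneParams, exclusion_footprint: np.ndarray | None,
                      seed) -> tuple[HeightMap, list]:
    """Non-overlapping paraboloid fragment bumps outside the cell footprint.

    Sizes (equivalent diameters) are drawn from the configured Gaussian
    mixture, truncated below at ``fragment_min_size_nm``. Placement is
    rejection sampling with at most 10*n attempts; failure to place all
    fragments raises :class:`PlacementError` reporting the placed count. The
    returned list matches the rendered bumps one-to-one.
    """
    n, px = params.grid_points, params.pixel_size_nm
    field = np.zeros((n, n))
    if params.n_fragments == 0:
        return HeightMap(field, px), []
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sizes = _draw_mixture_sizes(rng, params.n_fragments,
                                params.fragment_size_mixture,
                                params.fragment_min_size_nm)
    heights = np.empty(params.n_fragments)
    for i in range(params.n_fragments):
        while True:
            h = rng.normal(params.fragment_height_mean_nm,
                           params.fragment_height_sd_nm)
            if h >= params.fragment_min_height_nm:
                heights[i] = h
                break
    placed: list[dict] = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    max_attempts = 10 * params.n_fragments
    extent = params.field_size_nm
    i = 0
    while i < params.n_fragments:
        if attempts >= max_attempts:
            raise PlacementError(params.n_fragments, len(placed))
        attempts += 1
        R = sizes[i] / 2.0
        cx = rng.uniform(R + px, extent - R - px)
        cy = rng.uniform(R + px, extent - R - px)
        if centers:
            d = np.hypot(np.array([c[0] for c in centers]) - cx,
                         np.array([c[1] for c in centers]) - cy)
            sep = params.fragment_separation_factor
            if np.any(d < sep * (R + np.array(radii)) + px):
                continue
        if exclusion_footprint is not None:
            ci, cj = int(cy / px), int(cx / px)
            ri = int(np.ceil(R / px)) + 1
            lo_i, hi_i = max(ci - ri, 0), min(ci + ri + 1, n)
            lo_j, hi_j = max(cj - ri, 0), min(cj + ri + 1, n)
            if exclusion_footprint[lo_i:hi_i, lo_j:hi_j].any():
                continue
        _render_paraboloid(field, px, cx, cy, R, heights[i])
        centers.append((cx, cy))
        radii.append(R)
        placed.append({"center_nm": [cx, cy], "size_nm": float(sizes[i]),
                       "height_nm": float(heights[i])})
        i += 1
    return HeightMap(field, px), placed


def _render_paraboloid(field: np.ndarray, px: float, cx: float, cy: float,
                       R: float, height: float) -> None:
    n = field.shape[0]
    ri = int(np.ceil(R / px)) + 1
    ci, cj = int(cy / px), int(cx / px)
    lo_i, hi_i = max(ci - ri, 0), min(ci + ri + 1, n)
    lo_j, hi_j = max(cj - ri, 0), min(cj + ri + 1, n)
    yy = (np.arange(lo_i, hi_i) * px - cy)[:, None]
    xx = (np.arange(lo_j, hi_j) * px - cx)[None, :]
    r2 = (xx ** 2 + yy ** 2) / R ** 2
    bump = np.maximum(height * (1.0 - r2), 0.0)
    field[lo_i:hi_i, lo_j:hi_j] = np.maximum(field[lo_i:hi_i, lo_j:hi_j], bump)


def _render_gaussian(field: np.ndarray, px: float, cx: float, cy: float,
                     sigma: float, height: float) -> None:
    n = field.shape[0]
    ri = int(np.ceil(4 * sigma / px)) + 1
    ci, cj = int(cy / px), int(cx / px)
    lo_i, hi_i = max(ci - ri, 0), min(ci + ri + 1, n)
    lo_j, hi_j = max(cj - ri, 0), min(cj + ri + 1, n)
    yy = (np.arange(lo_i, hi_i) * px - cy)[:, None]
    xx = (np.arange(lo_j, hi_j) * px - cx)[None, :]
    bump = height * np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
    field[lo_i:hi_i, lo_j:hi_j] = np.maximum(field[lo_i:hi_i, lo_j:hi_j], bump)


def make_net_mesh(params: SceneParams, seed) -> tuple[HeightMap, list]:
    """NET meshwork: chains of 30-50 nm granules along random-walk paths.

    Granules are compact paraboloid beads laid bead-to-bead along each chain
    (step 1.25 * size, leaving a small gap so every granule remains an
    individually resolvable component); different chains are kept disjoint
    by bounded-retry rejection of colliding steps. Requires a grid fine
    enough to resolve the granules (size > 2 px).
    """
    n, px = params.grid_points, params.pixel_size_nm
    field = np.zeros((n, n))
    granules: list[dict] = []
    if params.n_granule_chains == 0:
        return HeightMap(field, px), granules
    if params.granule_size_mean_nm <= 2 * px:
        raise ValueError(
            f"granule size {params.granule_size_mean_nm} nm not resolvable at "
            f"{px:.3g} nm/pixel (need > 2 px)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    extent = params.field_size_nm
    margin = 3 * params.granule_size_mean_nm
    others: list[tuple[float, float, float]] = []  # granules of earlier chains
    for _ in range(params.n_granule_chains):
        sizes = []
        for _ in range(params.granules_per_chain):
            while True:
                s = rng.normal(params.granule_size_mean_nm,
                               params.granule_size_sd_nm)
                if s > 2.5 * px:
                    sizes.append(s)
                    break
        cx = rng.uniform(margin, extent - margin)
        cy = rng.uniform(margin, extent - margin)
        direction = rng.uniform(0, 2 * np.pi)
        chain: list[tuple[float, float, float]] = []
        for j, size in enumerate(sizes):
            ok = False
            for _ in range(25):
                cx = np.clip(cx, margin / 2, extent - margin / 2)
                cy = np.clip(cy, margin / 2, extent - margin / 2)
                neighbours = others + chain[:-1]  # all but the previous bead
                collides = any(np.hypot(gx - cx, gy - cy) < 0.65 * (gs + size)
                               for gx, gy, gs in neighbours)
                if not collides:
                    ok = True
                    break
                direction += rng.normal(0, 1.5)
                cx += 0.65 * (sizes[j - 1] + size) * np.cos(direction)
                cy += 0.65 * (sizes[j - 1] + size) * np.sin(direction)
            if not ok:
                break  # chain terminates early; truth stays one-to-one
            _render_paraboloid(field, px, cx, cy, size / 2.0, size / 2.0)
            granules.append({"center_nm": [cx, cy], "size_nm": float(size)})
            chain.append((cx, cy, size))
            if j + 1 < len(sizes):
                # bead-to-bead step with a 15% gap so neighbours stay disjoint
                direction += rng.normal(0, 0.6)
                step = 0.65 * (size + sizes[j + 1])
                cx += step * np.cos(direction)
                cy += step * np.sin(direction)
        others.extend(chain)
    return HeightMap(field, px), granules


def _truth_type(params: SceneParams) -> int:
    """Rule table shared with the morphometric classifier, applied to the
    generating parameters."""
    if params.n_granule_chains > 0:
        return 4
    if params.cell_height_nm < 150 and params.n_fragments >= 10:
        return 4
    if params.cell_height_nm >= 900 and params.cell_diameter_nm <= 12000:
        return 1
    if params.cell_height_nm < 900 and params.n_lobes >= 2:
        return 2
    if params.cell_height_nm < 900 and params.n_lobes <= 1:
        return 3
    return 5  # "other"


def make_scene(params: SceneParams, return_components: bool = False):
    """Compose a full scene: noise + cell + masked roughness + fragments
    (+ NET mesh), with fully populated ground truth.

    The scene height at any pixel is the sum of the component fields at that
    pixel. The ground-truth type label is assigned from the parameters by
    the same rule table the morphometric classifier targets.
    """
    n, px = params.grid_points, params.pixel_size_nm
    streams = params.streams()
    components: dict[str, np.ndarray] = {}

    noise = streams["noise"].normal(0.0, params.substrate_noise_sd_nm, (n, n)) \
        if params.substrate_noise_sd_nm > 0 else np.zeros((n, n))
    components["noise"] = noise

    body = make_cell_body(params).heights
    footprint = body >= CONTACT_HEIGHT_NM if params.cell_height_nm > 0 \
        else np.zeros((n, n), dtype=bool)
    # the membrane skirt extends slightly beyond the basal contour; using it
    # as the roughness support keeps rim fluctuations symmetric about the
    # segmentation threshold
    skirt = body >= 2.0 if params.cell_height_nm > 0 \
        else np.zeros((n, n), dtype=bool)

    # roughness rides on the membrane: confined to the cell footprint when a
    # cell is present, covering the whole field for pure membrane patches
    rough = np.zeros((n, n))
    for band, stream in (("band1", "band1"), ("band2", "band2")):
        period = getattr(params, f"{band}_period_nm")
        amp = getattr(params, f"{band}_amplitude_nm")
        if amp > 0 and 2 * px < period < params.field_size_nm / 2:
            rf = make_roughness_field(n, params.field_size_nm, period, amp,
                                      streams[stream])
            rough += rf.heights
    # the textured cell surface is renormalised so its maximum equals the
    # nominal cell height; the effective roughness amplitudes (recorded in
    # the ground truth) shrink by the same factor
    amp_scale = 1.0
    if params.cell_height_nm > 0:
        rough *= skirt
        surface = body + rough
        amp_scale = params.cell_height_nm / surface.max()
        surface *= amp_scale
        components["cell_surface"] = surface
    else:
        components["cell_surface"] = body + rough

    frag_field, fragments = scatter_fragments(params, skirt if skirt.any() else None,
                                              streams["fragments"])
    components["fragments"] = frag_field.heights

    mesh_field, granules = make_net_mesh(params, streams["mesh"])
    components["mesh"] = mesh_field.heights

    total = sum(components.values())
    hmap = HeightMap(total, px, metadata={"seed": params.seed})
    truth = GroundTruth(
        true_cell_height_nm=params.cell_height_nm,
        true_diameter_nm=params.cell_diameter_nm,
        true_type=_truth_type(params),
        true_n_lobes=params.n_lobes,
        band_periods_nm=(params.band1_period_nm, params.band2_period_nm),
        band_amplitudes_nm=(params.band1_amplitude_nm * amp_scale,
                            params.band2_amplitude_nm * amp_scale),
        fragments=fragments,
        granules=granules,
        seed=params.seed,
    )
    if return_components:
        return hmap, truth, components
    return hmap, truth


#: study presets: the four morphological stages of neutrophil activation
PRESETS: dict[str, dict] = {
    # type 1 — unactivated spherical cell
    "control": dict(
        grid_points=512, field_size_nm=30000.0,
        cell_height_nm=1200.0, cell_diameter_nm=9800.0, n_lobes=0,
        band1_period_nm=1000.0, band1_amplitude_nm=40.0,
        band2_period_nm=150.0, band2_amplitude_nm=2.3,
        n_fragments=0,
    ),
    # type 2 — spread cell, segmented nucleus (~30-60 min)
    "spread_segmented": dict(
        grid_points=512, field_size_nm=30000.0,
        cell_height_nm=638.0, cell_diameter_nm=16500.0,
        n_lobes=3, lobe_height_nm=200.0,
        band1_period_nm=1000.0, band1_amplitude_nm=21.2,
        band2_period_nm=180.0, band2_amplitude_nm=2.1,
        n_fragments=26, fragment_height_mean_nm=16.0,
        fragment_size_mixture=[(1.0, 330.0, 150.0)],
    ),
    # type 3 — spread cell, nuclear segmentation lost (~60-120 min)
    "spread_unsegmented": dict(
        grid_points=512, field_size_nm=30000.0,
        cell_height_nm=300.0, cell_diameter_nm=16500.0, n_lobes=1,
        band1_period_nm=800.0, band1_amplitude_nm=3.9,
        band2_period_nm=180.0, band2_amplitude_nm=1.0,
        n_fragments=40, fragment_height_mean_nm=40.0,
        fragment_height_sd_nm=8.0,
        fragment_size_mixture=[(1.0, 400.0, 190.0)],
    ),
    # type 4 — disrupted cell with NET release (>=120 min)
    "netotic": dict(
        grid_points=512, field_size_nm=30000.0,
        cell_height_nm=100.0, cell_diameter_nm=16500.0, n_lobes=0,
        band1_amplitude_nm=0.0, band2_amplitude_nm=0.0,
        n_fragments=58, fragment_height_mean_nm=61.0,
        fragment_height_sd_nm=13.0, fragment_min_height_nm=20.0,
        fragment_size_mixture=[(0.5, 250.0, 60.0), (0.5, 810.0, 120.0)],
    ),
    # high-resolution NET meshwork scan (1.5 x 1.5 um at <3 nm/pixel)
    "net_mesh": dict(
        grid_points=512, field_size_nm=1500.0,
        cell_height_nm=0.0, band1_amplitude_nm=0.0, band2_amplitude_nm=0.0,
        n_granule_chains=6, granules_per_chain=20,
        granule_size_mean_nm=50.0, granule_size_sd_nm=20.0,
        substrate_noise_sd_nm=0.3,
    ),
    # high-resolution 5 x 5 um membrane patch (control roughness, no cell edge)
    "membrane_patch": dict(
        grid_points=512, field_size_nm=5000.0,
        cell_height_nm=0.0,
        band1_period_nm=1000.0, band1_amplitude_nm=40.0,
        band2_period_nm=150.0, band2_amplitude_nm=2.3,
    ),
}


def scene_from_preset(name: str, seed: int = 0, **overrides) -> SceneParams:
    """SceneParams for a named study preset, optionally overridden."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    kwargs = {**PRESETS[name], **overrides, "seed": seed}
    return SceneParams(**kwargs)
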