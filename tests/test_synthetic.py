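import numpy as np
import pytest
from scipy import ndimage
from scipy import stats as sps

from afmtopo import (GroundTruth, PlacementError, SceneParams,
                     make_cell_body, make_net_mesh, make_roughness_field,
                     make_scene, scatter_fragments, scene_from_preset)
from afmtopo.synthetic import CONTACT_HEIGHT_NM


class TestRoughnessField:
    def test_zero_amplitude_gives_flat_field(self):
        hm = make_roughness_field(128, 5000.0, 1000.0, 0.0, seed=0)
        assert np.all(hm.heights == 0.0)

    def test_profile_peak_at_target_frequency(self):
        """Direct DFT oracle on a generated profile row."""
        hm = make_roughness_field(512, 5000.0, 1000.0, 40.0, seed=3)
        rows = hm.heights - hm.heights.mean(axis=1, keepdims=True)
        coeffs = np.abs(2.0 / 512 * np.fft.rfft(rows, axis=1)) ** 2
        mean_spec = coeffs[:, 1:256].mean(axis=0)
        freqs = np.arange(1, 256) / 5000.0
        peak_nu = freqs[np.argmax(mean_spec)]
        assert abs(peak_nu - 1e-3) <= 1.0 / 5000.0 + 1e-12

    def test_deterministic_given_seed(self):
        a = make_roughness_field(128, 5000.0, 800.0, 10.0, seed=42)
        b = make_roughness_field(128, 5000.0, 800.0, 10.0, seed=42)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_zero_mean(self):
        hm = make_roughness_field(256, 5000.0, 300.0, 5.0, seed=1)
        assert abs(hm.heights.mean()) < 1e-9 * hm.heights.std()

    @pytest.mark.parametrize("period", [5.0, 4000.0])
    def test_unrepresentable_period_rejected(self, period):
        with pytest.raises(ValueError):
            make_roughness_field(128, 5000.0, period, 10.0, seed=0)


class TestCellBody:
    def test_control_dome_max_height(self):
        params = SceneParams(field_size_nm=30000.0, cell_height_nm=1200.0,
                             cell_diameter_nm=9800.0, n_lobes=0)
        body = make_cell_body(params)
        assert body.heights.max() == pytest.approx(1200.0, rel=0.01)
        # single global maximum region at the centre
        peak = np.unravel_index(np.argmax(body.heights), body.heights.shape)
        assert abs(peak[0] - 255.5) < 2 and abs(peak[1] - 255.5) < 2

    def test_three_lobes_give_three_local_maxima(self):
        """Exhaustive local-maximum scan over the cell footprint."""
        params = SceneParams(field_size_nm=30000.0, cell_height_nm=638.0,
                             cell_diameter_nm=16500.0, n_lobes=3,
                             lobe_height_nm=200.0, seed=5)
        body = make_cell_body(params).heights
        footprint = body >= CONTACT_HEIGHT_NM
        local_max = (body == ndimage.maximum_filter(body, size=5)) & footprint
        # count maxima rising above half the lobe height over the cap top
        cap_top = body[footprint].max() - 200.0 * params.cell_height_nm / (
            params.cell_height_nm + 200.0)
        strong = local_max & (body > cap_top + 0.5 * 200.0 * 0.8)
        _, n = ndimage.label(strong)
        assert n == 3

    def test_zero_height_is_flat(self):
        params = SceneParams(cell_height_nm=0.0)
        assert np.all(make_cell_body(params).heights == 0.0)

    def test_cell_larger_than_field_rejected(self):
        with pytest.raises(ValueError):
            make_cell_body(SceneParams(field_size_nm=10000.0,
                                       cell_diameter_nm=9800.0))

    def test_basal_contour_diameter(self):
        params = SceneParams(field_size_nm=30000.0, cell_height_nm=1200.0,
                             cell_diameter_nm=9800.0, n_lobes=0)
        body = make_cell_body(params)
        area = np.count_nonzero(body.heights >= CONTACT_HEIGHT_NM) \
            * body.pixel_size_nm ** 2
        d = 2.0 * np.sqrt(area / np.pi)
        assert d == pytest.approx(9800.0, rel=0.02)


class TestFragments:
    def test_no_fragments_empty(self):
        hm, placed = scatter_fragments(SceneParams(n_fragments=0), None, 0)
        assert np.all(hm.heights == 0.0) and placed == []

    def test_planted_fragments_disjoint_and_counted(self):
        params = SceneParams(grid_points=300, field_size_nm=6000.0,
                             cell_height_nm=0.0, n_fragments=26, seed=2)
        hm, placed = scatter_fragments(params, None, 2)
        assert len(placed) == 26
        centers = np.array([p["center_nm"] for p in placed])
        radii = np.array([p["size_nm"] for p in placed]) / 2.0
        for i in range(26):
            d = np.hypot(*(centers[i] - centers[i + 1:]).T)
            assert np.all(d >= radii[i] + radii[i + 1:])

    def test_mixture_mean_matches_truncated_normal_oracle(self):
        """Pooled over 20 seeds, the empirical size mean is within 3 SE of
        the truncated-mixture mean (scipy.stats.truncnorm oracle)."""
        mu, sd, lo = 330.0, 150.0, 150.0
        a = (lo - mu) / sd
        target = sps.truncnorm.mean(a, np.inf, loc=mu, scale=sd)
        sizes = []
        for seed in range(20):
            params = SceneParams(grid_points=300, field_size_nm=6000.0,
                                 cell_height_nm=0.0, n_fragments=26, seed=seed)
            _, placed = scatter_fragments(params, None, seed)
            sizes += [p["size_nm"] for p in placed]
        sizes = np.array(sizes)
        se = sizes.std(ddof=1) / np.sqrt(len(sizes))
        assert abs(sizes.mean() - target) <= 3 * se

    def test_bimodal_truth_recorded(self):
        params = SceneParams(
            grid_points=300, field_size_nm=6000.0, cell_height_nm=0.0,
            n_fragments=20, seed=3,
            fragment_size_mixture=[(0.5, 250.0, 60.0), (0.5, 810.0, 120.0)])
        _, placed = scatter_fragments(params, None, 3)
        assert len(placed) == 20
        assert max(p["size_nm"] for p in placed) > 500.0

    def test_impossible_density_raises_placement_error(self):
        params = SceneParams(
            grid_points=128, field_size_nm=3000.0, cell_height_nm=0.0,
            n_fragments=60,
            fragment_size_mixture=[(1.0, 800.0, 50.0)], seed=0)
        with pytest.raises(PlacementError) as exc:
            scatter_fragments(params, None, 0)
        assert 0 <= exc.value.placed < 60


class TestNetMesh:
    def test_no_chains_empty(self):
        hm, granules = make_net_mesh(SceneParams(n_granule_chains=0), 0)
        assert np.all(hm.heights == 0.0) and granules == []

    def test_granule_sizes_match_normal_within_3_se(self):
        sizes = []
        for seed in range(5):
            params = scene_from_preset("net_mesh", seed=seed)
            _, granules = make_net_mesh(params, seed)
            sizes += [g["size_nm"] for g in granules]
        sizes = np.array(sizes)
        se = sizes.std(ddof=1) / np.sqrt(len(sizes))
        assert abs(sizes.mean() - 50.0) <= 3 * se

    def test_deterministic(self):
        params = scene_from_preset("net_mesh", seed=9)
        _, g1 = make_net_mesh(params, 9)
        _, g2 = make_net_mesh(params, 9)
        assert g1 == g2

    def test_unresolvable_granule_rejected(self):
        params = SceneParams(grid_points=64, field_size_nm=5000.0,
                             granule_size_mean_nm=50.0, n_granule_chains=1)
        with pytest.raises(ValueError, match="resolvable"):
            make_net_mesh(params, 0)


class TestScene:
    def test_bit_identical_for_equal_params(self):
        p = scene_from_preset("spread_segmented", seed=13)
        a, _ = make_scene(p)
        b, _ = make_scene(p)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_additivity_of_components(self):
        hm, _, comps = make_scene(scene_from_preset("spread_segmented", seed=3),
                                  return_components=True)
        total = sum(comps.values())
        np.testing.assert_array_equal(hm.heights, total)

    def test_all_zero_scene(self):
        p = SceneParams(cell_height_nm=0.0, band1_amplitude_nm=0.0,
                        band2_amplitude_nm=0.0, substrate_noise_sd_nm=0.0)
        hm, truth = make_scene(p)
        assert np.all(hm.heights == 0.0)
        assert truth.true_cell_height_nm == 0.0

    @pytest.mark.parametrize("preset,expected_type", [
        ("control", 1), ("spread_segmented", 2),
        ("spread_unsegmented", 3), ("netotic", 4)])
    def test_truth_type_rule_table(self, preset, expected_type):
        _, truth = make_scene(scene_from_preset(preset, seed=1))
        assert truth.true_type == expected_type

    def test_mesh_present_forces_type_4(self):
        _, truth = make_scene(scene_from_preset("net_mesh", seed=1))
        assert truth.true_type == 4

    def test_fragment_truth_count_matches_list(self):
        _, truth = make_scene(scene_from_preset("netotic", seed=4))
        assert truth.n_fragments == len(truth.fragments) == 58


class TestSerialization:
    def test_scene_params_yaml_round_trip(self):
        p = scene_from_preset("spread_segmented", seed=21,
                              substrate_noise_sd_nm=0.7)
        back = SceneParams.from_yaml(p.to_yaml())
        assert back == p

    def test_ground_truth_json_round_trip(self):
        _, truth = make_scene(scene_from_preset("netotic", seed=2))
        back = GroundTruth.from_json(truth.to_json())
        assert back == truth

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(grid_points=32)
        with pytest.raises(ValueError):
            SceneParams(band1_period_nm=400.0, band1_amplitude_nm=10.0)
        with pytest.raises(ValueError):
            SceneParams(fragment_size_mixture=[(0.5, 300.0, 50.0)])
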