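import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilmz import (
    SyntheticTruth,
    ThresholdConfig,
    ZProfile,
    estimate_background,
    find_lower_boundary,
    find_peak,
    find_upper_boundary,
    random_spikes,
    roi_thickness,
    simulate_profile,
)
from biofilmz.core import FLAG_BOUNDARY_AT_EDGE, FLAG_NO_SIGNAL, FLAG_SPIKE_REJECTED

from _oracles import iter_mask_cases, oracle_boundaries, rowgap_boundaries
from conftest import make_profile


class TestFindPeak:
    @pytest.mark.parametrize(
        "intensity,expected",
        [([1, 5, 9, 5, 1], 2), ([1, 9, 9, 1], 1), ([3, 3, 3], 0)],
    )
    def test_peak_with_first_index_tie_break(self, intensity, expected):
        assert find_peak(np.asarray(intensity, dtype=float)) == expected

    def test_accepts_profile_object(self):
        assert find_peak(make_profile([1, 5, 2])) == 1


class TestEstimateBackground:
    def test_side_specific_window_means(self):
        intensity = np.array([2.0, 2, 10, 10, 4, 4])
        cfg = ThresholdConfig(background_window_fraction=1 / 3)
        el = estimate_background(intensity, "electrode", 2, cfg)
        bu = estimate_background(intensity, "buffer", 2, cfg)
        assert el.mean_intensity == 2.0 and el.n_samples == 2
        assert bu.mean_intensity == 4.0 and bu.n_samples == 2

    def test_uniform_profile_same_mean_both_sides(self):
        intensity = np.full(10, 7.0)
        for side in ("electrode", "buffer"):
            est = estimate_background(intensity, side, 5)
            assert est.mean_intensity == 7.0

    def test_support_mask_excludes_bright_samples(self):
        # slab reaches into the nominal 50% edge window
        intensity = np.array([5.0, 5, 100, 100, 100, 100, 100, 8, 8, 8])
        cfg = ThresholdConfig(background_window_fraction=0.5)
        support = intensity <= 30
        el = estimate_background(intensity, "electrode", 4, cfg, support=support)
        assert el.mean_intensity == 5.0
        bu = estimate_background(intensity, "buffer", 4, cfg, support=support)
        assert bu.mean_intensity == 8.0

    def test_too_short_profile_raises(self):
        with pytest.raises(ValueError):
            estimate_background(np.array([1.0, 2]), "electrode", 0)


class TestLowerBoundary:
    def test_first_exceedance_scan(self):
        hit = find_lower_boundary(np.array([1.0, 1, 4, 9, 9]), 3.0, 3)
        assert (hit.index, hit.found) == (2, True)

    def test_signal_at_edge_flagged(self):
        hit = find_lower_boundary(np.array([9.0, 9, 9]), 3.0, 0)
        assert hit.index == 0 and hit.found and hit.at_edge

    def test_no_signal(self):
        hit = find_lower_boundary(np.array([1.0, 1, 1]), 3.0, 0)
        assert not hit.found and hit.index is None

    def test_contiguous_mode_skips_detached_noise(self):
        intensity = np.array([1.0, 5, 1, 9, 9, 1])
        assert find_lower_boundary(intensity, 3.0, 3).index == 1
        assert find_lower_boundary(intensity, 3.0, 3, require_contiguity=True).index == 3


class TestUpperBoundary:
    def test_gap_rejects_planktonic_spike(self):
        hit = find_upper_boundary(np.array([1.0, 9, 9, 9, 1, 5, 1]), 3.0, 1)
        assert hit.index == 3 and hit.found and hit.spike_rejected

    def test_run_to_edge_flagged(self):
        hit = find_upper_boundary(np.array([1.0, 9, 9]), 3.0, 1)
        assert hit.index == 2 and hit.at_edge

    def test_single_sample_biofilm(self):
        hit = find_upper_boundary(np.array([1.0, 9, 1]), 3.0, 1)
        assert hit.index == 1 and hit.found

    def test_peak_below_threshold_not_found(self):
        hit = find_upper_boundary(np.array([1.0, 2, 1]), 3.0, 1)
        assert not hit.found


class TestRoiThickness:
    def test_full_hand_trace(self):
        p = make_profile([1, 1, 8, 9, 8, 1, 1], z=np.arange(7.0))
        r = roi_thickness(p, ThresholdConfig(background_window_fraction=2 / 7))
        assert r.background_electrode == 1.0 and r.background_buffer == 1.0
        assert r.threshold_left == 3.0 and r.threshold_right == 3.0
        assert (r.boundaries.lower_idx, r.boundaries.upper_idx) == (2, 4)
        assert r.thickness_um == 2.0

    def test_scale_equivariance(self):
        p = make_profile([1, 1, 8, 9, 8, 1, 1])
        r1 = roi_thickness(p)
        r2 = roi_thickness(make_profile(p.intensity * 10))
        assert r1.boundaries.lower_idx == r2.boundaries.lower_idx
        assert r1.boundaries.upper_idx == r2.boundaries.upper_idx
        assert r1.thickness_um == r2.thickness_um

    def test_flat_profile_reports_no_signal(self):
        r = roi_thickness(make_profile([5, 5, 5, 5]))
        assert r.thickness_um is None
        assert FLAG_NO_SIGNAL in r.flags

    def test_orientation_flip_gives_same_thickness(self):
        p, truth = simulate_profile(SyntheticTruth())
        r = roi_thickness(p)
        flipped = make_profile(
            p.intensity[::-1], z=p.z, orientation="electrode_high_z"
        )
        rf = roi_thickness(flipped)
        assert rf.thickness_um == pytest.approx(r.thickness_um)
        assert rf.boundaries.lower_z <= rf.boundaries.upper_z

    def test_bright_peak_spike_does_not_hijack_measurement(self):
        # planktonic speck 3x brighter than the slab, beyond a background gap
        z = np.arange(40.0)
        intensity = np.full(40, 5.0)
        intensity[10:26] = 100.0
        intensity[33:35] = 300.0
        r = roi_thickness(make_profile(intensity, z=z))
        assert (r.boundaries.lower_idx, r.boundaries.upper_idx) == (10, 25)
        assert FLAG_SPIKE_REJECTED in r.flags

    def test_boundary_at_edge_flag(self):
        intensity = np.array([50.0, 50, 50, 50, 1, 1, 1, 1, 1, 1])
        r = roi_thickness(make_profile(intensity))
        assert FLAG_BOUNDARY_AT_EDGE in r.flags

    def test_missing_thickness_is_none_not_zero(self):
        r = roi_thickness(make_profile([0, 0, 0, 0]))
        assert r.thickness_um is None


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.integers(min_value=0, max_value=9), min_size=3, max_size=20),
        scale=st.floats(min_value=0.01, max_value=1000, allow_nan=False),
    )
    def test_scale_equivariance_property(self, data, scale):
        p = make_profile(data)
        r1 = roi_thickness(p)
        r2 = roi_thickness(make_profile(np.asarray(data, dtype=float) * scale))
        assert r1.thickness_um == (
            pytest.approx(r2.thickness_um) if r2.thickness_um is not None else None
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_multiplier_monotonicity(self, seed):
        p, _ = simulate_profile(SyntheticTruth(noise_sd=4.0, seed=seed))
        prev = np.inf
        for mult in (1.5, 2.0, 3.0, 4.0, 6.0):
            r = roi_thickness(p, ThresholdConfig(multiplier=mult))
            t = r.thickness_um if r.thickness_um is not None else -np.inf
            assert t <= prev + 1e-9
            prev = t

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_thickness_bounded_by_z_range(self, seed):
        rng = np.random.default_rng(seed)
        p = make_profile(rng.integers(0, 50, size=30).astype(float))
        r = roi_thickness(p)
        if r.thickness_um is not None:
            assert 0 <= r.thickness_um <= p.z_range_um

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_spike_robustness_property(self, seed):
        rng = np.random.default_rng(seed)
        truth = SyntheticTruth(seed=seed)
        base, _ = simulate_profile(truth)
        r0 = roi_thickness(base)
        spiked, _ = simulate_profile(random_spikes(truth, int(rng.integers(1, 4)), rng))
        r1 = roi_thickness(spiked)
        assert r0.thickness_um == r1.thickness_um
        assert r0.boundaries.lower_idx == r1.boundaries.lower_idx
        assert r0.boundaries.upper_idx == r1.boundaries.upper_idx


class TestOracleEquivalence:
    """Boundary operations vs run enumeration and the row-gap transcription."""

    @pytest.mark.parametrize("threshold", [3.0, 4.5])
    def test_small_grid_matches_both_oracles(self, threshold):
        values = [0.0, 1.0, 4.0, 9.0]
        for n in range(3, 7):
            for idx in np.ndindex(*([len(values)] * n)):
                intensity = np.array([values[i] for i in idx])
                id_max = int(np.argmax(intensity))
                self._check_case(intensity, threshold, id_max)

    def test_mask_classes_match_both_oracles(self):
        for intensity, id_max in iter_mask_cases(8):
            self._check_case(intensity, 3.0, id_max)

    @staticmethod
    def _check_case(intensity, threshold, id_max):
        lo_o, up_o = oracle_boundaries(intensity, threshold, id_max, False)
        lo_c, _ = oracle_boundaries(intensity, threshold, id_max, True)
        beg_r, end_r = rowgap_boundaries(intensity, threshold, id_max)

        lo = find_lower_boundary(intensity, threshold, id_max)
        loc = find_lower_boundary(intensity, threshold, id_max, require_contiguity=True)
        up = find_upper_boundary(intensity, threshold, id_max)

        assert (lo.index if lo.found else None) == lo_o
        assert (loc.index if loc.found else None) == lo_c
        assert (up.index if up.found else None) == up_o
        # the literal row-gap transcription defines boundaries only when the
        # peak row survives thresholding
        if intensity[id_max] > threshold:
            assert beg_r == lo_o
            assert end_r == up_o
        else:
            assert beg_r is None and end_r is None
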