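import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from olfbold.activation import (
    _ks_bulk,
    combined_map,
    detect_activation,
    ks_two_sample,
    roi_active_counts,
)
from olfbold.paradigm import analysis_windows
from olfbold.synthetic import VolumeSeries, default_config, simulate_subject


def ks_statistic_oracle(a, b):
    """Brute force: evaluate both ECDFs at every sample point, take the sup."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = 0.0
    for x in np.concatenate([a, b]):
        d = max(d, abs((a <= x).mean() - (b <= x).mean()))
    return d


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [5, 6, 7, 8])
        assert d == 1.0

    def test_interleaved_thirds(self):
        d, _ = ks_two_sample([1, 3, 5], [2, 4, 6])
        assert d == pytest.approx(1 / 3)

    def test_constant_identical_samples_give_p_one(self):
        d, p = ks_two_sample([2.0, 2.0], [2.0, 2.0, 2.0])
        assert d == 0.0 and p == 1.0

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1.0, 2.0])

    @given(
        a=st.lists(st.integers(0, 9), min_size=2, max_size=8),
        b=st.lists(st.integers(0, 9), min_size=2, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_statistic_matches_brute_force_oracle(self, a, b):
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(ks_statistic_oracle(a, b), abs=1e-12)


class TestKsBulk:
    def test_matches_scipy_per_voxel(self, rng):
        on = rng.normal(size=(40, 30))
        off = rng.normal(size=(40, 70))
        d, p = _ks_bulk(on, off)
        for i in range(40):
            ref = sp_stats.ks_2samp(on[i], off[i], method="asymp")
            assert d[i] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[i] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_handles_ties(self, rng):
        on = rng.integers(0, 4, size=(25, 12)).astype(float)
        off = rng.integers(0, 4, size=(25, 20)).astype(float)
        d, _ = _ks_bulk(on, off)
        for i in range(25):
            assert d[i] == pytest.approx(ks_statistic_oracle(on[i], off[i]), abs=1e-12)


def _series_from_flat(flat, grid):
    return VolumeSeries(np.asarray(flat, float).reshape(*grid, -1), 2.0, 1.5)


class TestDetectActivation:
    def test_noise_free_active_voxel_detected(self, paradigm, windows, rng):
        n = paradigm.n_frames
        grid = (2, 2, 1)
        flat = np.ones((4, n)) * 100 + 0.01 * rng.standard_normal((4, n))
        on_shift = np.zeros(n)
        on_shift[windows.ks_on_frames] = 2.0
        flat[0] += on_shift
        amap = detect_activation(_series_from_flat(flat, grid), windows, 0.01)
        assert amap.mask.ravel()[0]
        assert not amap.mask.ravel()[1:].any()

    def test_all_zero_series_yields_no_detection(self, paradigm, windows):
        flat = np.zeros((4, paradigm.n_frames))
        amap = detect_activation(_series_from_flat(flat, (2, 2, 1)), windows, 0.01)
        assert not amap.mask.any()
        assert np.all(amap.pvals == 1.0)

    def test_threshold_monotone(self, paradigm, windows, rng):
        flat = rng.normal(size=(100, paradigm.n_frames))
        s = _series_from_flat(flat, (10, 10, 1))
        loose = detect_activation(s, windows, 0.05)
        strict = detect_activation(s, windows, 0.001)
        assert not (strict.mask & ~loose.mask).any()

    def test_adjustment_never_adds_detections(self, paradigm, windows, rng):
        flat = rng.normal(size=(100, paradigm.n_frames))
        s = _series_from_flat(flat, (10, 10, 1))
        raw = detect_activation(s, windows, 0.01, adjust="none")
        bonf = detect_activation(s, windows, 0.01, adjust="bonferroni")
        bh = detect_activation(s, windows, 0.01, adjust="bh")
        assert not (bonf.mask & ~raw.mask).any()
        assert not (bh.mask & ~raw.mask).any()

    def test_overlapping_windows_rejected(self, paradigm, windows):
        bad = dataclasses.replace(windows, ks_off_frames=windows.ks_on_frames[:5])
        flat = np.zeros((4, paradigm.n_frames))
        with pytest.raises(ValueError, match="overlap"):
            detect_activation(_series_from_flat(flat, (2, 2, 1)), bad, 0.01)

    def test_brain_mask_restricts_testing(self, paradigm, windows, rng):
        flat = rng.normal(size=(4, paradigm.n_frames))
        mask = np.array([[True, False], [False, False]]).reshape(2, 2, 1)
        amap = detect_activation(_series_from_flat(flat, (2, 2, 1)), windows, 0.5,
                                 brain_mask=mask)
        assert np.isnan(amap.pvals[~mask]).all()
        assert np.isfinite(amap.pvals[mask]).all()


class TestRoiCounts:
    def test_empty_mask_gives_all_zero(self, atlas):
        from olfbold.activation import ActivationMap

        amap = ActivationMap(np.zeros(atlas.grid_dims, bool), None, 0.01, "s")
        counts = roi_active_counts(amap, atlas)
        assert len(counts) == 11 and (counts == 0).all()

    def test_full_roi_mask_counts_roi_size(self, atlas):
        from olfbold.activation import ActivationMap

        mask = atlas.roi_mask("olfactory_bulb")
        amap = ActivationMap(mask, None, 0.01, "s")
        assert roi_active_counts(amap, atlas)["olfactory_bulb"] == 32

    def test_grid_mismatch_rejected(self, atlas):
        from olfbold.activation import ActivationMap

        amap = ActivationMap(np.zeros((4, 4, 2), bool), None, 0.01, "s")
        with pytest.raises(ValueError, match="grid"):
            roi_active_counts(amap, atlas)

    def test_high_snr_counts_track_truth(self, paradigm, atlas):
        cfg = default_config(seed=0)
        gp = dataclasses.replace(cfg.groups["HC"], amplitude_mean=3.0,
                                 amplitude_sd=0.0, active_fraction=0.6)
        cfg = dataclasses.replace(cfg, groups={"PD": gp, "HC": gp}, noise_sd=0.3,
                                  drift_slope=0.0, physio_amps=(0.0, 0.0),
                                  lf_noise_sd=0.0)
        series, truth, _ = simulate_subject(cfg, atlas, paradigm, "HC", seed=2)
        w = analysis_windows(paradigm)
        amap = detect_activation(series, w, 0.01)
        from olfbold.activation import ActivationMap

        true_counts = roi_active_counts(
            ActivationMap(truth.mask, None, 0.01, "t"), atlas
        )
        counts = roi_active_counts(amap, atlas)
        ratio = counts[true_counts > 0] / true_counts[true_counts > 0]
        assert (np.abs(ratio - 1.0) <= 0.10).all()


class TestCombinedMap:
    def _map(self, mask):
        from olfbold.activation import ActivationMap

        return ActivationMap(mask, None, 0.01, "s")

    def test_union_of_disjoint_masks(self):
        m1 = np.zeros((3, 3, 1), bool)
        m1.ravel()[:3] = True
        m2 = np.zeros((3, 3, 1), bool)
        m2.ravel()[3:7] = True
        combined = combined_map([self._map(m1), self._map(m2)])
        assert combined.mask.sum() == 7
        assert combined.subject_id == "combined"
        assert combined.pvals is None

    def test_idempotent_on_identical_masks(self, rng):
        m = rng.random((4, 4, 2)) > 0.5
        combined = combined_map([self._map(m), self._map(m.copy())])
        assert np.array_equal(combined.mask, m)

    def test_union_is_monotone(self, rng):
        masks = [rng.random((4, 4, 2)) > 0.7 for _ in range(3)]
        small = combined_map([self._map(m) for m in masks[:2]])
        large = combined_map([self._map(m) for m in masks])
        assert not (small.mask & ~large.mask).any()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combined_map([])


class TestNullRoiScaling:
    def test_null_counts_scale_with_roi_size(self, paradigm, windows, atlas):
        """Under pure noise, expected per-ROI counts are proportional to ROI size."""
        rng = np.random.default_rng(77)
        total = np.zeros(11)
        sizes = atlas.roi_sizes().to_numpy(dtype=float)
        n_rep = 12
        overall = []
        for _ in range(n_rep):
            flat = rng.standard_normal((int(np.prod(atlas.grid_dims)), paradigm.n_frames))
            s = VolumeSeries(flat.reshape(*atlas.grid_dims, -1), 2.0, 1.5)
            amap = detect_activation(s, windows, 0.01)
            counts = roi_active_counts(amap, atlas)
            total += counts.to_numpy(dtype=float)
            overall.append(amap.mask.mean())
        rate = float(np.mean(overall))
        # least-squares slope through the origin of counts vs size
        slope = float((total @ sizes) / (sizes @ sizes) / n_rep)
        assert slope == pytest.approx(rate, rel=0.2)
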