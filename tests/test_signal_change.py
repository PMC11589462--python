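import dataclasses

import numpy as np
import pytest

from olfbold.paradigm import analysis_windows
from olfbold.signal_change import dss_volume, roi_dss, voxel_dss
from olfbold.synthetic import VolumeSeries, default_config, simulate_subject


class TestVoxelDss:
    def test_arithmetic(self, paradigm, windows):
        ts = np.ones(paradigm.n_frames)
        ts[windows.on_frames] = 1.02
        assert voxel_dss(ts, windows) == pytest.approx(2.0)

    def test_identical_distributions_give_zero(self, paradigm, windows):
        ts = np.full(paradigm.n_frames, 3.5)
        assert voxel_dss(ts, windows) == 0.0

    def test_zero_baseline_rejected(self, paradigm, windows):
        ts = np.zeros(paradigm.n_frames)
        with pytest.raises(ValueError, match="off mean|undefined"):
            voxel_dss(ts, windows)

    def test_noise_free_voxel_matches_closed_form(self, paradigm, windows):
        from olfbold.hrf import CANONICAL_HRF, block_response, expected_window_response

        a = 1.7
        r = block_response(paradigm, CANONICAL_HRF)
        ts = 1000.0 * (1 + a / 100.0 * r)
        expected = a * expected_window_response(paradigm, windows, CANONICAL_HRF)
        assert voxel_dss(ts, windows) == pytest.approx(expected, rel=1e-3)

    def test_gain_invariance(self, paradigm, windows, rng):
        ts = 100 + rng.normal(size=paradigm.n_frames)
        assert voxel_dss(7.3 * ts, windows) == pytest.approx(voxel_dss(ts, windows))


class TestRoiDss:
    def _uniform_series(self, atlas, paradigm, windows, dss_map):
        """Series whose on-frames are lifted by dss_map (%) per voxel."""
        n = paradigm.n_frames
        nvox = int(np.prod(atlas.grid_dims))
        flat = np.full((nvox, n), 100.0)
        lift = dss_map.ravel()
        flat[:, windows.on_frames] += lift[:, None]
        return VolumeSeries(flat.reshape(*atlas.grid_dims, n), paradigm.tr, 1.5)

    def test_single_voxel_selection(self, atlas, paradigm, windows):
        dss_map = np.zeros(atlas.grid_dims)
        ob = atlas.roi_mask("olfactory_bulb")
        dss_map[ob] = 2.0
        series = self._uniform_series(atlas, paradigm, windows, dss_map)
        sel = np.zeros(atlas.grid_dims, bool)
        sel[tuple(np.argwhere(ob)[0])] = True
        out = roi_dss(series, sel, atlas, windows, "individual")
        row = out[out.roi == "olfactory_bulb"].iloc[0]
        assert row.n_voxels == 1
        assert row.dss_percent == pytest.approx(2.0)

    def test_empty_intersection_flagged_missing(self, atlas, paradigm, windows):
        series = self._uniform_series(atlas, paradigm, windows, np.zeros(atlas.grid_dims))
        out = roi_dss(series, np.zeros(atlas.grid_dims, bool), atlas, windows, "individual")
        assert (out.n_voxels == 0).all()
        assert out.dss_percent.isna().all()

    def test_grid_mismatch_rejected(self, atlas, paradigm, windows):
        series = VolumeSeries(np.ones((4, 4, 2, paradigm.n_frames)), paradigm.tr, 1.5)
        with pytest.raises(ValueError, match="grid"):
            roi_dss(series, np.ones((4, 4, 2), bool), atlas, windows, "individual")

    def test_unknown_scheme_rejected(self, atlas, paradigm, windows):
        series = self._uniform_series(atlas, paradigm, windows, np.zeros(atlas.grid_dims))
        with pytest.raises(ValueError, match="scheme"):
            roi_dss(series, np.zeros(atlas.grid_dims, bool), atlas, windows, "best")

    def test_dilution_law(self, atlas, paradigm, windows):
        """Adding k zero-amplitude voxels scales the mean by n/(n+k) exactly."""
        ob = atlas.roi_mask("olfactory_bulb")
        coords = np.argwhere(ob)
        n_act, k = 12, 8
        dss_map = np.zeros(atlas.grid_dims)
        for c in coords[:n_act]:
            dss_map[tuple(c)] = 2.0
        series = self._uniform_series(atlas, paradigm, windows, dss_map)

        individual = np.zeros(atlas.grid_dims, bool)
        for c in coords[:n_act]:
            individual[tuple(c)] = True
        combined = individual.copy()
        for c in coords[n_act:n_act + k]:
            combined[tuple(c)] = True

        d_ind = roi_dss(series, individual, atlas, windows, "individual")
        d_comb = roi_dss(series, combined, atlas, windows, "combined")
        v_ind = d_ind[d_ind.roi == "olfactory_bulb"].dss_percent.iloc[0]
        v_comb = d_comb[d_comb.roi == "olfactory_bulb"].dss_percent.iloc[0]
        assert v_comb == pytest.approx(v_ind * n_act / (n_act + k), rel=1e-6)

    def test_combined_below_individual_for_partial_responder(
        self, paradigm, windows, atlas
    ):
        """A subject active in a subset of the control map shows diluted
        combined-scheme ΔS/S (noise-free)."""
        cfg = default_config(seed=0)
        gp = dataclasses.replace(cfg.groups["PD"], active_fraction=0.3,
                                 amplitude_sd=0.0, habituation_rate=1.0)
        cfg = dataclasses.replace(cfg, groups={"PD": gp, "HC": gp}, noise_sd=0.0,
                                  drift_slope=0.0, physio_amps=(0.0, 0.0),
                                  lf_noise_sd=0.0, voxel_amp_jitter=0.0)
        series, truth, _ = simulate_subject(cfg, atlas, paradigm, "PD", seed=4)
        control_union = atlas.labels > 0     # control map covering every ROI voxel
        d_ind = roi_dss(series, truth.mask, atlas, windows, "individual")
        d_comb = roi_dss(series, control_union, atlas, windows, "combined")
        merged = d_ind.merge(d_comb, on="roi", suffixes=("_i", "_c"))
        ok = merged.dropna()
        assert (ok.dss_percent_c < ok.dss_percent_i).all()

    def test_individual_selection_is_positively_biased(self, paradigm, atlas):
        """Averaging over detected voxels exceeds the all-voxel ROI average."""
        from olfbold.activation import detect_activation

        w = analysis_windows(paradigm)
        cfg = default_config(seed=0)
        gp = dataclasses.replace(cfg.groups["HC"], amplitude_mean=2.0,
                                 amplitude_sd=0.0, active_fraction=0.5)
        cfg = dataclasses.replace(cfg, groups={"PD": gp, "HC": gp}, noise_sd=0.3,
                                  drift_slope=0.0, physio_amps=(0.0, 0.0),
                                  lf_noise_sd=0.0)
        series, truth, _ = simulate_subject(cfg, atlas, paradigm, "HC", seed=6)
        amap = detect_activation(series, w, 0.01)
        d_sel = roi_dss(series, amap.mask, atlas, w, "individual")
        d_all = roi_dss(series, atlas.labels > 0, atlas, w, "combined")
        merged = d_sel.merge(d_all, on="roi", suffixes=("_sel", "_all")).dropna()
        assert (merged.dss_percent_sel > merged.dss_percent_all).all()


class TestDssVolume:
    def test_matches_voxel_dss(self, paradigm, windows, rng):
        grid = (3, 3, 2)
        n = paradigm.n_frames
        data = 100 + rng.normal(size=(*grid, n))
        series = VolumeSeries(data, paradigm.tr, 1.5)
        vol = dss_volume(series, windows)
        for idx in np.ndindex(grid):
            assert vol[idx] == pytest.approx(voxel_dss(data[idx], windows))
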