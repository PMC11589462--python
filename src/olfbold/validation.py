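"""Calibration and recovery experiments for the pipeline.

Each function here runs a self-contained simulation experiment and measures
one property of the analysis chain: the false-positive rate of the voxel-wise
detection under pure noise, detection power at a known effect size, recovery
of the simulated ΔS/S amplitude by the window rule, recovery of the HRF shape
metrics, and the voxel-selection sign-reversal phenomenon (individual vs
combined activation maps reporting opposite group differences).  Problem
sizes are deliberately desk-scale; they are documented in the methods note.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .activation import combined_map, detect_activation
from .hrf import expected_window_response
from .hrf_estimation import fit_hrf, hrf_basis, hrf_fwhm, hrf_ttp
from .paradigm import StimulusParadigm, analysis_windows, build_paradigm
from .preprocess import PreprocessConfig, preprocess_series
from .signal_change import dss_volume, roi_dss
from .synthetic import (
    SimulationConfig,
    VolumeSeries,
    default_config,
    make_atlas,
    simulate_cohort,
    simulate_subject,
)

__all__ = [
    "null_false_positive_rate",
    "detection_power",
    "dss_noise_free_recovery",
    "dss_cohort_bias",
    "hrf_recovery",
    "selection_reversal",
]


def _default_paradigm() -> StimulusParadigm:
    return build_paradigm(2.0, 60.0, 3, 60.0, 120.0)


def null_false_positive_rate(
    seed: int, n_voxels: int = 12_288, threshold: float = 0.01
) -> tuple[float, int]:
    """Voxel-wise detection rate on pure white noise (no true activation).

    Returns (rate, n_voxels).  Noise is iid Gaussian per frame, so every
    detection is a false positive.
    """
    p = _default_paradigm()
    w = analysis_windows(p)
    rng = np.random.default_rng(seed)
    side = int(round(n_voxels ** (1 / 3))) + 1
    grid = (side, side, max(n_voxels // (side * side) + 1, 1))
    nvox = int(np.prod(grid))
    data = rng.standard_normal((nvox, p.n_frames)).reshape(*grid, p.n_frames)
    series = VolumeSeries(data=data, tr=p.tr, voxel_size=1.5)
    amap = detect_activation(series, w, threshold=threshold)
    return float(amap.mask.mean()), nvox


def detection_power(
    seed: int, amplitude: float = 2.0, noise_sd: float = 0.5, threshold: float = 0.01
) -> tuple[float, int]:
    """Fraction of truly active voxels detected at a known amplitude and noise.

    One simulated subject, thermal noise only (no drift or physiological
    terms, which exist to exercise the filters, not the detector).
    """
    p = _default_paradigm()
    w = analysis_windows(p)
    atlas = make_atlas()
    cfg = default_config(seed=seed)
    groups = {
        g: dataclasses.replace(gp, amplitude_mean=amplitude, amplitude_sd=0.0,
                               active_fraction=1.0)
        for g, gp in cfg.groups.items()
    }
    cfg = dataclasses.replace(cfg, groups=groups, noise_sd=noise_sd,
                              drift_slope=0.0, physio_amps=(0.0, 0.0))
    series, truth, _ = simulate_subject(cfg, atlas, p, "HC", seed=seed)
    amap = detect_activation(series, w, threshold=threshold)
    n_true = int(truth.mask.sum())
    detected = int((amap.mask & truth.mask).sum())
    return detected / n_true, n_true


def dss_noise_free_recovery(amplitude: float = 2.0) -> tuple[float, float]:
    """Relative error of the window-rule amplitude estimate on noise-free data.

    Simulates a noise-free, drift-free subject, applies the ΔS/S window rule
    to the truly active voxels and divides by the closed-form window factor
    (the plateau correction).  Returns (relative error, window factor).
    """
    p = _default_paradigm()
    w = analysis_windows(p)
    atlas = make_atlas()
    cfg = default_config(seed=0)
    gp = dataclasses.replace(
        cfg.groups["HC"], amplitude_mean=amplitude, amplitude_sd=0.0,
        active_fraction=1.0, habituation_rate=1.0,
    )
    cfg = dataclasses.replace(
        cfg, groups={"PD": gp, "HC": gp}, noise_sd=0.0, drift_slope=0.0,
        physio_amps=(0.0, 0.0), lf_noise_sd=0.0, voxel_amp_jitter=0.0,
    )
    series, truth, _ = simulate_subject(cfg, atlas, p, "HC", seed=1)
    dss = dss_volume(series, w)
    measured = float(np.nanmean(dss[truth.mask]))
    factor = expected_window_response(p, w, gp.hrf, habituation_rate=1.0)
    recovered = measured / factor
    return abs(recovered - amplitude) / amplitude, factor


def dss_cohort_bias(seed: int, n: int = 24) -> tuple[float, int]:
    """Cohort-mean corrected ΔS/S minus mean true amplitude (percentage points).

    Simulates ``n`` control subjects under the default noise model (thermal
    noise + drift + physiological and low-frequency terms), runs the temporal
    preprocessing stages (high-pass + low-pass; spatial smoothing is a
    partial-volume matter orthogonal to the window rule, see the methods
    note), applies the window rule over each subject's truly active voxels,
    corrects by the window factor for the control HRF/habituation, and
    compares the cohort mean against the mean simulated amplitude.
    """
    p = _default_paradigm()
    w = analysis_windows(p)
    atlas = make_atlas()
    cfg = default_config(seed=seed)
    cfg = dataclasses.replace(cfg, n_subjects={"PD": 2, "HC": n})
    pre = PreprocessConfig(do_smooth=False)
    gp = cfg.groups["HC"]
    factor = expected_window_response(p, w, gp.hrf, habituation_rate=gp.habituation_rate)

    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n)]
    est, true = [], []
    for s in seeds:
        series, truth, _ = simulate_subject(cfg, atlas, p, "HC", seed=s)
        pseries, _ = preprocess_series(series, pre)
        dss = dss_volume(pseries, w)
        est.append(float(np.nanmean(dss[truth.mask])) / factor)
        true.append(float(truth.amplitude[truth.mask].mean()))
    return float(np.mean(est) - np.mean(true)), n


def hrf_recovery(
    seed: int, n_fits: int = 50, amplitude: float = 1.0, noise_sd: float = 0.5,
    n_voxels: int = 30,
) -> tuple[float, float, int]:
    """Median |FWHM error| and |TTP error| (s) over simulated ROI-level fits.

    Half the fits use the control impulse response, half the narrower patient
    one.  Each fit sees the mean of ``n_voxels`` active-voxel time series at
    the given plateau amplitude and per-voxel thermal noise, on the raw
    (unfiltered) signal scale.  Truth FWHM/TTP are read from the generating
    impulse response with the same crossing/refinement rules.
    """
    p = _default_paradigm()
    basis = hrf_basis(p)
    cfg = default_config()
    rng = np.random.default_rng(seed)
    t_fine = basis.t_fine

    fwhm_err, ttp_err = [], []
    for i in range(n_fits):
        gp = cfg.groups["HC"] if i % 2 == 0 else cfg.groups["PD"]
        truth_curve = gp.hrf.sample(t_fine)
        true_fwhm = hrf_fwhm(truth_curve, basis.dt_fine)
        true_ttp = hrf_ttp(truth_curve, basis.dt_fine)

        from .hrf import block_response

        r = block_response(p, gp.hrf, habituation_rate=1.0)
        s0 = 1000.0
        vox = s0 * (1.0 + (amplitude / 100.0) * r)[None, :] + s0 * (
            noise_sd / 100.0
        ) * rng.standard_normal((n_voxels, p.n_frames))
        est = fit_hrf(vox.mean(axis=0), basis)
        if np.isfinite(est.fwhm):
            fwhm_err.append(abs(est.fwhm - true_fwhm))
        if np.isfinite(est.ttp):
            ttp_err.append(abs(est.ttp - true_ttp))
    return float(np.median(fwhm_err)), float(np.median(ttp_err)), n_fits


def _reversal_config(seed: int, n_per_group: int) -> SimulationConfig:
    """Patients with 40% of the control active extent but doubled amplitude."""
    cfg = default_config(seed=seed)
    hc = cfg.groups["HC"]
    pd_gp = dataclasses.replace(
        cfg.groups["PD"],
        active_fraction=0.4 * hc.active_fraction,
        amplitude_mean=2.0 * hc.amplitude_mean,
        amplitude_sd=hc.amplitude_sd,
    )
    return dataclasses.replace(
        cfg, groups={"PD": pd_gp, "HC": hc},
        n_subjects={"PD": n_per_group, "HC": n_per_group},
    )


def selection_reversal(
    seed: int, n_replicates: int = 20, n_per_group: int = 6, threshold: float = 0.01
) -> tuple[float, int]:
    """Fraction of replicates reproducing the voxel-selection sign reversal.

    In each replicate, patients are simulated with 40% of the control active
    extent but twice the amplitude.  A replicate counts as a reversal when
    the pipeline reports patients > controls for individual-map ΔS/S AND
    patients < controls for combined-map ΔS/S (grand mean over subjects and
    ROIs with any selected voxels).

    Preprocessing is temporal only: on the desk-scale phantom the 4-mm
    kernel spans half an ROI, whereas at acquisition scale its footprint
    relative to the (thousands-of-voxel) regions is negligible — omitting
    smoothing is the scale-faithful correspondence (see the methods note).
    Detection uses the pipeline default (Bonferroni-adjusted p < 0.01).
    """
    p = _default_paradigm()
    atlas = make_atlas()
    pre = PreprocessConfig(do_smooth=False)
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_replicates)]

    w = analysis_windows(p)
    hits = 0
    for rs in rep_seeds:
        cfg = _reversal_config(rs, n_per_group)
        cohort = simulate_cohort(cfg, atlas, p)
        maps = {}
        pser = {}
        for subj in cohort.subjects:
            ps, _ = preprocess_series(subj.series, pre)
            pser[subj.subject_id] = ps
            maps[subj.subject_id] = detect_activation(
                ps, w, threshold=threshold, adjust="bonferroni",
                subject_id=subj.subject_id,
            )
        comb = combined_map(
            [maps[s.subject_id] for s in cohort.subjects if s.group == "HC"]
        )
        means = {("PD", "individual"): [], ("HC", "individual"): [],
                 ("PD", "combined"): [], ("HC", "combined"): []}
        for subj in cohort.subjects:
            ps = pser[subj.subject_id]
            ind = roi_dss(ps, maps[subj.subject_id].mask, atlas, w, "individual",
                          subj.subject_id)
            com = roi_dss(ps, comb.mask, atlas, w, "combined", subj.subject_id)
            iv = ind.dss_percent.dropna()
            cv = com.dss_percent.dropna()
            if len(iv):
                means[(subj.group, "individual")].append(iv.mean())
            if len(cv):
                means[(subj.group, "combined")].append(cv.mean())
        ind_rev = np.mean(means[("PD", "individual")]) > np.mean(means[("HC", "individual")])
        com_rev = np.mean(means[("PD", "combined")]) < np.mean(means[("HC", "combined")])
        if ind_rev and com_rev:
            hits += 1
    return hits / n_replicates, n_replicates
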