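"""Haemodynamic response estimation and FWHM / time-to-peak shape metrics.

The ROI-averaged time course of a subject's activated voxels is fit by least
squares with a flexible canonical basis: the double-gamma impulse response
plus its temporal and dispersion derivatives, each convolved with the
stimulation boxcar and sampled on the TR grid.  The impulse response is then
reconstructed on a fine grid from the fitted weights and the two shape
metrics are read off the reconstruction: time to peak (TTP, with parabolic
sub-sample refinement around the argmax) and full width at half maximum
(FWHM, linear interpolation of the half-maximum crossings).  Metrics are
computed on the impulse-response reconstruction, not on the block response,
so they live on the seconds scale of a single haemodynamic event.

A one-basis (canonical only) mode is available via ``include_derivatives``;
the default is the flexible fit, without which per-subject width variation
could not be expressed at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hrf import CANONICAL_HRF, HrfParams, hrf_time_derivative
from .paradigm import StimulusParadigm

__all__ = ["HrfBasis", "HrfEstimate", "hrf_basis", "fit_hrf", "hrf_ttp", "hrf_fwhm"]

_DISP_DELTA = 0.01  # finite-difference step for the dispersion derivative


@dataclass
class HrfBasis:
    """Fine-grid basis responses and their TR-sampled convolved design columns."""

    t_fine: np.ndarray        # (nt,) seconds, spacing dt_fine
    basis_fine: np.ndarray    # (k, nt) impulse-response basis on the fine grid
    design: np.ndarray        # (n_frames, k) convolved columns on the TR grid
    dt_fine: float
    names: tuple[str, ...]


@dataclass
class HrfEstimate:
    betas: np.ndarray          # weights for (canonical[, temporal, dispersion])
    hrf_samples: np.ndarray | None  # reconstruction on the fine grid; None if missing
    dt_fine: float
    fwhm: float                # seconds; NaN when missing
    ttp: float                 # seconds; NaN when missing
    fit_r2: float
    missing: bool = False
    missing_reason: str | None = None


def hrf_basis(
    p: StimulusParadigm,
    window_s: float = 32.0,
    dt_fine: float = 0.1,
    params: HrfParams = CANONICAL_HRF,
    include_derivatives: bool = True,
) -> HrfBasis:
    """Build the (canonical, temporal-derivative, dispersion-derivative) basis.

    Each basis response is sampled at ``dt_fine`` over ``window_s`` seconds,
    convolved with the paradigm's stimulation boxcar on the fine grid, and
    the convolved columns are read out at the frame acquisition times.
    """
    if window_s < 24:
        raise ValueError("window_s must be at least 24 s to contain the response")
    t_fine = np.arange(0.0, window_s, dt_fine)
    h = params.sample(t_fine)
    rows = [h]
    names = ["canonical"]
    if include_derivatives:
        rows.append(hrf_time_derivative(t_fine, params))
        h_wide = params.with_dispersion(params.dispersion + _DISP_DELTA).sample(
            t_fine, normalize=False
        )
        h_raw = params.sample(t_fine, normalize=False)
        peak = h_raw.max()
        rows.append((h_raw - h_wide) / (_DISP_DELTA * peak))
        names += ["temporal_derivative", "dispersion_derivative"]
    basis_fine = np.vstack(rows)

    # stimulation boxcar on the dt_fine grid (dt_fine need not divide tr:
    # convolved columns are read out at the nearest fine-grid sample)
    n_fine = int(round(p.total_s / dt_fine))
    tt = np.arange(n_fine) * dt_fine
    box_fine = np.zeros(n_fine)
    for onset in p.block_onsets:
        box_fine[(tt >= onset) & (tt < onset + p.on_s)] = 1.0
    cols = []
    frame_idx = np.round(np.arange(p.n_frames) * p.tr / dt_fine).astype(int)
    frame_idx = np.minimum(frame_idx, n_fine - 1)
    for row in basis_fine:
        conv = np.convolve(box_fine, row)[:n_fine] * dt_fine
        cols.append(conv[frame_idx])
    design = np.column_stack(cols)
    return HrfBasis(t_fine=t_fine, basis_fine=basis_fine, design=design,
                    dt_fine=dt_fine, names=tuple(names))


def fit_hrf(roi_ts: np.ndarray | None, basis: HrfBasis) -> HrfEstimate:
    """Least-squares fit of the convolved basis (plus intercept) to a time course.

    Returns a missing estimate when the ROI had no activated voxels
    (``roi_ts`` is None or all-NaN).  Shape metrics come from the fine-grid
    reconstruction ``Σ βk · basis_k``.
    """
    k = basis.design.shape[1]
    if roi_ts is None:
        return _missing_estimate(k, basis.dt_fine, "no activated voxels")
    y = np.asarray(roi_ts, dtype=float)
    if y.ndim != 1 or y.size != basis.design.shape[0]:
        raise ValueError("roi_ts length does not match the design")
    if np.all(np.isnan(y)):
        return _missing_estimate(k, basis.dt_fine, "no activated voxels")

    X = np.column_stack([np.ones(y.size), basis.design])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    betas = beta[1:]
    recon = betas @ basis.basis_fine
    ttp = hrf_ttp(recon, basis.dt_fine)
    fwhm = hrf_fwhm(recon, basis.dt_fine)
    return HrfEstimate(
        betas=betas, hrf_samples=recon, dt_fine=basis.dt_fine,
        fwhm=fwhm, ttp=ttp, fit_r2=r2,
        missing=not np.isfinite(ttp) and not np.isfinite(fwhm),
        missing_reason=None,
    )


def _missing_estimate(k: int, dt_fine: float, reason: str) -> HrfEstimate:
    return HrfEstimate(
        betas=np.full(k, np.nan), hrf_samples=None, dt_fine=dt_fine,
        fwhm=np.nan, ttp=np.nan, fit_r2=np.nan, missing=True, missing_reason=reason,
    )


def hrf_ttp(hrf_samples: np.ndarray, dt_fine: float) -> float:
    """Time (s) of the response's global maximum, parabolic sub-sample refinement.

    Missing (NaN) when the peak is non-positive or sits on the grid boundary
    (e.g. a monotone-decreasing trace has no interior peak).
    """
    y = np.asarray(hrf_samples, dtype=float)
    if y.size == 0:
        raise ValueError("hrf_samples is empty")
    i = int(np.argmax(y))
    if y[i] <= 0 or i == 0 or i == y.size - 1:
        return float("nan")
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    offset = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float((i + np.clip(offset, -0.5, 0.5)) * dt_fine)


def hrf_fwhm(hrf_samples: np.ndarray, dt_fine: float) -> float:
    """Width (s) between the half-maximum up-crossing and down-crossing.

    Linear interpolation between grid points; missing (NaN) when the response
    has no positive peak or never crosses half maximum on one side.
    """
    y = np.asarray(hrf_samples, dtype=float)
    if y.size == 0:
        raise ValueError("hrf_samples is empty")
    i = int(np.argmax(y))
    peak = y[i]
    if peak <= 0:
        return float("nan")
    half = peak / 2.0

    t_up = _cross_before(y, i, half, dt_fine)
    t_down = _cross_after(y, i, half, dt_fine)
    if np.isnan(t_up) or np.isnan(t_down):
        return float("nan")
    return float(t_down - t_up)


def _cross_before(y: np.ndarray, i_peak: int, half: float, dt: float) -> float:
    """Last up-crossing of ``half`` at or before the peak."""
    for j in range(i_peak, 0, -1):
        if y[j - 1] < half <= y[j]:
            frac = (half - y[j - 1]) / (y[j] - y[j - 1])
            return (j - 1 + frac) * dt
    if y[0] >= half:  # already above half at t = 0: no up-crossing recorded
        return float("nan")
    return float("nan")


def _cross_after(y: np.ndarray, i_peak: int, half: float, dt: float) -> float:
    """First down-crossing of ``half`` after the peak."""
    for j in range(i_peak, y.size - 1):
        if y[j] >= half > y[j + 1]:
            frac = (y[j] - half) / (y[j] - y[j + 1])
            return (j + frac) * dt
    return float("nan")
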