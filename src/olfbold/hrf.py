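"""Canonical haemodynamic response model (double gamma) and block responses.

The impulse response is the standard difference of two gamma densities
(response peak minus a late undershoot), parameterized by peak delay,
undershoot delay, the two dispersions and the undershoot ratio.  With the
default parameters (6, 16, 1, 1, 1/6) the peak-normalized response peaks at
t = 5 s.  Block responses are the convolution of this impulse response with
the stimulation boxcar, rescaled so that the sustained-plateau response to a
long block equals 1 — that makes a simulated amplitude ``a`` directly
interpretable as the plateau ΔS/S in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as _gamma

from .paradigm import AnalysisWindows, StimulusParadigm, boxcar_regressor

__all__ = [
    "HrfParams",
    "CANONICAL_HRF",
    "canonical_hrf",
    "block_response",
    "expected_window_response",
]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma parameters (seconds, except the unitless undershoot ratio)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion: float = 1.0
    u_dispersion: float = 1.0
    ratio: float = 1.0 / 6.0

    def sample(self, t: np.ndarray, normalize: bool = True) -> np.ndarray:
        return canonical_hrf(
            t,
            self.peak_delay,
            self.undershoot_delay,
            self.dispersion,
            self.u_dispersion,
            self.ratio,
            normalize=normalize,
        )

    def with_dispersion(self, dispersion: float) -> "HrfParams":
        return replace(self, dispersion=dispersion)


CANONICAL_HRF = HrfParams()


def canonical_hrf(
    t_grid: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    u_dispersion: float = 1.0,
    ratio: float = 1.0 / 6.0,
    normalize: bool = True,
) -> np.ndarray:
    """Sample the double-gamma impulse response on ``t_grid`` (seconds).

    The positive lobe is a gamma density with shape ``peak_delay/dispersion``
    and scale ``dispersion`` (mode at ``peak_delay − dispersion``); the
    undershoot is a second gamma density scaled by ``ratio``.  With
    ``normalize=True`` the response is divided by its maximum so the peak
    value is exactly 1.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("t_grid must be ascending and start at t >= 0")
    for name, v in [("peak_delay", peak_delay), ("undershoot_delay", undershoot_delay),
                    ("dispersion", dispersion), ("u_dispersion", u_dispersion)]:
        if v <= 0:
            raise ValueError(f"{name}={v} must be positive")
    if ratio < 0:
        raise ValueError(f"ratio={ratio} must be non-negative")
    g1 = _gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    g2 = _gamma.pdf(t, undershoot_delay / u_dispersion, scale=u_dispersion)
    h = g1 - ratio * g2
    if normalize:
        peak = h.max()
        if peak <= 0:
            raise ValueError("response has no positive peak; cannot peak-normalize")
        h = h / peak
    return h


def hrf_time_derivative(t_grid: np.ndarray, params: HrfParams = CANONICAL_HRF) -> np.ndarray:
    """Analytic time derivative of the peak-normalized double gamma."""
    t = np.asarray(t_grid, dtype=float)
    a1 = params.peak_delay / params.dispersion
    a2 = params.undershoot_delay / params.u_dispersion
    g1 = _gamma.pdf(t, a1, scale=params.dispersion)
    g2 = _gamma.pdf(t, a2, scale=params.u_dispersion)
    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = np.where(t > 0, g1 * ((a1 - 1) / np.where(t > 0, t, 1.0) - 1.0 / params.dispersion), 0.0)
        d2 = np.where(t > 0, g2 * ((a2 - 1) / np.where(t > 0, t, 1.0) - 1.0 / params.u_dispersion), 0.0)
    peak = (g1 - params.ratio * g2).max()
    return (d1 - params.ratio * d2) / peak


def block_response(
    p: StimulusParadigm,
    params: HrfParams = CANONICAL_HRF,
    dt: float = 0.1,
    habituation_rate: float = 1.0,
    window_s: float = 40.0,
) -> np.ndarray:
    """Noise-free unit-plateau response to the paradigm, sampled at frame times.

    Each odourant block b (0-based) contributes a boxcar scaled by
    ``habituation_rate**b`` convolved with the impulse response; the result is
    divided by the impulse-response integral so that a sustained block of
    amplitude 1 plateaus at 1.
    """
    if not 0.0 <= habituation_rate <= 1.0:
        raise ValueError("habituation_rate must lie in [0, 1]")
    t_fine = np.arange(0.0, p.total_s, dt)
    h = params.sample(np.arange(0.0, window_s, dt))
    plateau = h.sum() * dt
    resp = np.zeros_like(t_fine)
    for b, onset in enumerate(p.block_onsets):
        box = ((t_fine >= onset) & (t_fine < onset + p.on_s)).astype(float)
        resp += habituation_rate**b * box
    resp = np.convolve(resp, h)[: t_fine.size] * dt / plateau
    frame_idx = np.round(np.arange(p.n_frames) * p.tr / dt).astype(int)
    return resp[np.minimum(frame_idx, t_fine.size - 1)]


def expected_window_response(
    p: StimulusParadigm,
    w: AnalysisWindows,
    params: HrfParams = CANONICAL_HRF,
    habituation_rate: float = 1.0,
    dt: float = 0.1,
) -> float:
    """Window-rule value of the noise-free unit-amplitude block response.

    This is the plateau correction factor for the ΔS/S window rule: because
    the on window covers the rising first half of each block, the windowed
    mean of a unit-plateau response is below 1 (≈0.833 for the default
    design and canonical parameters).  Dividing a measured windowed ΔS/S by
    this factor recovers the plateau amplitude.
    """
    r = block_response(p, params, dt=dt, habituation_rate=habituation_rate)
    return float(r[w.on_frames].mean() - r[w.off_frames].mean())
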