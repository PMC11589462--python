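"""Percent signal change (ΔS/S) per voxel and per ROI.

ΔS/S = 100 × (mean stimulus-on signal − mean stimulus-off signal) / mean
stimulus-off signal, evaluated over the window rule's frames (first half of
each odourant block vs second half of the preceding control period).  ΔS/S is
computed voxel-by-voxel first and then averaged over the selection — never as
a ratio of averaged signals.

Two voxel-selection schemes are supported: the subject's own (individual)
activation map, and the fixed combined control map.  Averaging over the
combined map includes voxels that may be inactive in a given subject, which
dilutes the group mean — this selection effect is the mechanism by which the
two schemes can report opposite group differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import AnalysisWindows
from .synthetic import PhantomAtlas, VolumeSeries

__all__ = ["DssRecord", "voxel_dss", "dss_volume", "roi_dss"]


@dataclass(frozen=True)
class DssRecord:
    subject_id: str
    roi: str
    scheme: str          # "individual" or "combined"
    dss: float           # percent; NaN when no voxels selected
    n_voxels_used: int


def voxel_dss(ts: np.ndarray, w: AnalysisWindows) -> float:
    """ΔS/S (%) of one voxel's time series under the window rule."""
    ts = np.asarray(ts, dtype=float)
    if w.on_frames.size == 0 or w.off_frames.size == 0:
        raise ValueError("analysis windows must be non-empty")
    if np.intersect1d(w.on_frames, w.off_frames).size:
        raise ValueError("analysis windows overlap")
    off_mean = ts[w.off_frames].mean()
    if abs(off_mean) < 1e-12:
        raise ValueError("stimulus-off mean is zero; ΔS/S undefined")
    return float(100.0 * (ts[w.on_frames].mean() - off_mean) / off_mean)


def dss_volume(series: VolumeSeries, w: AnalysisWindows) -> np.ndarray:
    """Voxel-wise ΔS/S (%) over the whole grid; NaN where the off mean is zero."""
    flat = series.data.reshape(-1, series.n_frames).astype(np.float64)
    on_mean = flat[:, w.on_frames].mean(axis=1)
    off_mean = flat[:, w.off_frames].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dss = 100.0 * (on_mean - off_mean) / off_mean
    dss[np.abs(off_mean) < 1e-12] = np.nan
    return dss.reshape(series.grid_dims)


def roi_dss(
    series: VolumeSeries,
    selection_mask: np.ndarray,
    atlas: PhantomAtlas,
    w: AnalysisWindows,
    scheme: str,
    subject_id: str = "subject",
) -> pd.DataFrame:
    """Mean voxel ΔS/S over ``selection_mask ∩ ROI`` for each of the 11 ROIs.

    Returns one row per ROI with columns subject_id, roi, scheme, n_voxels,
    dss_percent; ROIs with an empty intersection are flagged missing
    (``n_voxels = 0``, ``dss_percent = NaN``).
    """
    if scheme not in ("individual", "combined"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if selection_mask.shape != atlas.grid_dims or series.grid_dims != atlas.grid_dims:
        raise ValueError("series, selection mask and atlas must share one grid")
    dss = dss_volume(series, w)
    rows = []
    for rid, name in atlas.roi_names.items():
        sel = selection_mask & (atlas.labels == rid)
        n = int(sel.sum())
        value = float(np.nanmean(dss[sel])) if n else np.nan
        rows.append((subject_id, name, scheme, n, value))
    return pd.DataFrame(
        rows, columns=["subject_id", "roi", "scheme", "n_voxels", "dss_percent"]
    )
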