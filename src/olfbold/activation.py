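"""Voxel-wise non-parametric activation detection and activation maps.

Each in-brain voxel's stimulus-on samples are compared with its stimulus-off
samples by the two-sample Kolmogorov–Smirnov test; voxels with adjusted
p below the threshold form the subject's activation map.  "Adjusted" defaults
to no multiplicity adjustment (the permissive per-voxel regime of the
olfactory KS-test literature); Bonferroni and Benjamini–Hochberg adjustments
over in-brain voxels are available.  The combined control map is the union of
the individual control maps, used downstream as a fixed voxel-selection
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .paradigm import AnalysisWindows
from .synthetic import PhantomAtlas, VolumeSeries

__all__ = [
    "ActivationMap",
    "ks_two_sample",
    "detect_activation",
    "roi_active_counts",
    "combined_map",
]

EXACT_LIMIT = 10_000  # use the exact small-sample KS distribution when |a|*|b| <= this


@dataclass
class ActivationMap:
    """Per-voxel detection decisions (and p-values) for one subject.

    Combined maps carry ``pvals=None`` (union semantics have no single
    p-value per voxel) and ``subject_id="combined"``.
    """

    mask: np.ndarray
    pvals: np.ndarray | None
    threshold: float
    subject_id: str
    adjust: str = "none"


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic D and two-sided p-value.

    D is the supremum over x of |ECDF_a(x) − ECDF_b(x)|.  The p-value comes
    from the exact small-sample distribution when |a|·|b| <= 10^4 and from the
    asymptotic Kolmogorov distribution otherwise.  Two identical constant
    samples give (0, 1) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need at least 2 samples per group, got {a.size} and {b.size}")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    method = "exact" if a.size * b.size <= EXACT_LIMIT else "asymp"
    res = sp_stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def _ks_bulk(on: np.ndarray, off: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized KS over rows: ``on`` (V, n1) vs ``off`` (V, n2).

    D is evaluated over the pooled sorted sample of each row, stepping the
    two ECDFs and reading the gap only after each run of tied values; p uses
    the asymptotic formula (Kolmogorov distribution of D at the effective
    sample size), matching the large-sample branch of ``ks_two_sample``.
    """
    n1, n2 = on.shape[1], off.shape[1]
    vals = np.concatenate([on, off], axis=1)
    labels = np.zeros(n1 + n2, dtype=bool)
    labels[:n1] = True
    order = np.argsort(vals, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=1)
    is_on_sorted = labels[order]
    cum_on = np.cumsum(is_on_sorted, axis=1)
    pos = np.arange(1, n1 + n2 + 1)[None, :]
    gap = np.abs(cum_on / n1 - (pos - cum_on) / n2)
    # only evaluate at the last element of each run of tied values
    valid = np.ones_like(gap, dtype=bool)
    valid[:, :-1] = sorted_vals[:, 1:] != sorted_vals[:, :-1]
    d = np.where(valid, gap, 0.0).max(axis=1)

    en = n1 * n2 / (n1 + n2)
    # D takes at most a few hundred distinct lattice values; evaluate the
    # survival function once per distinct value
    uniq, inverse = np.unique(d, return_inverse=True)
    p = sp_stats.distributions.kstwo.sf(uniq, int(round(en)))[inverse]
    # zero-variance rows (both samples one constant) are defined as p = 1
    const = np.ptp(vals, axis=1) == 0
    d[const] = 0.0
    p[const] = 1.0
    return d, np.clip(p, 0.0, 1.0)


def detect_activation(
    series: VolumeSeries,
    windows: AnalysisWindows,
    threshold: float = 0.01,
    brain_mask: np.ndarray | None = None,
    adjust: str = "none",
    subject_id: str = "subject",
) -> ActivationMap:
    """KS-test every in-brain voxel's on samples against its off samples.

    ``adjust`` ∈ {"none", "bonferroni", "bh"} is applied over in-brain voxels
    before thresholding.  Windows must be disjoint.
    """
    if np.intersect1d(windows.ks_on_frames, windows.ks_off_frames).size:
        raise ValueError("detection windows overlap")
    if adjust not in ("none", "bonferroni", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    grid = series.grid_dims
    if brain_mask is None:
        brain_mask = np.ones(grid, dtype=bool)
    if brain_mask.shape != grid:
        raise ValueError("brain_mask grid does not match series grid")

    flat = series.data.reshape(-1, series.n_frames).astype(np.float64)
    in_brain = brain_mask.ravel()
    on = flat[in_brain][:, windows.ks_on_frames]
    off = flat[in_brain][:, windows.ks_off_frames]
    n1, n2 = on.shape[1], off.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("detection windows must contain at least 2 frames each")

    if n1 * n2 <= EXACT_LIMIT:
        pv = np.array([ks_two_sample(on[i], off[i])[1] for i in range(on.shape[0])])
    else:
        _, pv = _ks_bulk(on, off)

    if adjust == "bonferroni":
        p_adj = np.minimum(pv * pv.size, 1.0)
    elif adjust == "bh":
        p_adj = multipletests(pv, method="fdr_bh")[1]
    else:
        p_adj = pv

    pvals = np.full(flat.shape[0], np.nan)
    pvals[in_brain] = pv
    mask = np.zeros(flat.shape[0], dtype=bool)
    mask[in_brain] = p_adj < threshold
    return ActivationMap(
        mask=mask.reshape(grid),
        pvals=pvals.reshape(grid),
        threshold=float(threshold),
        subject_id=subject_id,
        adjust=adjust,
    )


def roi_active_counts(amap: ActivationMap, atlas: PhantomAtlas) -> pd.Series:
    """Activated-voxel count per ROI (all 11 ROIs reported, zeros included)."""
    if amap.mask.shape != atlas.grid_dims:
        raise ValueError(
            f"activation map grid {amap.mask.shape} does not match atlas grid {atlas.grid_dims}"
        )
    counts = {
        name: int((amap.mask & (atlas.labels == rid)).sum())
        for rid, name in atlas.roi_names.items()
    }
    return pd.Series(counts, name="n_active")


def combined_map(control_maps: list[ActivationMap]) -> ActivationMap:
    """Union of the individual control maps (a voxel is included if it was
    significantly activated in at least one control subject)."""
    if not control_maps:
        raise ValueError("need at least one control activation map")
    shape = control_maps[0].mask.shape
    union = np.zeros(shape, dtype=bool)
    for m in control_maps:
        if m.mask.shape != shape:
            raise ValueError("control maps are not on a common grid")
        union |= m.mask
    return ActivationMap(
        mask=union,
        pvals=None,
        threshold=control_maps[0].threshold,
        subject_id="combined",
        adjust=control_maps[0].adjust,
    )
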