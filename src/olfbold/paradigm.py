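"""Block-design olfactory stimulation paradigm and derived analysis windows.

The stimulation design is a single baseline period of odourless control
(mineral oil) followed by ``n_blocks`` repetitions of an odourant-on period
(phenyl ethyl alcohol, PEA) interleaved with a control period.  Everything
downstream — frame labelling, the ΔS/S averaging windows and the detection
windows for the voxel-wise two-sample test — is derived from this object.

Frame indexing is 0-based; frame ``i`` covers the half-open interval
``[i*tr, (i+1)*tr)`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StimulusParadigm",
    "AnalysisWindows",
    "build_paradigm",
    "frame_labels",
    "analysis_windows",
    "boxcar_regressor",
]


@dataclass(frozen=True)
class StimulusParadigm:
    """Timing of a block-design olfactory stimulation run.

    Parameters
    ----------
    tr : float
        Repetition time (seconds per frame).
    baseline_s : float
        Initial odourless control period, seconds.
    n_blocks : int
        Number of odourant-on blocks.
    on_s : float
        Duration of each odourant-on (PEA) period, seconds.
    off_s : float
        Duration of the odourless control period following each block, seconds.
    trailing_s : float
        Extra odourless time appended after the last block (0 by default);
        analysis windows never depend on it.
    """

    tr: float
    baseline_s: float
    n_blocks: int
    on_s: float
    off_s: float
    trailing_s: float = 0.0

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.n_blocks * (self.on_s + self.off_s) + self.trailing_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_s / self.tr))

    @property
    def block_onsets(self) -> np.ndarray:
        """Onset times (s) of each odourant-on block."""
        return self.baseline_s + np.arange(self.n_blocks) * (self.on_s + self.off_s)

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table with columns onset, duration, trial_type."""
        rows = [(0.0, self.baseline_s, "mineral_oil")]
        for onset in self.block_onsets:
            rows.append((float(onset), self.on_s, "PEA"))
            rows.append((float(onset + self.on_s), self.off_s, "mineral_oil"))
        if self.trailing_s > 0:
            rows.append((self.total_s - self.trailing_s, self.trailing_s, "mineral_oil"))
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "tr": float(self.tr),
                "baseline_s": float(self.baseline_s),
                "n_blocks": int(self.n_blocks),
                "on_s": float(self.on_s),
                "off_s": float(self.off_s),
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "StimulusParadigm":
        d = yaml.safe_load(text)
        return build_paradigm(d["tr"], d["baseline_s"], d["n_blocks"], d["on_s"], d["off_s"])


@dataclass(frozen=True)
class AnalysisWindows:
    """Frame-index sets used for quantification and detection.

    ``on_frames`` / ``off_frames`` feed the ΔS/S window rule (first half of
    each odourant block vs second half of the preceding control period, no
    haemodynamic shift).  ``ks_on_frames`` / ``ks_off_frames`` feed the
    voxel-wise two-sample test (all on vs all off frames, both shifted
    forward by the haemodynamic lag).
    """

    on_frames: np.ndarray
    off_frames: np.ndarray
    ks_on_frames: np.ndarray
    ks_off_frames: np.ndarray


def _check_divisible(name: str, value: float, tr: float) -> None:
    k = value / tr
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"{name}={value} is not an integer multiple of tr={tr}")


def build_paradigm(
    tr: float,
    baseline: float,
    n_blocks: int,
    on: float,
    off: float,
) -> StimulusParadigm:
    """Construct and validate a block-design paradigm.

    All durations must be positive integer multiples of ``tr``; a violation is
    rejected with a message naming the offending field.
    """
    if tr <= 0:
        raise ValueError(f"tr={tr} must be positive")
    if n_blocks < 0:
        raise ValueError(f"n_blocks={n_blocks} must be non-negative")
    for name, value in [("baseline", baseline), ("on", on), ("off", off)]:
        if value <= 0:
            raise ValueError(f"{name}={value} must be positive")
        _check_divisible(name, value, tr)
    return StimulusParadigm(tr=float(tr), baseline_s=float(baseline),
                            n_blocks=int(n_blocks), on_s=float(on), off_s=float(off))


def frame_labels(p: StimulusParadigm) -> np.ndarray:
    """Boolean frame labels, True where the frame lies in an odourant-on period."""
    t = np.arange(p.n_frames) * p.tr
    on = np.zeros(p.n_frames, dtype=bool)
    for onset in p.block_onsets:
        on |= (t >= onset) & (t < onset + p.on_s)
    return on


def analysis_windows(
    p: StimulusParadigm,
    lag_s: float = 6.0,
    baseline_pairing: str = "preceding",
) -> AnalysisWindows:
    """Derive ΔS/S and detection frame windows from a paradigm.

    ΔS/S windows follow the verbatim window rule: the first half of each
    odourant-on period against the second half of the odourless period paired
    with that block.  With ``baseline_pairing="preceding"`` (default) each
    block is paired with the control period immediately before it (for block 1
    that is the initial baseline); ``"following"`` pairs each block with the
    control period after it.

    Detection windows are all on frames vs all off frames after shifting the
    on/off labelling forward by ``lag_s`` seconds (approximate haemodynamic
    lag); frames whose shifted time falls before the paradigm start count as
    off.
    """
    if baseline_pairing not in ("preceding", "following"):
        raise ValueError(f"unknown baseline_pairing {baseline_pairing!r}")
    tr = p.tr
    n = p.n_frames
    half_on = int(round(p.on_s / (2 * tr)))

    on_idx: list[np.ndarray] = []
    off_idx: list[np.ndarray] = []
    for onset in p.block_onsets:
        i0 = int(round(onset / tr))
        on_idx.append(np.arange(i0, i0 + half_on))
        if baseline_pairing == "preceding":
            # second half of the control period ending at this block's onset
            prev_len = p.baseline_s if onset == p.block_onsets[0] else p.off_s
            j0 = int(round((onset - prev_len / 2) / tr))
            off_idx.append(np.arange(j0, i0))
        else:
            # second half of the control period after this block
            k0 = int(round((onset + p.on_s + p.off_s / 2) / tr))
            k1 = int(round((onset + p.on_s + p.off_s) / tr))
            off_idx.append(np.arange(k0, k1))

    on_frames = np.concatenate(on_idx) if on_idx else np.empty(0, dtype=int)
    off_frames = np.concatenate(off_idx) if off_idx else np.empty(0, dtype=int)

    t_shifted = np.arange(n) * tr - lag_s
    ks_on = np.zeros(n, dtype=bool)
    for onset in p.block_onsets:
        ks_on |= (t_shifted >= onset) & (t_shifted < onset + p.on_s)
    ks_on_frames = np.flatnonzero(ks_on)
    ks_off_frames = np.flatnonzero(~ks_on)

    w = AnalysisWindows(on_frames, off_frames, ks_on_frames, ks_off_frames)
    _validate_windows(w, n)
    return w


def _validate_windows(w: AnalysisWindows, n_frames: int) -> None:
    for name, arr in [("on_frames", w.on_frames), ("off_frames", w.off_frames),
                      ("ks_on_frames", w.ks_on_frames), ("ks_off_frames", w.ks_off_frames)]:
        if arr.size and (arr.min() < 0 or arr.max() >= n_frames):
            raise ValueError(f"{name} contains indices outside [0, {n_frames})")
    if np.intersect1d(w.on_frames, w.off_frames).size:
        raise ValueError("on_frames and off_frames overlap")
    if np.intersect1d(w.ks_on_frames, w.ks_off_frames).size:
        raise ValueError("ks_on_frames and ks_off_frames overlap")


def boxcar_regressor(p: StimulusParadigm, dt: float) -> np.ndarray:
    """Unit-amplitude indicator of odourant-on periods sampled every ``dt`` s.

    ``dt`` must divide ``tr``.
    """
    k = p.tr / dt
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"dt={dt} does not divide tr={p.tr}")
    n = int(round(p.total_s / dt))
    t = np.arange(n) * dt
    box = np.zeros(n)
    for onset in p.block_onsets:
        box[(t >= onset) & (t < onset + p.on_s)] = 1.0
    return box
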