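"""The voxel-selection dilution effect on ΔS/S.

A 'patient-like' subject is active in only 30% of each ROI but with a large
amplitude.  Averaging ΔS/S over the subject's own active voxels vs over a
map covering the whole ROI (a stand-in for the combined control map) gives
systematically different — here opposite-ordered — values.
"""

import dataclasses

from olfbold import analysis_windows, build_paradigm, make_atlas, roi_dss
from olfbold.synthetic import default_config, simulate_subject

paradigm = build_paradigm(2, 60, 3, 60, 120)
windows = analysis_windows(paradigm)
atlas = make_atlas()

cfg = default_config(seed=2)
gp = dataclasses.replace(cfg.groups["PD"], active_fraction=0.3, amplitude_mean=1.6)
cfg = dataclasses.replace(cfg, groups={"PD": gp, "HC": cfg.groups["HC"]})
series, truth, _ = simulate_subject(cfg, atlas, paradigm, group="PD", seed=7)

own = roi_dss(series, truth.mask, atlas, windows, "individual")
full = roi_dss(series, atlas.labels > 0, atlas, windows, "combined")
merged = own.merge(full, on="roi", suffixes=("_own", "_full"))
print(f"{'ROI':24s} {'ΔS/S own map':>13s} {'ΔS/S full ROI':>14s}")
for _, r in merged.iterrows():
    print(f"{r.roi:24s} {r.dss_percent_own:13.3f} {r.dss_percent_full:14.3f}")

ratio = merged.dss_percent_full.mean() / merged.dss_percent_own.mean()
print(f"\nmean dilution factor {ratio:.2f} (≈ active fraction: inactive voxels"
      " contribute ≈ 0 and drag the full-ROI mean down)")
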