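"""Build the olfactory block design and inspect its analysis windows.

The design: 60 s odourless baseline, then three blocks of 60 s odourant
interleaved with 120 s odourless control, sampled every 2 s (300 frames).
"""

from olfbold import analysis_windows, build_paradigm, frame_labels

p = build_paradigm(tr=2, baseline=60, n_blocks=3, on=60, off=120)
labels = frame_labels(p)
w = analysis_windows(p)  # default 6-s haemodynamic lag for detection windows

print(f"total duration      {p.total_s:.0f} s ({p.n_frames} frames)")
print(f"odour-on frames     {labels.sum()} of {p.n_frames}")
print(f"ΔS/S on-window      {w.on_frames.size} frames (first half of each block)")
print(f"ΔS/S off-window     {w.off_frames.size} frames (second half of preceding control)")
print(f"detection windows   {w.ks_on_frames.size} on vs {w.ks_off_frames.size} off (lag-shifted)")
print()
print("events table (BIDS style):")
print(p.to_events().to_string(index=False))

# The on/off window counts are what the ΔS/S window rule averages over; the
# detection windows feed the voxel-wise KS test.
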