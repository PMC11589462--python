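"""Estimate the haemodynamic response and its shape metrics.

Fits the canonical double gamma plus temporal and dispersion derivatives to
a noisy ROI-averaged time course generated with a narrower-than-canonical
impulse response, and reads FWHM and time to peak off the reconstruction.
"""

import numpy as np

from olfbold import build_paradigm, fit_hrf, hrf_basis, hrf_fwhm, hrf_ttp
from olfbold.hrf import CANONICAL_HRF, HrfParams, block_response

paradigm = build_paradigm(2, 60, 3, 60, 120)
basis = hrf_basis(paradigm)

truth = HrfParams(peak_delay=5.8, dispersion=0.8)   # narrower, same mode
t = np.arange(0, 32, 0.01)
print(f"truth:     FWHM {hrf_fwhm(truth.sample(t), 0.01):.2f} s, "
      f"TTP {hrf_ttp(truth.sample(t), 0.01):.2f} s")
print(f"canonical: FWHM {hrf_fwhm(CANONICAL_HRF.sample(t), 0.01):.2f} s, "
      f"TTP {hrf_ttp(CANONICAL_HRF.sample(t), 0.01):.2f} s")

rng = np.random.default_rng(3)
r = block_response(paradigm, truth, habituation_rate=1.0)
voxels = 1000 * (1 + 0.01 * r) + 5.0 * rng.standard_normal((30, paradigm.n_frames))
est = fit_hrf(voxels.mean(axis=0), basis)
print(f"estimate:  FWHM {est.fwhm:.2f} s, TTP {est.ttp:.2f} s  (R² {est.fit_r2:.3f})")

# The flexible basis recovers the narrower width from a 1%-amplitude block
# response with 0.5% per-voxel noise averaged over 30 voxels.
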