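# olfbold

Quantification of block-design olfactory BOLD fMRI, with a synthetic cohort
generator.

Olfactory dysfunction is an early sign of Parkinson's disease, and olfactory
fMRI studies of patients vs controls have reported confusingly opposite
signal changes in the same brain regions. A key reason is *voxel selection*:
whether the percent signal change (ΔS/S) is averaged over each subject's own
activated voxels or over a fixed map of control-activated voxels changes the
sign of the group difference whenever patients activate fewer voxels more
strongly. `olfbold` implements the full quantification chain needed to study
this, end to end:

- **Paradigm** — a baseline + repeated odour-on/odour-off block design
  (default: 60 s + 3 × (60 s PEA / 120 s mineral oil), TR = 2 s, 300 frames)
  with the derived analysis windows: ΔS/S compares the first half of each
  odour block against the second half of the preceding odourless period,
  `ΔS/S = 100 × (S_on − S_off)/S_off` (%).
- **Preprocessing** — 4-mm isotropic Gaussian smoothing, a 1/180 Hz
  running-line high-pass (drift removal) and a 0.03 Hz zero-phase
  Butterworth low-pass.
- **Detection** — a voxel-wise two-sample Kolmogorov–Smirnov test of on vs
  off samples (`D = sup_x |ECDF_on(x) − ECDF_off(x)|`), adjusted p < 0.01,
  per-ROI activated-voxel counts, and the combined control map (union of
  control subjects' maps).
- **HRF shape metrics** — least-squares fit of the canonical double gamma
  plus temporal and dispersion derivatives to the ROI-averaged activated
  time course; full width at half maximum (FWHM) and time to peak (TTP) of
  the reconstructed impulse response, in seconds.
- **Group statistics** — per-ROI OLS group comparison adjusted for age and
  ROI volume, Cohen's d, partial correlation with the UPSIT smell-test
  score, relative change `100 × (mean_PD − mean_HC)/mean_HC`, and
  Benjamini–Hochberg FDR control across the 11 olfactory ROIs.
- **Synthetic data** — an 11-ROI phantom atlas (olfactory bulb through the
  cingulate cortices) and 4D cohorts with group-dependent activation
  extent, amplitude, HRF width, habituation, drift, physiological and
  low-frequency noise.

See `docs/methods.md` for the models, defaults and design rationale.

## Worked example

```python
import dataclasses
from olfbold import (RunConfig, analyze_cohort, default_config, make_atlas,
                     simulate_cohort)
from olfbold.preprocess import PreprocessConfig

sim = dataclasses.replace(default_config(seed=31), n_subjects={"PD": 8, "HC": 8})
atlas = make_atlas()                       # 24 x 24 x 12 phantom, 11 ROIs
cohort = simulate_cohort(sim, atlas, RunConfig().paradigm)
res = analyze_cohort(cohort, RunConfig(simulation=sim,
                                       preprocess=PreprocessConfig(do_smooth=False)))
for measure in ("n_active", "dss_individual", "dss_combined", "fwhm"):
    t = res.group_tables[measure]
    print(f"{measure:16s} PD {t.mean_pd.mean():7.3f}  HC {t.mean_hc.mean():7.3f}")
```

prints (seed 31):

```
n_active          PD  70.239  HC 135.114
dss_individual    PD   0.827  HC   0.507
dss_combined      PD   0.315  HC   0.370
fwhm              PD   4.838  HC   5.363
```

Reading: patients activate about half as many voxels (70 vs 135 per ROI on
average), yet their ΔS/S averaged over their *own* activation maps is
*higher* (0.83 % vs 0.51 %) — the surviving voxels respond more strongly.
Averaged over the fixed combined control map the ordering *reverses*
(0.32 % vs 0.37 %), because the map contains voxels that are silent in
patients and dilute their mean. The patients' haemodynamic response is also
narrower (FWHM 4.8 s vs 5.4 s), the faster-habituation signature.

## Command line

```bash
olfbold simulate --seed 1 --out data/            # write a synthetic dataset
olfbold analyze  --seed 1 --data data/ --out results/
olfbold report   --results results/              # print the group tables
```

`analyze` accepts `--threshold`, `--adjust {none,bonferroni,bh}` and a YAML
`--config`; every run writes a manifest with checksums, the configuration
hash and the seed. `examples/` contains short narrative scripts, one per
capability.

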