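# Methods

`olfbold` quantifies block-design olfactory BOLD fMRI runs and ships a
synthetic cohort generator that emulates the statistical structure such
studies assume. This note describes the models, the defaults and the reasons
behind the design choices that were genuinely open.

## Stimulation design and analysis windows

The design is a 60-s odourless (mineral oil) baseline followed by three
blocks of 60 s odourant (phenyl ethyl alcohol, PEA) interleaved with 120 s of
odourless control; at TR = 2 s that is 300 frames over 10 minutes. Frames are
0-based and frame *i* covers `[i·TR, (i+1)·TR)`.

Two window sets are derived from the design:

- **ΔS/S windows** — the first half of each odourant block against the
  second half of the odourless period *preceding* that block (for block 1,
  the last 30 s of the initial baseline). No haemodynamic shift is applied;
  the window rule is kept verbatim. Pairing each block with the preceding
  rather than the following control period avoids contaminating the baseline
  with the post-stimulus undershoot; the following-period alternative is
  selectable (`baseline_pairing="following"`).
- **Detection windows** — all odour-on frames against all off frames, both
  shifted forward by a configurable haemodynamic lag (default 6 s ≈ the
  canonical time to peak). The shift exists only for the detection test;
  ΔS/S windows are never shifted.

## Haemodynamic response model

The impulse response is the canonical double gamma: a gamma density with
shape `peak_delay/dispersion` and scale `dispersion` minus `ratio` times a
second (undershoot) gamma, peak-normalized. Defaults (6, 16, 1, 1, 1/6)
give time to peak 5.0 s and FWHM 5.26 s. Block responses are the boxcar
convolution rescaled to unit sustained plateau, so a simulated amplitude
`a` is the plateau ΔS/S in percent.

**Window factor (plateau correction).** Because the ΔS/S on-window covers
the *rising* first half of each block, the window rule applied to a
unit-plateau response yields ≈ 0.835, not 1 (`expected_window_response`
computes it for any design/HRF/habituation). Amplitude-recovery checks
divide the measured windowed ΔS/S by this factor; pipeline outputs report
the raw (uncorrected) windowed value, which is what the method defines.

## Synthetic data

The phantom atlas packs 11 disjoint box ROIs (olfactory bulb, piriform
cortex, orbitofrontal cortex, temporal pole, insula, amygdala, hippocampus,
parahippocampus, anterior/middle/posterior cingulate) into a 24×24×12 grid
of 1.5-mm voxels. The olfactory bulb is deliberately the smallest label
(32 voxels); the others span 100–384, mimicking the scale gap between the
bulb and cortical regions while staying desk-sized. Real ROIs are 1–2
orders of magnitude larger; consequences are discussed under *Smoothing and
phantom scale*.

Per subject, each ROI's truly active voxels form a **compact blob** — the
`k = active_fraction × ROI size` nearest voxels around a random seed voxel —
rather than a random scatter, because activation is spatially clustered in
real data and a salt-and-pepper truth would be erased by any spatial
smoothing. Active voxels carry
`S0·(1 + a_voxel/100 · r(t))`, where `r` is the unit-plateau block response
under the group's HRF, with per-block geometric amplitude decay
(`habituation_rate^(block−1)`) modelling olfactory habituation with one
parameter.

Nuisance terms (all voxels): linear drift (default 0.5 %/min, random sign
and per-subject scale), sinusoidal respiratory/cardiac components (0.3 and
1.1 Hz at 0.1 %, deliberately aliased by the 2-s TR to 0.2/0.1 Hz so the
low-pass stage is exercised), white thermal noise (0.5 %), and
**band-limited spontaneous low-frequency fluctuations** (0.3 % below
0.05 Hz). The last term matters: after the mandated 0.03 Hz low-pass the
other terms leave essentially zero in-band variance, detection then
saturates on arbitrarily small numerical leakage, and no parameter setting
recovers realistic behaviour. Spontaneous 0.01–0.1 Hz fluctuations are the
dominant residual of temporally filtered BOLD data, so they are part of the
noise model, not an optional extra.

Default group conditions (22 patients vs 24 controls): patients have a
smaller active extent (0.30 vs 0.70 of each ROI) but twice the amplitude
(1.6 % vs 0.8 %) in surviving voxels, a narrower impulse response with
unchanged mode (dispersion 0.8, peak delay 5.8 → time to peak 5.0 s in both
groups, FWHM 4.7 vs 5.3 s), stronger habituation (0.75 vs 0.9), and are
older (ages ~N(65, 8) vs ~N(45, 8)) to exercise covariate adjustment. The
odour-identification (UPSIT) score is a linear link — rising in active
extent, falling in amplitude — plus Gaussian noise, clipped to [0, 40],
giving group means near 19 vs 29. Note the amplitude × extent product is
*below* the control value (0.3·2 = 0.6 per unit); that inequality, not any
single parameter, is what makes the combined-map ΔS/S fall in patients
while individual-map ΔS/S rises. With spatially uniform within-subject
amplitudes a generator cannot simultaneously match a mild extent reduction
and a combined-map decrease; real data reconcile the two through
within-subject amplitude heterogeneity and selection effects the phantom
does not model.

What the phantom does **not** emulate: susceptibility artefacts, motion,
registration error, anatomically realistic ROI shapes, within-subject
amplitude gradients, or non-Gaussian physiological noise. Passing tests
therefore demonstrate correctness of the computations and the selection
mechanisms, not performance on acquired scans.

## Preprocessing

Order is fixed: spatial smoothing → high-pass → low-pass. Motion
correction, registration and ICA denoising are explicit no-op stages
(phantoms have no motion or registration problem).

- **Smoothing**: isotropic Gaussian, FWHM 4 mm (FWHM, not σ — the
  neuroimaging convention), converted to voxels via the voxel size; reflect
  padding. FWHM 0 is the identity.
- **High-pass (1/180 Hz)**: a Gaussian-weighted running-line detrend
  (σ = 1/(2·cutoff) = 90 s), i.e. at each time point a weighted local
  straight-line fit is subtracted and the series mean restored. A sharp IIR
  high-pass is the wrong tool here: the task fundamental (one cycle per
  180 s) sits *exactly at* the cutoff, and an order-4 zero-phase Butterworth
  would cut the windowed on–off contrast by ~30 %. The running line removes
  constant and linear drift to machine precision while passing the task
  fundamental with gain ≈ 0.99. The output mean is re-centred to the input
  mean so ΔS/S denominators stay meaningful.
- **Low-pass (0.03 Hz)**: order-4 zero-phase Butterworth (no phase
  distortion of timing metrics). The block response's first harmonics
  (1/180, 1/90, 1/60 Hz) pass essentially unattenuated; the aliased
  physiological components (0.1–0.2 Hz) are suppressed > 10×.

A per-run provenance log records stage order, parameters and a config hash.

## Activation detection

Each in-brain voxel's detection-window on samples are compared with its off
samples by the two-sample Kolmogorov–Smirnov test (D = sup ECDF difference,
pooled-sample evaluation with standard tie handling). The p-value uses the
exact small-sample distribution when `n·m ≤ 10⁴` and the asymptotic
Kolmogorov distribution otherwise; voxel-wise batches share one vectorized
ECDF pass. Two identical constant samples give p = 1, never NaN.

**Adjustment.** On raw white noise the voxel-wise test is calibrated
(false-positive rate ≈ 0.9 % at p < 0.01, slightly conservative because the
discrete D lattice). Inside the full pipeline, however, the 0.03 Hz
low-pass leaves ~36 effective degrees of freedom per series; the KS test
assumes exchangeable samples and becomes grossly anticonservative on such
smooth noise (60–85 % of null voxels below unadjusted p < 0.01). The
pipeline therefore defaults to a **Bonferroni-adjusted p < 0.01** over
in-brain voxels: true block responses sit orders of magnitude below the
adjusted threshold while the measured maps track the true active extent.
`adjust ∈ {none, bonferroni, bh}` is exposed everywhere.

The **combined control map** is the union of the control subjects'
individual maps — not a second-level test. Union semantics match the
observation that combined-map sizes exceed per-subject control map sizes.

## ΔS/S

`100 × (mean over on frames − mean over off frames)/(mean over off frames)`
per voxel, then averaged across the selected voxels (never a ratio of
averaged signals). Two selection schemes: the subject's own activation map
(`individual`) and the fixed combined control map (`combined`). Averaging a
subject over combined-map voxels that are inactive in that subject dilutes
the mean by exactly `n/(n+k)` for `k` zero-amplitude voxels — the mechanism
by which the two schemes can report *opposite* group differences. ROIs with
an empty selection are reported missing (`NA`), not zero.

## HRF estimation

The ROI-averaged time course of the subject's *individual-map* voxels is fit
by least squares with the canonical double gamma plus its temporal and
dispersion derivatives (each convolved with the stimulation boxcar on a
0.1-s grid and read out at frame times), plus an intercept. A one-basis
(canonical only) mode exists, but per-subject width variation requires the
flexible fit. The impulse response is reconstructed from the fitted weights
on the fine grid and the shape metrics are read off the reconstruction:

- **TTP** — time of the global maximum with parabolic sub-sample
  refinement; missing if the peak is non-positive or on the grid boundary.
- **FWHM** — width between the half-maximum up-crossing before the peak and
  the first down-crossing after it, linearly interpolated; missing (with
  the side recorded) if a crossing does not exist.

Metrics are computed on the impulse-response reconstruction, not on the
60-s block response, which is why they live on the few-seconds scale of a
single haemodynamic event. They are invariant to amplitude scaling and
baseline shifts.

Two numerical points discovered during development and built into the
pipeline: (i) the design matrix is passed through the same temporal filter
as the data — fitting filtered data against an unfiltered design pushes the
filters' shape distortion into the derivative weights; (ii) the fit uses
the **high-passed (pre-low-pass)** series. A zero-phase low-pass adds no
information to a model-based least-squares fit; applied before the fit it
concentrates the noise into the very band that separates the basis
functions, inflating the derivative-weight variance and producing an
amplitude-dependent downward bias of FWHM (≈ −0.7 s at 0.8 % amplitude)
large enough to flip a group contrast. On high-passed data the fit is
unbiased (recovered 5.28 s vs truth 5.26 s noise-free).

## Group statistics

Per ROI and measure (activated-voxel count, ΔS/S under both schemes, FWHM,
TTP): group means ± standard error (sd/√n), relative change
`100 × (mean_PD − mean_HC)/mean_HC` computed from **unrounded** means, a
two-sided p for the group term of an OLS model with age and the subject's
structural ROI volume as covariates, Cohen's d on the raw (unadjusted)
values with pooled n−1 standard deviation, and the partial correlation of
the measure with the UPSIT score given the same covariates (a zero-order
switch exists, since summaries in this literature do not always say which
is tabulated). P-values are Benjamini–Hochberg corrected across the 11 ROIs
within each measure at α = 0.05; missing tests neither count toward m nor
get flagged. Constant covariate columns are dropped (the model then reduces
exactly to the two-sample t-test); genuinely collinear columns raise an
error naming the offending column.

Report rounding: voxel counts to integers, ΔS/S and FWHM/TTP to 2 decimals,
relative change to 1 decimal for counts and to integers for ΔS/S and HRF
metrics. Because relative changes are computed from unrounded means, a
summary recomputed from *rounded* means can disagree in the last printed
digit.

## Smoothing and phantom scale

At acquisition scale a 4-mm kernel is small relative to ROIs of 10³–10⁴
voxels; on the 24×24×12 phantom it spans roughly half an ROI box, so
smoothing leaks signal across entire ROIs and genuinely activates every
in-ROI voxel — the extent structure the selection analyses study is
physically erased, and active-voxel amplitudes acquire a partial-volume
dilution (measured ≈ −0.24 pp on compact blobs). The scale-faithful
correspondence on the phantom is therefore to run the *selection and
recovery experiments* with temporal preprocessing only, while smoothing
remains in the default pipeline configuration. The amplitude-recovery
experiments follow the same logic: the noise-free recovery uses the raw
window rule; the noisy cohort recovery applies high-pass + low-pass.

## Validation experiment sizes

Chosen once as desk-scale problem sizes: null calibration on 12,672
white-noise voxels; detection power on one subject at 2 % amplitude and
0.5 % noise (~2,000 active voxels); ΔS/S cohort recovery over 24 control
subjects; HRF recovery over 50 ROI-level fits (alternating control/patient
impulse responses, 30 voxels averaged per fit) at 1 % amplitude and 0.5 %
noise; the voxel-selection sign reversal over 20 replicates of 6 + 6
subjects with patients at 40 % of control extent and 2× amplitude. The
reversal counts a replicate as reproducing the phenomenon when the grand
mean (subjects × ROIs) individual-map ΔS/S is higher in patients *and* the
combined-map ΔS/S is lower.

## Known limitations

- KS detection after heavy low-pass filtering is anticonservative by
  construction; the Bonferroni default is a pragmatic guard, not an exact
  error-rate control, and cluster/random-field inference is out of scope.
- The phantom's box ROIs and uniform within-subject amplitudes are
  idealized; absolute FWHM/TTP values are comparable in scale, not
  bit-comparable, to values from acquired data, and relative changes larger
  in magnitude than real extent reductions are needed to realize the
  combined-map sign behaviour (see above).
- The exact filter family, KS p adjustment and HRF-toolbox basis used by
  any given acquisition pipeline are rarely published; all three are
  configuration here, with defaults as argued above.
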