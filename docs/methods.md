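# Methods

`ramanprep` implements a self-supervised preprocessing scheme for Raman
spectra: a training-data factory that manufactures labeled
(reference, ideal) spectrum pairs, a two-branch convolutional
encoder–decoder trained on those pairs to perform joint denoising and
baseline correction, the two classical comparators it is benchmarked
against, an evaluation metric suite, and per-pixel tooling for
hyperspectral cubes.  This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The problem

A measured Raman spectrum is modeled as

    x(ν) = y(ν) + α·n(ν) + β·b(ν)

where `y` is the ideal spectrum (Raman peaks only), `n` is zero-baseline
noise (detector and shot noise, cosmic-ray texture), and `b` is a smooth
baseline (residual Rayleigh scattering and autofluorescence).
Preprocessing is the inverse problem: recover `y` from `x`.  Supervised
learning needs (x, y) pairs, but ideal spectra cannot be measured — the
package therefore synthesizes them.

## Training-data factory

**Decomposition** (`ramanprep.decompose`).  Source spectra are split by a
multilevel discrete wavelet transform (db8, 8 levels — the same setting
as the wavelet comparator; the split is pure level assignment without
intra-level thresholding): details d1–d2 are assigned to noise, d3–d6 to
signal, d7–d8 plus the approximation to baseline.  The reconstruction
residual is folded into the noise component so the three parts sum to the
input exactly (machine precision; enforced).  We use the `smooth`
(linear-extrapolation) boundary extension: with `symmetric` extension an
8-level db8 transform of a 1024-point record leaks several percent of a
smooth polynomial baseline into the signal band at the edges; with
`smooth` the leak is ~0.01%.  Individual peaks are then cut from the
signal component by a first-difference method: apexes where the first
difference changes + to −, boundaries at the nearest sign change or
sub-threshold point, profile = segment minus its linear chord,
floor-clipped at 0.  Fragments narrower than 3 points or with prominence
below 2% of the signal maximum are discarded (both configurable).

**Recombination** (`ramanprep.synthesis`).  Ideal spectra are assembled
from k ~ Uniform{5..20} fragments drawn with replacement, each placed at
a uniformly random start (fragments keep their shape, not their original
wavenumber — position randomization maximizes diversity and every
placement is recorded in a manifest), amplitude-jittered by
Uniform(0.5, 1.5), and summed; overlaps superpose additively.  References
add one pooled noise vector (scaled to unit SD) and one pooled baseline
(unit max), with α set by a target spectral SNR and β expressed in
multiples of the tallest peak.

**Severity regimes.**  Powers are grid mean squares throughout, so the
realized SNR equals the target by construction:
`α = sqrt(P_signal / (P_noise · 10^(SNR/10)))`, supported range −10…60 dB.

| preset               | target SNR (dB) | baseline amplitude (× max peak) |
|----------------------|-----------------|---------------------------------|
| `default`            | U(5, 40)        | U(0, 5)                         |
| `baseline_dominated` | U(10, 30)       | U(1, 5)                         |

`baseline_dominated` is the regime used in the preprocessing trial:
baselines dwarfing the peaks with moderate noise, the situation in which
baseline-correction quality dominates the error.

**Mathematical simulation** (ablation control).  `generate_mathsim_pair`
builds ideal spectra from Lorentzian peaks (random center; FWHM
U(5, 50) cm⁻¹; amplitude U(0.2, 1.0)), i.i.d. Gaussian white noise, and a
monotone-cubic baseline through 4–8 random control points — the classical
simulation recipe, kept as a first-class generator so recombination-vs-
mathsim training can be compared under identical severity.

**Source-to-pair ratio.**  Pools are built from one source spectrum per
ten synthesized pairs (the factory's design ratio); the default trial at
2,000 + 100 pairs therefore decomposes 210 sources.

**Adversarial refinement** (`ramanprep.gan`).  A conditional generator
(stem convolution + three U-shaped 1D blocks + global skip from the ideal
channel) maps (ideal, Gaussian latent) to a reference; a residual 1D conv
classifier discriminates generated from recombination references.  The
loss is non-saturating BCE plus an L1 consistency term to the paired
synthetic reference, weight 10: conditional-GAN practice that anchors
outputs to plausible references while the adversary adds texture.  The
discriminator sees candidate references alone (not (x, y) pairs).  Labels
are never produced by the network — generated spectra stay paired with
their conditioning ideals.  Desk-scale defaults (width 8, ≤16-sample
batches, ≤10 epochs) make the stage a demonstrable contract rather than a
production training run.

## The preprocessing network (`ramanprep.model`)

Two parallel branches feed an Inception-style encoder–decoder:

* **Patches branch** — the spectrum is split into overlapping sliding
  windows (window 64, step 32 by default; fixed after training), each
  window passes a shared affine map initialized to the identity, and
  windows are reassembled by overlap-averaging.  `make_patches` /
  `overlap_average` form an exact partition-of-unity pair.
* **Background-estimation branch** — a U-shaped contour extractor (three
  stride-2 convolutions down, three transposed convolutions up, widths
  8/16/32) whose final layer is zero-initialized, so the untrained
  estimate is exactly B(x) = 0.

Each branch has a three-layer convolutional pre-encoder bringing it to a
common channel width c; the feature maps are subtracted (peak features
minus background features).  The trunk is: Stem (length /4, channels ×4,
kernel 8 stride 4) → Inception_A → Reduction_A (length /2, channels ×2) →
Inception_B → Reduction_B → Inception_C → mirrored transposed-convolution
upsampling with skip connections at every resolution, including a
full-resolution skip from the subtracted feature map.  Inception blocks
run parallel kernel-1/3/7 branches concatenating back to the input width
plus a residual add, so they are dimension-preserving by construction.
The output is

    P(x) = head(u3) + (patches(x) − B(x))

— a global spectrum-space residual: after background pretraining the
model starts at "input minus estimated background" and the trunk learns
the correction (mainly denoising and peak restoration).  The two-layer
full-resolution head carries the peak-amplitude fidelity.  An earlier
variant that clamped the output nonnegative was removed: with sparse
targets the output ReLU permanently silenced tall peaks whose
pre-activation went negative early in training (a dying-ReLU failure
visible as whole peaks stuck at zero).

**Shapes.**  The grid length must be divisible by 16 (Stem /4, two
Reductions /2).  For L = 1024 and c = 4 the stage trace is
Stem (16 ch, 256), Reduction_A (32, 128), Reduction_B (64, 64); every
Inception stage preserves its input dimensions.  Traces are exposed via
`forward_preprocess(..., want_trace=True)`.

**Losses.**  Both terms are the Huber penalty with δ = 1 on the natural
residuals,

    L_BE = mean Huber(B(x) − (x − y)),
    L    = λ · mean Huber(P(x) − y) + (1 − λ) · L_BE,   λ = 0.2 default.

(An appendix below records why the piecewise forms are written this way.)
Training is two-step: the background branch alone under L_BE, then the
whole network under L.  Inputs are max-normalized per spectrum and the
scale inverted on output, which makes preprocessing exactly
scale-equivariant: P(c·x) = c·P(x) up to float32 rounding.

**Optimization.**  Adam, lr 2e-3 with step decay (×0.5 at 50% of epochs,
×0.25 at 80%, ×0.1 at 92%), batch 32, float32 throughout, fully
deterministic under a fixed seed on one machine.  Presets:

* `desk` — c = 8, 15 background + 110 full epochs: the configuration used
  by the acceptance script; trains on 2,000 pairs of length 1024 in
  roughly a quarter of an hour on one CPU core.
* `full` — c = 16, 100 + 400 epochs: the documented scale-up; not
  exercised by the test suite.

The network core (`ramanprep.nn`) is a small hand-written layer library
(Conv1d / ConvTranspose1d / Linear / ReLU / Adam) with explicit backward
passes, channel-last activations and im2col convolutions so each pass is
a single sgemm; backward passes are exact adjoints of the forwards
(unit-tested via inner-product identities).

## Classical comparators (`ramanprep.baselines`)

* **Iterative polynomial fitting** — fit a polynomial (default order 5),
  replace points above the fit by the fit, repeat until the relative L2
  change of the fitted baseline drops below 5% (the "iteration error"
  interpreted as that relative change) or `max_iter`; subtract; then
  denoise with Savitzky–Golay local polynomial smoothing over a ~50-point
  window (polyorder 7 — keeps a FWHM-20-point Lorentzian apex within
  ~5% while still averaging noise; order 5 costs ~12% of such an apex).
  Baseline subtraction precedes smoothing.
* **Wavelet level selection** — db8, 8-level decomposition, reconstruct
  from detail levels 3–6 (1–2 treated as noise, 7–8 + approximation as
  baseline), run for a configurable number of cycles (default 100,
  matching common practice; the selection is a near-projection and
  stabilizes after the first cycle).

## Metrics (`ramanprep.metrics`)

RMSE and L∞ against the ideal spectrum; pairwise-comparison AUC (ties
count ½, equal to the Mann–Whitney U statistic over M·N) with threshold
sensitivity/specificity/PPV/NPV; quantification error
`E_Q = sqrt(Σ (log10 y − log10 x)²)` (base 10 — concentrations in these
assays are decade-spaced); spectral SNR
`10·log10(mean I[2800,3200) / mean I[1800,2800))` with region means
floored at 1e-12 of the spectrum maximum and the result capped at
±120 dB (a silent zone at/below the floor reports the cap — "no
measurable noise"); masked image CNR/STDB with the normalized variants
defined raw-over-preprocessed.  Significance tests (Wilcoxon signed-rank,
Mann–Whitney U) are two-sided, exact for small samples (n ≤ 12, no
ties/zeros), normal approximation with continuity correction otherwise.
The silent-zone bounds are configurable (`RegionSpec`); the defaults
follow the SNR definition with silent region 1800–2800 cm⁻¹.  No
multiple-testing correction is applied; reports expose raw p-values per
pair.

## Hyperspectral cubes (`ramanprep.hyperspectral`)

A cube is H×W×L with a shared axis; preprocessing is applied per pixel in
deterministic row-major order (hence permutation-equivariant).  Channel
maps pick the nearest axis index (ties toward the lower index) or average
over ±band; `top_k_mean_spectrum` ranks pixels by spectral SNR and
averages the best k (default min(10 000, H·W)) so blank-substrate pixels
do not dilute image-level summaries.  PCA treats pixels as observations
and wavenumbers as variables (mean-centered, full SVD).  The simulated
cube places elliptical "cells" that alternate lipid-like (2850 cm⁻¹ CH2
dominant) and protein-like (2928 cm⁻¹ CH3) band sets on a smooth
fluorescence-like baseline field with Gaussian noise, and returns
ground-truth cell/background masks for CNR evaluation.  CNR requires
explicit masks; none are inferred.

## What the synthetic study does and does not show

The generators emulate the *structure* of measured spectra — sparse
positive peak sets, smooth dominant baselines, additive noise, controlled
SNR — and the recombination factory reproduces the paired-label training
recipe exactly.  They do not reproduce instrument artifacts (grating-
switch steps, cosmic-ray spikes, detector etaloning), correlated
pixel-to-pixel noise, or the chemical correlations of real analytes; the
noise and baseline pools are finite (one per ten pairs), so a trained
model partially keys on pool texture, just as the real factory keys on
the texture of its measured sources.  Passing tests therefore demonstrate
the pipeline's contracts and the in-distribution preprocessing gain, not
field performance on any particular instrument.  Clinical-scale results
(cancer-diagnosis AUC, pesticide quantification curves, measured-cell
SNR gains) require the corresponding measured datasets; the package
ships the metric suite those trials score with.

## Problem sizes used by the shipped runs

* Acceptance script: 210 simulated sources → pools; 2,000 recombination
  training pairs + 100 disjoint validation pairs (grid 1024,
  baseline-dominated severity); desk preset; wavelet comparator at its
  defaults.
* Test suite: the training-dependent checks run a reduced study (800
  training pairs, 100 validation pairs, 10 + 45 epochs) and a 32×32×512
  simulated cube with a small 512-grid model; all other tests are
  seconds-scale.  At reduced scale the headline check asserts the
  per-spectrum win rate against the wavelet comparator (the percentage
  reductions are a full-scale quantity, recomputed by the acceptance
  script); image-level SNR on cubes follows the top-k protocol so
  blank-substrate pixels do not dilute the summary.

## Known limitations

* One CPU core is assumed; there is no GPU path and no data-parallel
  training.
* The desk preset's error floor is optimization-limited: longer
  schedules and the `full` preset reduce validation error further.
* The GAN stage is a functional contract at desk scale, not a
  production-quality generative model.
* Spectra with axes outside the training grid's range are edge-filled on
  resampling; preprocessing quality degrades outside the trained range.

## Appendix: the piecewise loss forms

The piecewise definitions this model family is usually written with
switch between a quadratic and a linear branch on the magnitude of the
*data* residual |x−y| while penalizing a *model* residual, and one branch
mixes signs in a way that can return a negative value (a residual of 0 in
the linear branch gives −0.5), which cannot serve as a minimized
objective.  Both branches are recognizable as the standard Huber penalty
up to these slips, so the implementation uses the standard form — branch
condition and penalty both on the model residuals r_BE = B(x) − (x − y)
and r = P(x) − y with δ = 1 — which is continuous, nonnegative, and zero
exactly at the targets.
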