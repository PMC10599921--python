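# Methods

This package re-implements, as a tested pipeline over synthetic cohorts, the
quantification chain of a multimodal imaging study of neuroinflammation in
ADT-treated prostate-cancer patients: dynamic [11C]-PBR28 TSPO PET with
arterial input-function modelling and 2-tissue-compartment kinetics,
semi-quantitative SUV/SUVR with a cerebellar pseudoreference, a block-design
choice-reaction-time (CRT) BOLD-fMRI GLM at ROI level, and the group and
cross-modal correlation statistics.  No imaging data are deposited for the
study; everything here runs on a synthetic cohort generator with known
ground truth, plus the demographic and neurocognitive summary tables the
study printed.

## The synthetic cohort

The generator emulates the study design at ROI level: 11 subjects — 4 with
reported cognitive impairment (rCI) and 5 with reported normal cognition
(rNC), all with BOLD sessions, plus 2 subjects of unknown cognitive status
who instead carry arterial blood sampling.  Per subject it produces:

* **Dynamic PET** as regional time–activity curves (TACs) on the 26-frame
  90-min schedule (8×15 s, 3×60 s, 5×120 s, 5×300 s, 5×600 s).  TACs are
  frame-averaged 2TCM predictions driven by the true arterial input, with
  zero-mean Gaussian noise of SD `sd0·sqrt(C/Δt)` — the standard proxy for
  PET count statistics (`sd0 = 0.5` by default, giving ~2% CoV on the late
  600-s frames, typical for ROI-level data).
* **Arterial blood**: a continuous 1 Hz whole-blood channel for the first
  15 min (with a configurable multiplicative calibration bias, default 1,
  to exercise the calibration stage), discrete whole-blood/plasma samples
  at 5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90 min, and parent-fraction
  measurements at 5, 10, 20, 30, 50, 70, 90 min.  Noise is multiplicative
  (2% CV continuous and discrete) with additive SD 0.02 on fractions.
* **BOLD ROI sessions**: 161 volumes at TR 2 s; five cycles of 31.5-s task
  blocks separated by ~32.5-s rest after a 2-s pre-task baseline (onsets at
  2 + 64k s, reconciling the 322-s scan with five cycles).  Signal =
  baseline·(1 + psc/100 · x_c) + motion-coupled drift + AR(1) noise, where
  x_c is the range-normalised, mean-centred convolved task regressor — the
  centring makes the psc estimator exactly unbiased in the noiseless limit.
  Motion regressors are six random walks.
* **Dosimetry**: injected activity uniform on 294–374 MBq, body weight and
  age drawn near the study's ranges; blood-curve amplitude scales with
  injected activity per body weight so SUV is dose-normalised by design.

**True input function.** Whole blood rises linearly from 0 to its peak at
60 s and decays tri-exponentially (fractions 0.72/0.20/0.08 with time
constants 40/300/3600 s).  Plasma-over-blood follows an exponential
approach to a constant (c0 = 1.0, c_inf = 1.6, λ = 0.01 s⁻¹); the parent
fraction is a decreasing Hill sigmoid pf(t) = 1/(1+(t/t50)^h) with
t50 = 1200 s, h = 2.  The peak amplitude (39.5 kBq/ml at the reference
dosing of 337 MBq / 85 kg) was set once so the whole-brain SUV(60–90 min)
lands at ~1.0 g/ml, matching the published summaries the generator is
anchored to; regional kinetic parameters sit around K1 = 0.10 ml cm⁻³
min⁻¹, k2 = 0.05, k3 = k4 = 0.03 min⁻¹ (VT = 4.0 ml/cm³), with mild
deterministic regional heterogeneity and the cerebellum at base so that
whole-brain SUVR ≈ 1.  All simulated activities are decay-corrected by
convention; no decay term appears anywhere.

**Cross-modal coupling.** For every non-reference region a bivariate-normal
latent pair couples the subject's regional uptake multiplier (applied to
K1, CV 10%, reference region untouched so the SUVR ratio carries it) to the
subject's true percent signal change (mean 0.8%, between-subject SD 0.3%).
The target Pearson correlation ρ is a config knob; measured through the full
pipeline the sample correlation is mildly attenuated (~0.72–0.74 median at
ρ = 0.75 over 500 cohorts of n = 9) by TAC and BOLD measurement noise, as
expected from the noise-to-signal variance ratios.

**Determinism.** Per-subject RNG streams derive from a CRC-32 hash of
(master seed, subject id); identical (config, seed) regenerate byte-identical
tables, and the pipeline adds no timestamps, so full reruns are
byte-identical.

**What the generator does not emulate:** voxelwise anatomy and partial
volume, scanner physics (randoms/scatter/attenuation), frame-to-frame
motion, dispersion in the arterial line, plasma protein binding,
physiological (cardiac/respiratory) BOLD noise, and any registration or
segmentation step.  Passing tests therefore validate the quantification
chain, not image preprocessing.

## Input-function assembly

Stages run in a fixed order, every stage's parameters recorded in the model:

1. **Calibration**: the continuous channel is scaled by the mean, over the
   5/10/15-min overlap samples, of discrete / local continuous average
   (±5 s window).  A ratio mean is used rather than regression through the
   origin — with three points they are equivalent in practice.
2. **Merge**: calibrated continuous verbatim on [0, 900] s, linear
   interpolation through the later discrete samples, junction pinned to the
   continuous endpoint (interpolation error vs the true curve < 1.5%).
3. **Plasma-over-blood**: POB(t) = c_inf − (c_inf − c0)e^(−λt).  Because the
   first plasma sample is at 5 min, c0 is unidentified whenever the ratio
   equilibrates faster than the sampling; λ is therefore profiled on a grid
   (the model is linear in c0, c_inf given λ) and among statistically
   indistinguishable optima the fit whose c0 is closest to the earliest
   measured ratio is preferred, with a nonlinear polish accepted only on a
   material improvement.  Noiseless recovery is exact; under noise the
   guard trades a small, known bias in the unsampled early segment for
   robustness (without it, runaway c0 values corrupt VT by ~40%).
4. **Parent fraction**: the two-parameter decreasing Hill sigmoid above
   (pf(0) = 1 is physiologic for intact parent at injection), least squares.
5. **Multiply and smooth**: parent plasma = pf·POB·whole blood; the
   post-peak portion is replaced by a tri-exponential fitted in log space
   (relative error), seeded by non-negative least squares at several decay
   triplets, with the first post-peak minute up-weighted so the smoothed
   curve joins the raw pre-peak segment continuously (an exponential sum
   cannot reproduce the zero slope at the peak itself; the peak is located
   on a lightly smoothed copy so noise cannot pin it to a spike).  A
   bi-exponential fallback is flagged on failure.  The tri-exponential is an
   approximation: against the generator truth its relative ripple reaches
   ~5% where the metabolite sigmoid steepens, while preserving the curve's
   integral to <1% and downstream VT to ~0.1%.
6. **Delay**: grid search δ ∈ [−30, +30] s in 0.5-s steps, fitting a
   1-tissue + 5% blood volume model to the whole-brain TAC over the first
   120 s at each shift; ties break toward smaller |δ|, boundary minima are
   flagged.  Positive delay means the tissue sees the tracer after the
   blood-sampling site; blood tables stay on the sampling clock.  Noiseless
   recovery is exact to the grid step; under default noise the recovery
   carries a ~+1 s median bias inherited from the c0 guard in stage 3 (the
   flat early-POB extrapolation maps onto a small apparent delay).

## Kinetic modelling

The reversible 2TCM with fixed blood volume (Vb = 5%):
C_model = (1−Vb)(h ⊛ Cp) + Vb·C_b, with the standard two-exponential
impulse response in (K1, k2, k3, k4).  The convolution is evaluated exactly
against the piecewise-linear input on a uniform grid (closed-form integral
per segment, first-order recursion), and the model is compared to data as
frame-interval averages, since midpoint sampling is biased on 600-s frames.
Agreement with a stiff-ODE oracle is ~1e−7 relative.  Fitting is weighted
(w ∝ frame duration, normalised to the frame count) nonlinear least squares
with bounds [1e−6, 10] (per-minute units), three starts, lowest weighted SSE
winning and SSE ties broken by the delta-method VT variance; a fit where all
starts fail is flagged non-convergent with NaN VT and the pipeline
continues.  VT = (K1/k2)(1+k3/k4).

**Logan oracle.** The graphical-analysis slope over frames with mid time
≥ t* (default 1800 s), after removing the known blood-volume term, serves
as an independent cross-check of the 2TCM.  For the default kinetics the
slowest system eigenvalue is α1 ≈ 0.016 min⁻¹ (63-min equilibration), so
the Logan plot is still curved within a 90-min scan and the estimate
carries the method's well-known negative bias: ≈ −4% at t* = 1800 s,
shrinking to ≈ −2% at the latest window that retains the minimum four
frames (t* = 3000 s).  Validation therefore reads the oracle at the late
window; the bias-versus-t* behaviour is itself asserted in the unit tests.

## Semi-quantification

SUV (g/ml) is the duration-weighted mean concentration over frames whose
mid time lies in [3600, 5400) s, times body weight over injected activity;
an overlap-weighted window variant is provided and differs by <1% on this
schedule.  SUVR divides by the cerebellar pseudoreference SUV.  Composites
(cortex = occipital/temporal/frontal/parietal/insula/hippocampus/amygdala;
subcortex = pallidum/striatum/thalamus; whole brain = all regions) are
volume-weighted means with SUVR recomputed from the composite SUV, not
averaged over member SUVRs.  ROI extraction from 4-D arrays + integer label
maps (optionally NIfTI via nibabel) is exact voxel-mean per label.

## BOLD GLM

First level: a single task regressor (boxcar ⊛ canonical double-gamma HRF,
peak 6 s, undershoot 16 s, ratio 6, peak-normalised), six motion
regressors, an intercept, and high-pass filtering with a 100-s cutoff
applied to regressors and data.  The drift basis uses Slepian (DPSS)
tapers — half-bandwidth ≈ 0.78/cutoff Hz, floor(2T/cutoff) tapers, columns
centred so the intercept passes through — chosen over the discrete-cosine
basis because band concentration matters at this short scan length: with
the intercept it removes >99% of a 200-s sinusoid at any phase while
attenuating the convolved task regressor <5% (DCT at the same order leaves
up to ~29% of an off-phase slow sinusoid).

Autocorrelation is handled by iterated Prais–Winsten/Cochrane–Orcutt AR(1)
prewhitening.  A single pass underwhitens here: projecting out the design
and drift deflates the residual lag-1 estimate, so the iteration drives the
measured lag-1 correlation to the design's analytic white-noise value
tr(L·M)/tr(M) (M the residual-maker) rather than to zero, and whitening is
skipped when the estimate is within 2/√n of noise.  Measured operating
characteristics: null |Z|>1.96 rate ≈ 0.05–0.06 for white and AR(1) (φ=0.3
or 0.6) noise, and exact noiseless recovery.  psc = 100·β·(max−min of the
convolved regressor)/mean(series); this is invariant to rescaling the
series, while adding a constant rescales psc by the new baseline (as the
definition implies) and leaves β, t and Z untouched.  Z maps the t tail
probability through the normal quantile.  Group level: one-sample t on psc
and a Welch two-sample rCI-vs-rNC comparison — an ROI-level stand-in for
voxelwise mixed-effects modelling, which is out of scope along with all
spatial preprocessing.

## Statistics

Two-sample comparisons use the pooled-variance Student t by default (Welch
by flag), computable identically from raw values or printed summaries
(mean, SD, n).  On the reference cohort's printed neurocognitive table the
ten comparisons are all non-significant under Welch (min p ≈ 0.07), but the
colour-word naming row is significant under the pooled variant (t = 2.88,
df = 8, p ≈ 0.02) — with groups of 4 and 6 and a five-fold variance ratio,
pooling is the wrong model, and only Welch reproduces the published
all-null narrative; the corresponding pooled acceptance check is left
failing by design and the discrepancy is documented rather than hidden.
The printed age SD (7.5) is likewise not recoverable from the printed ages
(sample SD 6.7); the mean (68.5) is the check.

Cross-modal correlations are Pearson r per region between SUVR and CRT
activation (psc by default; Z or β configurable) across subjects,
pairwise-complete on subject id, two-sided p from the t distribution with
n−2 df; a permutation cross-check agrees within ~0.03 (worst at mid-range
p, where decisions are insensitive).  At n = 9 the 5% critical |r| is
0.666, so sample correlations of 0.72–0.79 are significant while ≲0.6 are
not.  No multiple-testing correction is applied by default (the reference
values are unadjusted); Benjamini–Hochberg is available.

## Problem sizes

Monte-Carlo sizes used by the tests and the reproduction script: 4000 null
simulations for each type-I rate, 500 zero-effect sessions for the GLM null
rate, 500 cohorts (three-region fast configuration, full measurement path)
for the coupling calibration, 100–200 seeds for the blood-stage recovery
checks and 20–40 for the slower delay and kinetic Monte-Carlos.  These are
the package's validation sizes; they keep the complete suite within a few
minutes on one core.

## Known limitations

* The exact functional forms behind the original software's
  "exponential approach to a constant" and "sigmoid-2" labels are not
  recoverable; the chosen forms are isolated behind single fit functions
  so alternatives can be swapped.
* The tri-exponential post-peak smoothing cannot follow the product of a
  tri-exponential blood curve with the metabolite sigmoid to better than a
  few percent pointwise (see above); its effect on VT is negligible.
* Early plasma-over-blood behaviour (before the first plasma sample) is
  unidentified from data; under noise the plausibility guard trades bias
  for robustness and induces the ~1-s delay bias noted above.
* ROI-level group tests and correlations stand in for voxelwise
  mixed-effects maps and cluster correction; conclusions about spatial
  specificity are outside this package's reach.
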