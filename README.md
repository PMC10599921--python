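# tspoquant

Multimodal quantification of dynamic TSPO-PET and block-design BOLD-fMRI,
built as a tested analysis pipeline over synthetic cohorts.

## The problem

Neuroinflammation can be imaged with PET using TSPO radioligands such as
[11C]-PBR28, and quantified either fully — fitting a reversible 2-tissue
compartment model (2TCM) against a metabolite-corrected arterial
parent-plasma input function to obtain the total volume of distribution

&nbsp;&nbsp;&nbsp;&nbsp;*V*<sub>T</sub> = (K₁/k₂)(1 + k₃/k₄) ,

— or semi-quantitatively as SUV (uptake normalised by injected activity per
body weight) and SUVR (SUV relative to a pseudoreference region, here the
cerebellum).  Relating regional TSPO uptake to task activation from
BOLD-fMRI (a block-design choice-reaction-time task analysed with a GLM)
asks whether inflammation and functional recruitment co-vary across
subjects — the regime this package targets is a small cohort (n ≈ 9–11,
e.g. prostate-cancer patients on androgen-deprivation therapy), where the
interesting outputs are regional SUVR, VT in the arterial-blood arm,
percent signal change (psc) per ROI, and per-region Pearson correlations
between SUVR and activation.

Because no imaging data are deposited for such studies, every stage here is
exercised on a **synthetic cohort generator with known ground truth** (TACs
on the 26-frame/90-min schedule, continuous + discrete arterial blood with
parent-fraction measurements, BOLD ROI sessions with motion regressors, and
a controllable cross-modal coupling ρ), plus the demographic and
neurocognitive summary tables printed in the reference study.  See
`docs/methods.md` for the model details and design choices.

## Layout

```
src/tspoquant/     library: frames, cohort (generator), blood (input function),
                   kinetics (2TCM + Logan), semiquant (SUV/SUVR), fmri (GLM),
                   stats, studydata (printed reference tables), validation
                   (Monte-Carlo calibration), pipeline (driver)
analysis/          numbered narrative drivers writing under results/
scripts/           acceptance.py (see "Reproducing the results")
tests/             pytest suite incl. test_acceptance.py
```

## Worked example

```bash
python analysis/01_simulate_cohort.py   # 11 subjects, rho = 0.75, seed 42
python analysis/02_input_function.py
python analysis/03_kinetics.py
python analysis/04_semiquant.py
python analysis/05_fmri_glm.py
python analysis/06_stats_report.py
```

Step 02 prints, per arterial-blood subject, the fitted chain parameters:

```
sub-010: calibration 1.0061, POB c_inf 1.616, PF t50 1198 s, delay +0.5 s, ...
```

— the continuous-detector calibration factor (truth 1.0 here), the
plasma-over-blood plateau (truth 1.6), the parent-fraction half-time
(truth 1200 s) and the fitted blood-to-tissue delay (truth 0).  Step 03
fits the 2TCM per region:

```
fitted 22 regional 2TCM models (100% converged)
             mean    std
sub-010     3.948  0.341
sub-011     3.826  0.373
```

i.e. regional VT averaging ≈3.9 ml/cm³ against a generator truth of
≈4.0 — the few-percent shortfall is the noise-limited identifiability of
the early input curve, quantified in the methods note.  Step 04 reports the
semi-quantitative regime (`whole-brain SUV mean 1.014 g/ml`, `SUVR mean
1.008`), step 05 the ROI activations (mean psc ≈ 0.7–0.9% per region,
truth 0.8%), and step 06 the statistics: the reference cohort's
demographics (`n=11, mean age 68.5 y`), ten neurocognitive group
comparisons (all non-significant under Welch), null rCI-vs-rNC SUVR
comparisons, and the cross-modal correlations, e.g.

```
SUVR vs CRT activation (Pearson, whole cohort):
  amygdala     r=+0.86 p=0.003 (n=9)*
  striatum     r=+0.82 p=0.006 (n=9)*
  ...
```

With n = 9 paired subjects the 5% critical |r| is 0.666, so per-cohort
sample correlations scatter widely around the generated ρ = 0.75 — exactly
the behaviour the coupling calibration (`analysis/07_calibration_checks.py`)
quantifies: the median sample R over many cohorts sits at ≈0.73.

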