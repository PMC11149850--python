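# ppgsurv

Ten-year cardiovascular risk modelling from single-pulse
photoplethysmography (PPG) waveforms.

## The problem

Most cardiovascular risk scores need a blood-pressure cuff, body
measurements or laboratory assays, which limits screening reach in
low-resource health systems. A finger-pulse PPG waveform, by contrast,
can be captured by a pulse oximeter or a smartphone camera. `ppgsurv`
implements a two-stage deep survival score that predicts the ten-year
probability of a major adverse cardiovascular event (MACE) from nothing
but age, sex, smoking status and a single device-summarized pulse
waveform — together with the comparison models, evaluation statistics,
interpretability analyses and a synthetic cohort generator, so the whole
pipeline can be exercised end to end without access-restricted data.

It is aimed at biostatisticians and ML-for-health researchers who want a
transparent, fully reproducible reference implementation of the method
and its evaluation machinery.

## The model

**Stage 1 — deep pulse features.** Each 100-sample summarized pulse is
resampled onto a uniform 18.2 ms grid (length `⌊period/18.2⌋ + 1`,
so 55 steps at 60 bpm), min–max normalized, and zero-padded into
batches. A 1-D residual CNN (ResNet18 topology at desk-scale widths
16–128, implemented in numpy with explicit backprop) maps each pulse to
an embedding `e(x)` and a scalar risk score, trained by minimizing the
mean negative Cox partial likelihood over minibatch risk sets

```
L = −(1/D) Σ_{i: event} [ r_i − log Σ_{j: T_j ≥ T_i} exp(r_j) ]
```

with Breslow tie handling and a Brownian tape-speed time-warp
augmentation. The checkpoint with the best tune-split partial
likelihood is kept; train-split PCA reduces embeddings to five deep
pulse features **PPG-1..PPG-5**.

**Stage 2 — ridge Cox.** A Cox proportional-hazards model over
standardized covariates maximizes the Breslow partial likelihood minus
`(λ/2)‖β‖²` (Newton–Raphson, λ tuned on the tune split), with age ×
feature interaction terms for the deep-feature models. Absolute risk
comes from the Breslow baseline cumulative hazard:
`p₁₀ = 1 − exp(−H₀(10y) · e^{lp})`.

Evaluation follows the paired-comparison playbook: Harrell's C with
1,000-iteration bootstrap CIs, a paired permutation test for
non-inferiority at a 2.5-percentage-point margin, category-free and
threshold NRI with event/non-event components, sensitivity/specificity
at thresholds matched to the SBP > 140 mmHg rule (Clopper–Pearson
intervals), decile calibration slope, Kaplan–Meier/log-rank, subgroup
tables, and integrated-gradients saliency of the Cox log partial hazard
with respect to the waveform.

## Worked example

```python
from ppgsurv import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1, extractor={"max_epochs": 8}))
m = result.metrics
print(f"C (DLS)        {m['models']['dls']['c_statistic']['estimate']:.3f}")
print(f"C (metadata)   {m['models']['metadata']['c_statistic']['estimate']:.3f}")
print(f"C (oracle lp)  {m['oracle_c']:.3f}")
comp = result.comparisons["dls_vs_office_refit_who"]
print(f"delta C        {comp['delta_c_pct']:+.2f} pp, "
      f"p_noninf = {comp['p_noninferiority']:.4f}")
print(f"slope (DLS)    {m['models']['dls']['calibration_slope']:.3f}")
```

which prints (seed 1, cohort of 12,000 → ~6,000 train / ~2,600 tune /
~3,400 test, ~2 minutes on one CPU):

```
C (DLS)        0.779
C (metadata)   0.741
C (oracle lp)  0.782
delta C        +3.13 pp, p_noninf = 0.0010
slope (DLS)    1.057
```

Reading: on the held-out geographic test region the deep score (0.779)
recovers almost all of the discrimination of the *generating* linear
predictor (0.782, the simulator's upper bound) and clearly beats the
metadata-only Cox model (0.741); it is non-inferior to the office-based
comparator at the 2.5 pp margin (p ≈ 0.001), and its decile calibration
slope is near 1. On the synthetic cohort the waveform carries a large
share of the risk signal by construction, so the deep-vs-metadata gap is
wider than one would expect on real screening data.

The same run is available from the shell:

```bash
ppgsurv run out/ --seed 1
ppgsurv verify out/        # re-check the manifest checksums
```

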