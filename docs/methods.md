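# Methods

This note documents the modelling, simulation and numerical choices in
`ppgsurv`, in the spirit of a statistical-software methods appendix.

## Waveform preprocessing

The input record is the device-summarized pulse: 100 amplitude samples
in arbitrary units plus the pulse rate measured during the recording.
Because the device stretches every pulse to 100 samples regardless of
heart rate, physical time per sample varies across subjects. We place
the 100 samples on `t_i = i · period/99` (endpoints inclusive; the
divisor is a config switch, 99 vs 100, since the device's endpoint
convention is not documented) and linearly interpolate onto the uniform
grid `t_k = 18.2·k` ms, `k = 0..⌊period/18.2⌋`. Linear interpolation is
chosen over splines as the simplest contract consistent with resampling
the x-axis; it is exact for constant waves and never overshoots the
input range. Each pulse is then min–max normalized to [0, 1] (the model
needs a fixed scale; device units are arbitrary); flat or non-finite
records are rejected with a logged reason, mirroring cohort-exclusion
plumbing. Batches are right-padded with zeros and carry per-row valid
lengths.

## Tape-speed augmentation

During extractor training each pulse is re-read at a randomly varying
speed: the log tape speed follows a Brownian random walk with per-step
standard deviation σ (default 0.05), warped times are the cumulative
sum of the exponentiated walk, rescaled to pin both endpoints, and the
wave is linearly interpolated at the warped times. The warp is strictly
monotone, so landmark order is preserved; σ = 0 reproduces the input
exactly. The exact published formulation of this augmentation is not
available in the primary description we follow, so this geometric
construction is our concrete stand-in, kept behind a single `augment`
entry point so an alternative can be swapped in. Augmentation is never
applied when computing embeddings.

## Morphology features

Landmarks are detected on the normalized uniform-grid pulse: systolic
peak = global maximum within the first 60% of the pulse (the window
avoids capturing the reflected peak in stiff-vessel morphologies, and
is configurable); dicrotic notch = the most *prominent* strict local
minimum after the peak, i.e. the one with the largest rebound to a
later maximum — depth alone fails on decaying pulses because the
deepest post-systolic minimum is in the near-zero diastolic tail; a
second-difference maximum serves as a lower-confidence fallback for
shallow notches; reflected peak = largest local maximum after the
notch; shoulder = first second-difference sign change on the downstroke
between peak and notch (the "shoulder" has no standard definition, so
this inflection rule is a documented choice). A light 1-2-1 smoothing
pass suppresses single-sample noise extrema. Derived features:
reflection index `100·A_refl/A_peak` (%), peak-to-peak transit time
(ms), stiffness index `height/Δt` (m/s), landmark positions (always in
ms, never sample indices), and a notch-presence flag. Missing landmarks
propagate as missing values; the morphology comparison model is fitted
complete-case on the subset with all morphology features available.

## Deep feature extractor

A 1-D residual CNN with the ResNet18 topology: strided stem convolution
(kernel 7, stride 2), four stages of two residual blocks (kernel 3,
stride-2 downsampling at stage entry), channel widths 16/32/64/128
rather than the canonical 64/512 — inputs are single pulses of ≲150
steps and the narrow variant trains on one CPU in minutes with the same
topology; full width is a config knob. There is no batch
normalization: at this scale Adam (lr 10⁻³) trains the plain residual
network stably, and omitting it keeps the forward pass purely
deterministic. Activations beyond each row's valid length are zeroed
after every convolution and pooling averages over valid steps only, so
embeddings are exactly invariant to the pad length. The embedding is
the 128-dim pooled feature vector; a linear head yields the training
risk score.

The loss is the mean negative Cox log partial likelihood with Breslow
tie handling, computed within each minibatch (batch 256) — the standard
deep-survival approximation to the full partial likelihood; batches
without events are skipped. The checkpoint maximizing the tune-split
partial likelihood is selected. Forward, backward and Adam are
implemented explicitly on numpy arrays; gradients are verified against
finite differences in the test suite. Everything is seeded and
single-threaded-deterministic. Optional auxiliary task heads are
deliberately out of scope (default off).

PCA (exact SVD, train split only) reduces embeddings to five scores,
PPG-1..PPG-5; the device pulse rate (PPG-HR) bypasses the network and
joins at the Cox stage.

## Survival models

`CoxRidge` standardizes continuous covariates with train-split
statistics (binary 0/1 features pass through), optionally appends
age × feature interaction products, and maximizes the Breslow partial
log likelihood minus `(λ/2)‖β‖²` by Newton–Raphson with step halving,
declaring convergence at max |score gradient| < 10⁻⁷. Deep-feature
models (`dls`, `dls_plus`, `dls_plus_plus`) include age interactions by
default; the refit-WHO comparators do not (configurable), since the
evidence for age-declining hazard ratios concerns the deep-feature
models. λ is chosen on a log-spaced grid {0, 0.1, 1, 10, 100} by
tune-split unpenalized partial likelihood, ties toward the larger λ.
The baseline cumulative hazard is the Breslow step-function estimator
(the classical choice; Efron would be a drop-in alternative), giving
`p₁₀ = 1 − exp(−H₀(10y)·e^{lp})`. Each named feature set is fitted
complete-case. The SBP-140 rule reads "above 140 mmHg" strictly:
141 → 1, 140 → 0. Survival times are in days; ten years = 3652.5 days.
Kaplan–Meier and the log-rank test delegate to lifelines.

## Evaluation statistics

* **Harrell's C**: pairs are comparable when the shorter time is an
  event (tied times are not comparable); score ties count ½.
* **Ten-year labels**: event before the horizon → 1; followed to the
  horizon event-free → 0; censored earlier → excluded. This one rule is
  applied consistently to sensitivity/specificity, NRI/cfNRI and
  calibration, so all binary-outcome metrics share a censoring
  treatment.
* **cfNRI / NRI**: event component `100·[P(new>ref|event) −
  P(new<ref|event)]`, non-event component with directions flipped,
  exact ties contribute zero; threshold NRI applies the same formula to
  the two risk categories at a threshold (high iff score ≥ threshold).
* **Confidence intervals**: Clopper–Pearson (exact beta quantiles) for
  proportions; percentile bootstrap over subjects (default B = 1,000,
  paired resampling for paired statistics, degenerate resamples redrawn
  and counted) for everything else. Percentile rather than BCa: the
  least-assumption reading of a non-parametric bootstrap.
* **Non-inferiority**: the permutation scheme is ours to pin down — the
  null exchanges the two scores within a subject with probability ½,
  independently per subject and permutation; `p_sup = P(Δ* ≥ Δ_obs)`,
  and non-inferiority at margin m uses the shift construction
  `P(Δ* ≥ Δ_obs + m)`, both one-sided with add-one correction. Type-I
  error of the superiority test is verified by simulation in the test
  suite (rejection rate in (0.03, 0.07) at α = 0.05).
* **Calibration**: prediction deciles (quintiles for small subgroups),
  observed rate per bin from the ten-year-label rule, slope/intercept
  by OLS of observed on predicted bin means; empty bins are merged and
  counted. The slope and the mean absolute calibration error are
  reported separately (they are different quantities).
* **Threshold matching**: matching a binary rule's *specificity*
  returns the smallest threshold achieving at least it; matching
  *sensitivity* returns the largest such threshold (sensitivity
  decreases in the threshold, so "smallest" would be degenerate); the
  fixed 10% absolute-risk threshold passes through untouched.

## Integrated gradients

Attribution of the Cox log partial hazard with respect to the waveform,
metadata held fixed (an additive constant): straight path from the
all-zeros padded baseline, right-endpoint Riemann approximation with m
steps (default 64). With age interactions the effective deep-feature
coefficients are evaluated at a fixed reference age (median event age).
The completeness residual `ΣIG − (F(x) − F(0))` is always reported, and
shrinks as m grows (≈0.5% relative at m = 256 on the trained synthetic
model). For display, maps are normalized to max |value| = 1; raw values
are kept in outputs. Quantile-averaged waveforms select the k = 100
subjects nearest a quantile (ties toward lower index) and average the
min–max-normalized 100-point display-space waves.

## Synthetic cohort

The generator reproduces the *structure* of a biobank PPG cohort, not
its exact joint distributions: ages uniform on 40–74, 45% male, 43%
smokers, 15 named sites with coordinates grouped into three regions
(center/north-west/south-east ≈ 50/22/28%) used as train/tune/test.
A latent vascular-stiffness factor `s = 0.045·(age − 57) + ε`,
ε ~ N(0, 1), drives **both** the waveform and the hazard — the minimal
structure under which the pulse carries risk information beyond
metadata. The waveform is a log-normal-shaped direct wave (peak
~150 ms) plus a reflected bump delayed by `250 − 25·s` ms with
amplitude `0.45 + 0.07·s`, minus a notch dip of depth `0.13 − 0.03·s`,
plus N(0, 0.01) noise, rendered to 100 samples at the subject's pulse
rate. The hazard is exponential with per-SD log hazard ratios 0.85
(age), 0.35 (male), 0.40 (smoking) and 0.55 (latent s); the baseline
rate is solved numerically (Brent) so the population ten-year event
probability hits the ~3% target; censoring is administrative at 12
years plus a 10% uniform early-censoring fraction. SBP, BMI,
cholesterol, glucose and HbA1c are loosely coupled to `s` so the
office/lab comparators gain realistic signal. Hazard-coefficient
magnitudes were fixed once so the generating predictor's concordance
and the metadata-only/PPG-only orderings land in the neighbourhood
reported for real cohorts of this kind (oracle ≈ 0.78, metadata ≈ 0.74
at the default seed); they are structural settings, not fitted values.

What the simulator does **not** emulate: real waveform noise families
(motion artifact, device quantization), non-proportional hazards,
competing risks, covariate measurement error, and realistic
correlation between heart rate and risk. Passing pipeline tests on
this cohort therefore demonstrates mechanism recovery and software
correctness — not clinical performance; the deep-vs-metadata gap here
is deliberately larger than plausible on real data so that signal
recovery is testable at desk scale. Latent columns are physically
present (`_latent_*`) but refused by the modelling feature resolver,
preventing accidental leakage in tests.

## Pipeline discipline and problem sizes

A single global seed fans out to named per-stage substreams (SHA-256 of
`seed:stage`). The extractor, PCA, covariate scalers and λ selection
see only train/tune data; the test split is consumed exclusively by the
evaluation stage; each stage records the participant ids it used and a
run-level assertion checks the discipline. Default study conditions: a
cohort of 12,000 (≈6,000 train / 2,600 tune / 3,400 test after the
geographic split), extractor trained for up to 12 epochs (8 in the
bundled example runs — selection always by tune partial likelihood),
B = 1,000 bootstrap and permutation iterations. A full run takes about
two minutes on a single CPU; all outputs are byte-reproducible given
the config and seed.

## Known limitations

* The CNN is desk-scale; widths and epochs are deliberately small, and
  there is no GPU path, no batch norm, and no hyperparameter search
  beyond the ridge grid.
* The permutation scheme and the censoring treatment inside cfNRI are
  reasonable conventions, not canonical definitions; both are config
  points.
* Proportional-hazards diagnostics (Schoenfeld-type checks for
  individual deep features) are not yet implemented.
* The Breslow estimator slightly underestimates the baseline hazard
  with heavy ties; tie density is negligible at the simulated scales.
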