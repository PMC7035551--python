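# Methods

## Scope and model family

`patbp` treats cuff-less blood-pressure estimation as a calibration
problem: a BP–PAT model with a small number of unknowns is solved exactly
from cuff-BP / mean-PAT pairs and then used to convert continuous PAT
measurements into continuous BP.  Five model forms are implemented (see
the README table): two coefficient models per channel of two unknowns
(MK-EE logarithmic, L-MK linear), two anchor models of one unknown pair
(MK-BH, dMK-BH, parameterised by the calibration state
SBP₀/DBP₀/PAT₀ plus the fixed vascular constant γ), and one
three-coefficient radical model (M-M).

Conventions worth stating explicitly:

* PAT is in seconds everywhere.  MK-EE/L-MK/M-M coefficients absorb the
  unit; dMK-BH depends on PAT only through the ratio PAT₀/PAT and is
  unit-invariant by construction.
* The MK-BH DBP channel uses the model's *own* SBP estimate at the same
  PAT (`DBP = SBP_est − PP₀·r²`), mirroring the symmetric structure of the
  dMK-BH rows.
* The M-M form is `BP = a + √(b + c/PAT²)`.  The radical is isolated in
  one helper; a negative radicand raises a domain error ("no real
  solution"), which during calibration marks the subset as unusable
  rather than aborting the run.  The squared 3-point system also admits a
  spurious `a − √(·)` branch; solutions on it cannot reproduce the
  calibration points and are rejected the same way.
* dMK-BH is evaluated in a rearranged but algebraically identical form
  (`DBP = DBP₀ + (2/γ)ln r + (PP₀/3)(1 − r²)`) so that both channels hit
  the anchor exactly at PAT = PAT₀ in floating point.
* γ defaults to 0.031 mmHg⁻¹ (healthy young adults) and is never fitted;
  it enters MK-BH/dMK-BH as an input constant, and its influence is
  studied by the γ sweep instead.

## Advanced PTP calibration

One calibration **round** is four (cuff BP, 30-s PAT̄) pairs.  For a model
needing k points, all C(4,k) subsets of each round are solved exactly and
every scalar parameter is averaged arithmetically over the successful
subsets of all rounds (default 4 rounds, 16 pairs, ~8 minutes of cuff
time).  Design choices:

* **All subsets, not four.** For 1- and 3-point models C(4,k) = 4; for
  2-point models we enumerate all 6 subsets.  Exhaustive enumeration makes
  the result invariant to the ordering of pairs within a round.
* **Averaging in parameter space.**  The alternative (averaging
  predictions) is not what "average values of these parameters" suggests;
  PP₀ and MBP₀ are recomputed from the averaged SBP₀/DBP₀ so the baseline
  identities survive averaging.
* **Degeneracy tolerance.**  Two PAT̄s closer than 1e-9 relative are
  treated as duplicates.  Window means of near-identical beat PATs can
  differ by one ULP; without the tolerance such "distinct" pairs produce
  slopes of order 10⁶ that destroy the average.
* Anchored models (MK-BH/dMK-BH) are identified exactly only when the
  calibration pairs sit at the anchor itself: their curve families are
  not closed under re-anchoring (a baseline taken elsewhere on the same
  curve generates a *different* curve).  Coefficient models conversely
  need distinct PATs.  Exact-recovery tests therefore calibrate anchored
  models at rest and coefficient models during the post-exercise decay.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: twelve
healthy young adults, a stair-climbing bout that elevates BP, then a
seated recording in which BP and heart rate relax back to rest; ECG+PPG
at 1 kHz; an automatic cuff reading every 30 s; ~30 monitoring windows
and ~1,200–3,000 beats per subject.

PAT is the primary stochastic process and beat-wise "true" BP is derived
from it through the subject's generating model, so ground truth is exactly
model-consistent and recovery tests need no numerical inversion.  Per-beat
PAT is

```
PAT(t) = PAT₀ − Δ_ex·exp(−(t − t_ex)/τ) + OU(t) + ε_t
```

with exercise drop Δ_ex (default 40 ms, ~+23 mmHg SBP at onset through
dMK-BH), recovery constant τ (default 360 s, shared with heart rate
110→70 bpm), a slow mean-reverting Ornstein–Uhlenbeck component (sd 4 ms,
correlation time 60 s) representing vasomotion/autonomic variability —
resting BP is genuinely non-constant, which is exactly what makes repeated
calibration rounds informative — and white per-beat jitter ε (sd 5 ms).
Cohort parameters are drawn from population distributions with resting
SBP 118.37 ± 12.95 and DBP 69.40 ± 8.79 mmHg, PAT₀ 0.25 ± 0.02 s, and a
physiologic floor of 20 mmHg on resting pulse pressure.  Cuff readings are
window means of true beat-wise BP plus Gaussian device error (sd
2.5 mmHg, emulating a ~3 mmHg-accuracy automatic monitor); inverted
readings (SBP ≤ DBP after noise) are dropped and counted.

Waveform rendering is deliberately schematic: Gaussian R-spikes (σ = 8 ms)
and a PPG pulse whose raised-cosine rising edge is steepest exactly at
`beat + PAT`, followed by a shifted-exponential decay that reaches zero
smoothly (a truncated decay puts a step under a later pulse's rising edge
and biases its max-slope point).  The record starts 0.5 s before the first
beat so boundary beats render whole.  No PQRST morphology, dicrotic notch,
respiration or motion artefacts are modelled: passing waveform tests show
the *delineation logic* is correct at 1 kHz timing resolution, not that
the detectors are robust to clinical-grade artefacts.

Two generator modes matter for testing:

* `model_consistent_cuff`: cuff readings are the generating model
  evaluated at the window-mean PAT instead of the window mean of beat-wise
  BP.  The two differ by the nonlinear window-averaging error (~0.2 mmHg
  under the default decay); the model-consistent mode makes noiseless runs
  exactly recoverable (errors at machine precision).
* `calibrate_at_rest`: the calibration segment (8 min) is recorded at
  rest and the exercise recovery starts at its end, matching a protocol
  in which calibration happens in a quiet state; with `False` the whole
  recording is post-exercise decay, which spreads calibration PATs wider.

## Signal processing

Zero-phase 4th-order Butterworth high-/low-pass sections
(ECG 1–40 Hz, PPG 0.5–20 Hz, `sosfiltfilt`).  R-peaks: local maxima above
half the 99th-percentile amplitude with a 250 ms refractory period.  The
PPG fiducial is searched per cardiac cycle `[rᵢ, rᵢ₊₁)`: pulse peak
first (cycle argmax), then the foot (pre-peak minimum), then the maximum
first difference on the foot→peak rising edge — searching the cycle-wide
minimum instead can land on the slow drift toward the next beat's trough.
Both fiducials get 3-point parabolic sub-sample refinement (offsets
clipped to ±1 sample), which brings the noiseless end-to-end PAT error of
a 15-minute 1 kHz record to ≤0.45 ms, comfortably inside one sample.
Windows admit a mean PAT only with ≥8 cardiac cycles (respiratory
averaging rule); beats with missing or non-positive PAT are dropped with
a warning.

## Evaluation

Agreement statistics per model/channel: ME, MAD, SSE, σ = √(SSE/(n−1)),
c.v. = σ/ME, SD = √((1/n)Σ(xᵢ−x̄)²) and RMSE = √(SSE/n).  The divisor
asymmetry (σ uses n−1, SD uses n) is intentional and kept exactly as
conventionally reported; c.v. is undefined at ME = 0 and reported as
absent, and near-zero ME legitimately produces extreme c.v. magnitudes.
AAMI acceptance is |ME| ≤ 5 and SD ≤ 8 mmHg, both inclusive.  Correlations
are pooled over all subjects' monitoring pairs (one R per model/channel).
Kruskal–Wallis (tie-corrected, χ² p with g−1 df) and Dunn's pairwise
z-tests are implemented from the rank formulas — the installed SciPy
routine serves as an independent cross-check in the tests, and no Dunn
implementation ships in the environment — with Bonferroni (default),
Holm, or no correction.  Model comparison groups are per-subject mean
errors.  The γ sweep recalibrates dMK-BH per subject at each grid value
(default 0.0005–0.05, step 0.0005 mmHg⁻¹) and reports pooled MAD curves
and their raw grid argmins; no interpolation is applied.

## Problem sizes and determinism

Default experiment: 12 subjects × (8 min calibration + 15 min
monitoring), ~1,500–2,500 beats/subject at beat level; the full study
runs in ~1 s, the 100-point γ sweep in ~2 s, and a single 15-minute
1 kHz waveform round trip in ~4 s, so the test suite and the acceptance
script stay interactive.  The waveform path is off by default in
`run_experiment` (beat-level PAT feeds windowing directly) and exercised
separately.  Every stochastic step takes an explicit seed; experiment
sub-seeds derive from the config seed, reports embed a config hash, and
identical configs produce byte-identical report files.

## Known limitations

* The generator's PAT→BP coupling *is* the model under test; results on
  synthetic cohorts demonstrate internal consistency and estimator
  properties, not clinical accuracy on real subjects.
* Pre-ejection period, vascular-tone drift, arrhythmias and measurement
  artefacts are not modelled; real-data robustness of the detectors is
  out of scope.
* Two-point models calibrated on windows with small PAT spread produce
  heavy-tailed slope estimates; the subset-averaged parameters can then
  be far worse than any single good subset.  This is a property of the
  exact-solution-averaging method itself under low within-round signal,
  and it is surfaced in the default-noise study tables rather than hidden.
* M-M calibration can fail outright (no real solution in every subset)
  for subjects with small PAT spread; such subjects carry an explicit
  failure record in the report.
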