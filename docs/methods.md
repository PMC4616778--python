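# Methods

This note documents the models, measurement conventions, numerical choices
and limitations behind `dynea`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Index definitions and measurement grids

All three indices are computed per ventilator cycle (the respiratory rate is
set on the ventilator and fixed, so cycles are aligned to the clock, not
derived from the pressure signal):

* **PPV** per cycle is `100·2(PPmax−PPmin)/(PPmax+PPmin)`. Cycle values are
  averaged into 8-s epochs (a cycle belongs to the epoch containing its
  midpoint), and each reported PPV reading is the rolling mean of 4
  consecutive epochs — the update convention of bedside PPV monitors.
* **SVV** per cycle is `100·(SVmax−SVmin)/SVmean` from the pulse-contour SV
  estimates; the reported reading every 20 s is the mean over the cycles in
  that window, mirroring the 20-s update of pulse-contour platforms.
* **Dynamic arterial elastance** at a time point is the ratio of the average
  of the last 3 PPV readings to the average of the last 3 SVV readings
  (*ratio of averages*, not average of ratios). Because the two series live
  on different native grids (8 s vs 20 s), this mirrors the clinical
  two-monitor setup and makes the grid mismatch second-order.

Epochs/windows containing no complete cycle are skipped with a warning;
fewer than 4 usable PPV epochs is an error. A respiratory cycle only counts
as complete when it contains ≥ 2 beats *and* is fully covered by detected
beats — a cycle truncated by the trace boundary would otherwise sample the
sinusoidal modulation asymmetrically and bias the extrema.

**Protocol rules.** The fluid-challenge gate requires every SVV reading in
the trailing 10 minutes to be strictly > 10% and the patient to be
hypotensive (MAP < 65 mmHg or SBP < 90 mmHg; strict inequalities). The
responder rule is inclusive: MAP increase ≥ 15%. It is evaluated with a
1e-12 guard (`≥ 0.15 − 1e-12`) because a case sitting exactly on the
boundary can otherwise flip on floating-point representation alone;
clinically distinct cases are ≥ 10⁻³ away from the boundary.

## 2. Beat detection and the stroke-volume surrogate

The trace is smoothed (Savitzky–Golay, ~110 ms window, order 3) *for
landmark localization only*; pressures are read off the raw trace.
Systolic upstrokes are contiguous runs of slope above 30% of the trace's
95th-percentile slope, at least ~30 ms long; runs closer than half the
fastest physiological beat (250 bpm) merge. The diastolic foot is the last
sample at the bottom of the preceding valley (within a noise-scaled
tolerance of the valley minimum, refined by descending on the raw trace) —
this keeps the foot at the upstroke onset even when the diastolic run-off
is flat or noisy. Beats touching either trace boundary, shorter than the
250-bpm period, or with non-positive pulse pressure/area are discarded
(with a warning for the latter); beats whose instantaneous rate falls
outside 20–250 bpm are flagged but kept.

The SV surrogate is the **systolic area**: the integral of pressure above
the foot pressure over the first 35% of the instantaneous beat period (a
fixed ejection-duration convention; the synthetic template has no dicrotic
notch), with a fractionally interpolated endpoint so the area is
insensitive to where the window boundary falls between samples. SV in mL is
`calibration_k × area`; the calibration constant is arbitrary and every
downstream index is invariant to it (asserted to 1e-12 in tests), as it is
to a pressure gain factor.

Limitations: at very low pulse amplitudes (PP of a few mmHg) with realistic
noise the slope threshold degrades and beats are dropped; arrhythmia is not
handled beyond the rate flag (the clinical protocol excludes it).

## 3. Synthetic waveform generator

Beat *j* starts at `j·60/HR`. Its stroke volume is
`SV_j = SV₀·(1 + m·sin(2π f_resp t_j))` and its pulse pressure
`PP_j = k·SV_j^γ`. The power-law coupling makes γ a minimal model of
arterial tone: to first order in *m*, PPV ≈ γ·SVV, so the true PPV/SVV
ratio → γ, giving the pipeline a clean recovery target (the package asserts
|Ea − γ| ≤ 0.05 for m ≤ 0.15, γ ∈ [0.6, 1.2], and Ea = 1 to 1e-6 when
γ = 1).

Each beat is rendered as a linear upstroke to `baseline + PP_j` over 30% of
the cycle and an exponential decay back to baseline over the rest. The
per-beat decay rate is solved (Brent) so that the *systolic area of the
first 35% of the cycle is proportional to SV_j*. This is the one deliberate
departure from a strictly fixed pulse shape: with a fixed shape the area is
proportional to PP, the SV surrogate collapses onto pulse pressure, and the
estimated Ea would be ≡ 1 for every γ. Physiologically it encodes the same
assumption pulse-contour monitors rely on — the ejected volume shapes the
systolic portion of the pulse beyond its peak excursion. Respiratory
modulation is purely sinusoidal in SV; an additive baseline swing is
available (`baseline_swing`, default 0) but no intrathoracic-pressure
mechanics are modelled. Gaussian noise (default sd 0.5 mmHg, a typical
arterial-line noise floor) is added last; everything is deterministic given
the seed.

Stored ground truth (`true_ppv`, `true_svv`, `true_ea`) is the exact
enumeration of the beat sequence over the first respiratory cycle — the
discrete sampling of the sinusoid matters (e.g. 5 beats/cycle at HR 60 /
RR 12 give true SVV = 19.02%, not the continuous-limit 20%), and tests
verify it against an independent brute-force enumeration to 1e-12.

The minimum simulated duration is 52 s (four 8-s PPV epochs plus one 20-s
SVV window); the 60-s default additionally yields the ≥ 3 readings per
series that the elastance average needs.

## 4. Synthetic cohort generator

Each patient draws a dynamic elastance from a two-component Normal mixture:
means 0.79 (responder-leaning component, weight 17/39) and 0.61, common sd
0.145. The sd is set once so that the binormal separation
`Φ((0.79−0.61)/(√2·0.145))` has AUC ≈ 0.81; the weight mirrors a 17/22
split. The MAP response to the fluid challenge is linear in elastance:

```
ΔMAP% = β₀ + β₁·Ea + ε,   β₀ = −30, β₁ = 60,  ε ~ N(0, 3²)
```

placing the 15% responder boundary at Ea = 0.75, with ε representing
short-term MAP measurement/biological variability. T2 snapshots always
satisfy the protocol gate by construction (MAP drawn below 65 mmHg, SVV
above 10%); T3 MAP is T2 MAP scaled by ΔMAP%. **Responder labels are never
stored** — `PatientRecord.responder` is a derived property recomputing the
≥ 15% rule from the T2/T3 MAPs, so the generator→classifier round trip is a
real test surface (exact at ε = 0).

What a green test does and does not establish: because labels are induced
by a noisy threshold on Ea itself, the true AUC of Ea against the induced
labels is ≈ 0.977 (computed in tests by numerical integration of the
mixture density against the label model) — *higher* than a clinical
cohort's, where preload reserve, aortic compliance and measurement error
all enter. The generator validates the pipeline's statistics, not the
clinical effect size; cohort-level AUC values from this generator are not
comparable to published patient results. For confidence-interval
calibration the package uses the plain two-group binormal sampler, whose
true AUC is the closed-form Φ expression.

Other snapshot fields (heart rate, cardiac index, stroke volume index,
SBP/MAP ratio) are drawn from plausible intraoperative ranges and carry no
signal; they serve as realistic negative controls in the per-variable ROC
table.

## 5. Cohort statistics

* **Two-group comparison**: Shapiro–Wilk per group; Student's unpaired t
  test (equal variances, as in classical practice) when both p ≥ 0.05,
  Mann–Whitney otherwise; chi-square for categorical data unless an
  expected cell count is < 5, then Fisher's exact test (2×2). All p-values
  two-sided; no multiple-testing correction across the ROC variables (they
  are reported individually).
* **Two-way repeated-measures ANOVA** (between = responder group, within =
  time T1–T4, subjects nested in group): classical sums-of-squares
  decomposition, no sphericity correction, no imputation (a missing time
  point is an error). Degenerate inputs follow F = 0 when the effect SS is
  zero and F = ∞ (p = 0) when the error mean square vanishes. The
  implementation is hand-rolled for exactly this degenerate-case control
  and is cross-checked against `pingouin.mixed_anova` in tests.
* **ROC**: thresholds are the distinct observed scores; the prediction rule
  is `score > cutoff → responder`, with the orientation fixed (higher Ea
  predicts pressure response) and never auto-flipped, so a sign error
  surfaces as AUC < 0.5 instead of being silently hidden. The AUC is
  computed from midranks — identical to the trapezoidal area of the
  tie-grouped curve and to the normalized Mann–Whitney U with ties counted
  ½ (asserted to 1e-12 against brute-force pairwise comparison). The
  Youden cut-off maximizes sensitivity + specificity − 1; ties resolve to
  the lowest threshold, favouring sensitivity.
* **DeLong 95% CI**: DeLong's covariance estimate, interval constructed on
  the logit scale (delta method) and mapped back. The plain Wald interval
  clipped to [0, 1] under-covers near high AUCs at this cohort size
  (~90–93% measured); the logit form restores 93–97% coverage against the
  known binormal truth in 1000 synthetic 17/22 cohorts (asserted in the
  acceptance suite) and produces the asymmetric intervals characteristic
  of published ROC tables. With perfect separation the variance is zero
  and the interval degenerates to (1, 1).
* **Sample size (Hanley–McNeil)**: with Q₁ = θ/(2−θ), Q₂ = 2θ²/(1+θ) and R
  negatives per positive, the default closed-form variant computes

  ```
  n₊ = ⌈ (z_{α/2}√V(θ₀) + z_β√V(θ₁))² / (θ₁−θ₀)² ⌉,
  V(θ) = (Q₁−θ²)/R + (Q₂−θ²)
  ```

  which for 0.75 vs 0.5, two-sided α = 0.05, power 0.80, R = 1 gives
  19 + 19 = 38 — the classical design number for this study type (also the
  value MedCalc-style software reports). A finite-sample iterative variant
  (`variant="exact"`, keeping the θ(1−θ) and (n−1) variance terms) is
  provided as a documented switch; it is slightly conservative (40 for the
  same inputs). Enrollment inflates the total by the dropout rate, rounded
  to the nearest integer (38 → 42 at 10%).

## 6. Reproducibility

Every stochastic component takes a seed (`numpy.random.default_rng`); the
pipeline serializes its full configuration next to its outputs and
reproduces every output byte-for-byte for the same config and seed (asserted
in tests). Interchange is plain CSV with explicit headers plus JSON sidecar
metadata; logs contain no timestamps.
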