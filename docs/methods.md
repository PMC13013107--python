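# Methods

This note documents the models, conventions and numerical choices of the
PAM toolkit, what the synthetic generator does and does not emulate, and
where a design decision was genuinely open.

## Alignment and windows

Each sample's pre-event lag is `(event_day − day_post_index) × 24` hours
at day resolution, or the exact hour difference when an
`hour_post_index` is recorded (hour resolution is preferred whenever
present, since the true acquisition convention of day-resolved clinical
data is ambiguous). Window boundaries are half-open:
`W24_48 = [24, 48)` and `W48_72 = [48, 72)` hours pre-event, so at day
resolution a 1-day gap maps to W24_48 and a 2-day gap to W48_72. The
labels themselves do not dictate boundary ownership; half-open intervals
were chosen so the windows partition the lag axis with no double
counting. Samples 0–24 h pre-event are excluded by design (metabolic
volatility immediately before onset makes that window unreliable at
daily sampling resolution), and samples at or after the event are kept
in the data model but never enter a stratum.

## Matching

The metric over matching covariates is a Gower-style weighted sum:
`|Δage|/IQR_age + 1[sex differs] + 1[location differs] + |ΔHH|/4 +
|ΔmF|/4`, unit weights by default. The source design names the matching
variables but no metric, weights, tie-break or reuse policy, so all of
these are explicit configuration logged into every run manifest:

* day matching is exact first and auto-widens to ±1 day on pool
  exhaustion (`day_gap_used` records what was actually used);
* ties break deterministically by (distance, control patient id,
  control sample id);
* a control sample may serve several cases (`per_case_unique`, the
  default — the motivating study filled 72 control slots from 53
  distinct samples); `globally_unique` consumes each control once.

With reuse allowed, per-case greedy selection of the k smallest
distances is exactly the global minimum-cost assignment (cases do not
compete), which the tests verify by subset enumeration. Balance is
reported as standardized mean differences before/after matching; because
the metric pools covariates, individual SMDs can trade off against each
other and only the aggregate imbalance is guaranteed to shrink.

## Differential screen

All testing happens on log₂ peak areas (zeros floored at half the
feature's smallest positive value before the transform; the transform is
stateful and can be applied only once). Per feature the screen computes
Student's t (primary test for FDR), Welch's t, Mann–Whitney U and
Levene's test with median centering (Brown–Forsythe — more robust than
mean centering; the choice is config-exposed). A Levene p < 0.1 flags
the feature so the variance-robust companions are highlighted. The
Mann–Whitney p uses exact enumeration when both groups have ≤ 25 untied
values, else the tie-corrected normal approximation.

Benjamini–Hochberg q-values are the step-up
`q_(i) = min_{j≥i} p_(j)·m/j`, with NaN p-values (degenerate variance)
excluded from `m`. The multiplicity scope is a parameter
(`annotated_only` vs `all_features`) so the annotated-set and full-set
FDR burdens can both be reproduced. Ranks are ascending-p with the
minimum-rank tie convention; rank concordance reports each feature's
best and worst rank across the three tests.

Case samples are tested against the *distinct union* of their matched
controls at sample level; independence handling is deliberately deferred
to the patient-level evaluation stage, mirroring the two-stage design
this package implements. Ratios (log₂ numerator − log₂ denominator) are
screened identically but with BH across the ratio set only.

The paired Wilcoxon for dual-window patients builds the exact null of W
(sum of positive ranks) over all 2ⁿ sign assignments via a
generating-function convolution on doubled (integer) midranks for
n ≤ 25, with zero differences dropped and average ranks for ties; larger
n falls back to the tie-corrected normal approximation.

## QC

PCA runs on Pareto-scaled data (center, divide by √SD; zero-variance
features dropped). Hotelling's T² per sample is the sum of squared
component scores over their variances across the first A = 5 components
(config-exposed; the component count behind the reference threshold is
not fixed by the source design), with critical value
`A(n−1)/(n−A)·F_{1−α}(A, n−A)` at α = 0.001. Exclusion is applied once —
no iterative re-exclusion — before matching and discovery.

## Predictor evaluation

One observation per patient: event patients contribute their in-window
sample (the one closest to 24 h pre-event when two exist), control
patients the mean of their matched samples. Logistic models use
predictors z-scored on the analysis set after averaging (the ordering of
standardization vs averaging was open; standardizing the analysis set is
what makes "odds ratio per 1 SD" refer to the modelled population).
McFadden pseudo-R² is `1 − ll_model/ll_null` (defined as exactly 0 for
the intercept-only model); AIC is `2(k+1) − 2·ll`. Perfect separation is
reported as non-converged rather than silently returned.

AUC uses the rank (Mann–Whitney) formulation with ties counting ½; ROC
scores are the model's fitted event probability, so a protective
(depleted) predictor still yields AUC > 0.5. Bootstrap CIs resample
cases and controls separately (class counts preserved in every
replicate), percentile flavor by default with a basic-bootstrap option.
DeLong's test is implemented from placement values (structural
components), which is what lets the tests verify its single-AUC variance
against a brute-force bootstrap. The Monte Carlo sensitivity analysis
redraws one sample per control patient per iteration (child seeds
spawned from one seed sequence) and reports the mean, SD and full AUC
distribution — SD rather than a CI half-width, since the distribution is
returned anyway.

## Synthetic cohorts

The generator emulates the motivating study's conditions: 60 patients,
event fraction 0.5, event day from pmf {3: .10, 4: .30, 5: .40, 6: .10,
7: .10} (median 5, IQR 4–5), every-other-day sampling with random phase
over days 0–7, and 2,022 features with feature-level baselines
μ_f ~ U[20, 30] log₂ units and σ_f ~ U[0.3, 0.9]. Because a strict
alternate-day schedule can never put one patient in both adjacent
windows, each non-scheduled day also carries a 0.2 chance of an extra
draw ("predominantly every-other-day"); this yields ~36 window samples
from 30 event patients with ~5–8 contributing to both windows, matching
the observed sample flow. Severity scores are drawn conditionally on
event status (events skew higher), and event status is *not* re-derived
from covariates — matching, not causal modelling, is the target.
Outcome scores are drawn worse for event patients with ~10% missingness.

Spikes add a window-specific log₂ effect to event-group samples falling
in that window. The canonical configuration plants an arginine-like
−0.715 at 24–48 h (baseline pinned to the reported control-group
moments, mean 27.61 / SD 0.48 — the case group's larger SD reflects an
outlier the reference analysis itself removed), a citrulline-like −0.38,
a glutamine-like −0.35/−0.31 across both windows, and null
ornithine/glutamate-like features as ratio denominators.

Noise is independent Gaussian in log₂ space with no feature–feature or
within-patient correlation. Passing tests therefore demonstrate correct
recovery under independence; they do not certify behaviour under batch
effects, drift, correlated pathways or informative missingness, none of
which the generator simulates.

## Calibration checks and problem sizes

The repeated-simulation studies (also driven by
`scripts/acceptance.py`) use: 200 replicate canonical cohorts for effect
recovery and the design comparison; 60 spike-free cohorts of 500
features for type-I control; 100 null-predictor replicates at the
study's observation counts (16/29) with 1,000-iteration bootstrap CIs;
and 8 simulated n = 40 score sets with 2,000-iteration bootstraps for
the DeLong-variance agreement. These sizes give Monte Carlo standard
errors comfortably below the tolerances being checked while keeping a
full calibration run around half a minute.

One statistical subtlety: under the global null, the BH procedure makes
at least one rejection with probability exactly α, so "zero discoveries
in ≥ 95% of runs" is a boundary property — the finite-sample check is a
one-sided binomial test that the zero-hit rate is not significantly
below 0.95, alongside a two-sided check that the nominal hit rate is
~5%.

## Known limitations

* Retrospective alignment only; no real-time/prospective mode and no
  multi-event patients.
* Day-resolution lags quantize windows; hour-resolution inputs are
  supported but the generator does not produce them.
* The matching metric is a pragmatic Gower sum, not propensity or
  optimal-network matching; no caliper by default.
* The generator's independence assumptions above.
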