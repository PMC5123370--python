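# Methods

## The design problem

A two-arm superiority trial with a time-to-event primary outcome is sized by
events, not patients: the log-rank test's power depends on the number of
primary-outcome events `d` observed by the analysis, the target hazard ratio
HR, the significance level α with its sidedness, and the power 1 − β.
Patients matter only through the probability that each contributes an event
by the analysis, which is where accrual and follow-up durations enter. The
package treats these two layers separately — an events layer (pure error
calculus) and an accrual layer (survival and entry-time model) — and composes
them into full designs.

## Events layer

Two standard event formulas are implemented, with `z_a` the normal quantile
at `1 − α` (one-sided) or `1 − α/2` (two-sided) and `z_b` the quantile at the
power:

* Schoenfeld-type: `d = 4 (z_a + z_b)² / (ln HR)²`
* Freedman-type: `d = ((1 + HR)/(1 − HR))² (z_a + z_b)²`

For HR < 1 the Freedman-type count is always the larger; both are symmetric
under HR → 1/HR only in the Schoenfeld case. A third, "combined" engine
returns the ceiling of the mean of the two raw counts.

**Why three engines.** Published redesign tables for the worked example do
not state their generating formula. The Schoenfeld-type formula with
nearest-integer rounding reproduces the original design's 147 events (raw
147.07) exactly, while the combined engine with ceiling rounding reproduces
every revised row (raw 249.41 → 250, 196.46 → 197, 182.48 → 183, 170.65 →
171, 160.40 → 161). The combined rule is therefore a calibration, flagged as
such: both raw and rounded values are always exposed, the rounding policy is
an explicit parameter, and the ledger records per-row which engine produced
each number rather than forcing one engine on all rows.

**Sidedness.** One-sided tests are for benefit only; harm and no-effect lead
to the same operational decision. A one-sided level-α design is identical on
the benefit side to a two-sided level-2α design, and the implementation makes
this an exact identity (same quantile, hence same events) rather than an
approximation.

**Degenerate specifications.** `ErrorSpec` rejects α or power outside (0, 1)
and combinations where the α and power quantiles sum to a non-positive number
(e.g. one-sided α = 0.9 with power 0.05), for which the formulas would
produce meaningless event counts.

## Accrual layer

Survival is exponential in each arm and accrual is uniform over `[0, a]`;
the analysis happens at calendar time `T` from the first entry, so a patient
entering at `u` is followed for `T − u`. Integrating the exponential CDF over
entry times gives

```
P(event) = 1 − e^{−λ(T−a)} · (1 − e^{−λa}) / (λa)
```

implemented via `expm1` so it is continuous as `a → 0` (where it reduces to
`1 − e^{−λT}`) and returns exactly 0 at λ = 0. Recruitment is the event
requirement divided by the allocation-weighted mean event probability across
arms (experimental hazard = control hazard × HR); totals are rounded up,
then bumped to an even number under 1:1 allocation. The inverse problem —
the smallest total duration at which a fixed cohort yields the required
events — is solved by monotone bisection on `[a, a + 100]` years to 1e-6
years.

**Known 2–4 % gap.** This is the minimal model consistent with a design
stated as "accrue for a years, answer after T years". The historical worked
example's published recruitment totals (576, 929, 820, 646, 600, 561, 527)
exceed this model's outputs (556, 910, 806, 636, 590, 552, 520) by a
consistent 2–4 %; the software and assumptions behind the published numbers
(possibly a dropout allowance or a non-exponential survival curve) are not
stated. The gap is documented and tested as a tolerance band (< 4 %) rather
than absorbed by an ad-hoc inflation factor. Event requirements, by
contrast, reproduce exactly. There is no loss-to-follow-up parameter; the
field exists on `AccrualPlan` but must be 0.

**Survival-fraction reading.** The worked example's narrative says 70 % of
control-arm patients "would experience events" by 3 years, but its own
arithmetic (HR 0.63 described as a 10-point absolute improvement) is only
consistent with 70 % being the event-*free* survival: 0.70^0.63 ≈ 0.799.
The package adopts the event-free reading throughout.

## The design ledger

Redesigning proceeds by small, individually justified alterations grouped in
three ordered stages: (1) broaden what is feasible (collaboration,
eligibility, accrual/follow-up time), (2) revisit the standard knobs
(research arm, outcome, target effect, power), (3) the less conventional
levers (sidedness, relaxed α, covariate adjustment, re-randomisation,
external information). The ledger enforces this ordering; recording a
deliberate revisit of an earlier stage (as the worked example does when it
extends follow-up after changing the effect target) requires an explicit
`allow_out_of_order` flag, so the audit trail shows the deviation.

Qualitative steps are first-class entries with empty parameter changes and
zero deltas, so the ledger documents the whole deliberation, not only the
arithmetic. Deltas are exact integer differences of the rounded requirements
against a declared reference row — by default the *first post-baseline* row,
matching the convention of comparing each change against the revised working
design rather than the original. Ledgers are immutable (each alteration
returns an extended copy), replay deterministically from their serialised
form, and export to CSV/TSV with a fixed column order.

Covariate adjustment is recorded as an annotation asserting the reclaimed
true power (e.g. "≥ 85 %") without resizing the trial: planning to adjust the
analysis recovers precision that the unadjusted sample-size calculation
ignores, so the requirements are left unchanged and an asserted power below
the nominal one is rejected.

## Portfolio calculus

From the societal perspective — the set of trials a disease area can support
— the relevant error rates are joint ones across independent trials: joint
power `1 − Π(1 − pᵢ)`, joint type-I error `1 − (1 − α)^t` over `t` claimed
positive results, and the expected number of false-positive trials. The
default for the latter is `N · π · α` with π the hypothesised fraction of
positive results, which matches the verifiable cells of the published
tabulation this package reproduces; the alternative reading `N · (1 − π) · α`
(α applied to the hypothesised null trials) is exposed via `of_negatives=True`
since the prose interpretation is ambiguous.

## Monte-Carlo verifier

`generate_trial` draws one trial: 1:1 allocation by permutation of the full
cohort, entry times uniform over the accrual window, event times exponential
at the arm-and-stratum hazard, censoring at the analysis time. The analysis
trigger is event-driven by default — the analysis happens at the calendar
time the design's pooled event count is reached, mirroring the event-based
sizing logic — with a calendar-time trigger available for follow-up
experiments. Event indicators are computed on the calendar scale so the
event that defines the analysis time is itself counted; when the event
target is unreachable (e.g. a zero hazard), the analysis falls back to the
planned calendar time.

The analysis is a self-implemented log-rank test: observed-minus-expected
events in the experimental arm with the hypergeometric variance and the
standard tie correction `(n − d)/(n − 1)`, summed over strata when a
stratified analysis is requested. The signed z statistic is negative when
the experimental arm has fewer events than expected; one-sided p-values
report the benefit direction only. The implementation is cross-checked in
the test suite against both a brute-force risk-set enumeration and an
independent library implementation.

Covariate adjustment is realised as this stratified log-rank rather than a
proportional-hazards regression: summing O − E within strata removes
between-stratum outcome variation from the comparison, which is sufficient
to demonstrate the power-reclaim effect while keeping the analysis exactly
testable. Simulated strata scale both arms' hazards by a common multiplier,
so the treatment hazard ratio is shared across strata.

All randomness flows through one named NumPy generator; the seed is recorded
in every `SimulationResult` and seeded runs are bit-reproducible.

**What the generator does and does not emulate.** It matches the
calculators' assumptions exactly — exponential survival, uniform accrual, no
dropout, proportional hazards, instantaneous event ascertainment. Passing
simulations therefore verify the internal consistency of the design
calculus, not its robustness to real-data features such as non-proportional
hazards, accrual ramp-up, loss to follow-up, cure fractions or interval
censoring, none of which are modelled.

## Numerical choices and problem sizes

* Normal quantiles via `scipy.special.ndtri`, tested to 1e-6 against an
  independent root-finding inversion of the normal CDF; all printed-number
  reproductions are insensitive to quantile precision beyond 1e-6.
* Event-probability formula tested to 1e-8 against numerical integration.
* Bisection tolerance for duration solving: 1e-6 years.
* Routine test-suite simulations use 800–2,000 replications (Monte-Carlo
  standard error under 1 percentage point); the headline operating
  characteristics — empirical power within 2 points of nominal, null
  rejection within 3 Monte-Carlo standard errors of α — are verified at
  10,000 replications, the package's standard for reportable estimates.
* Percent output is formatted to one decimal; raw values are always
  available (`--raw` on the CLI, unrounded fields in every result object).

## Limitations

Non-inferiority designs, binary/continuous/ordinal endpoint sample sizes,
group-sequential boundaries and interim monitoring, re-randomisation
inference, Bayesian borrowing of external information, competing risks,
non-uniform accrual and piecewise survival are all out of scope. The
allocation-ratio field is general but only 1:1 designs are exercised by the
worked examples and guaranteed exact.
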