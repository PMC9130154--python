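# Methods

## Model structure

The engine evaluates one-period decision trees: a single decision node at the
root enumerates strategies; chance nodes below it carry branch probabilities;
terminal nodes carry a cost (€) and an effectiveness payoff (QALYs). Branch
probabilities and payoffs are expressions in a closed mini-language — sums,
products and complements of parameter references and literals — which is
sufficient for diagnostic-pathway models (joint probabilities are products,
the "other" branch is a complement) and keeps model files auditable. Chance
probabilities must sum to one within 1e-9 at the point estimates; violations
are validation errors, never silently renormalised, because renormalisation
hides configuration bugs.

Rollback computes per-strategy expected cost and QALYs by recursive expected
value. Expressions evaluate over scalars or NumPy arrays, so the same code
path evaluates one assignment or ten thousand Monte-Carlo draws. Two
independent oracles check the engine: brute-force path enumeration
(probability-product sums over all root-to-leaf paths) and a patient-level
microsimulation whose means converge to the rollback expectations by the law
of large numbers.

## The bundled fracture model

Strategies: CR only, CR+CBCT, CR+MSCT. Stages: fracture status (pretest
probability 0.18), diagnostic result, then for treated true positives a
*sequential* complication chain — displacement (0.12), else non-union (0.15),
else arthritis (0.784), else uncomplicated. The three complication
probabilities sum to more than one, so they cannot be branches of a single
chance node; reading them as conditional probabilities of a nested sequence
is the minimal structure that uses each value exactly once and keeps every
chance node a probability partition. False negatives route to a
"missed fracture" state; in the no-fracture arm the test either raises a
false positive or correctly rules out. The CR-only arm uses CR sensitivity
0.70 and, since no CR specificity is reported anywhere, the baseline
correct-diagnosis rate 0.98 in that role (a documented stand-in; the
calibration makes the CR arm flat in prevalence, so this choice has little
leverage).

Costs: each terminal of a strategy carries that strategy's unit cost
(CR 32 €, CBCT 67.33 €, MSCT 106.23 €), so rollback returns the unit cost
exactly. This matches how the source reports per-strategy cost (the CT unit
cost alone, not CR + CT) without inventing unprinted cost arithmetic.

### Endpoint calibration

The published per-strategy QALYs (7.9 / 9.08 / 8.18, and 8.8 / 7.9 at zero
prevalence for the CT arms) sit on a compressed scale: they are inconsistent
with both a one-year horizon (≤ 0.93 QALYs) and a lifetime at utility ≤ 0.93
(≈ 42 QALYs). No printed information recovers that scaling, so the model
treats strategy-level QALYs as calibrated quantities: the published
disease-present values are taken as conditional expectations given a
fracture, the published prevalence-0 endpoints as conditional expectations
given no fracture (CR is flat at 7.9), and the leaf payoffs are solved to
reproduce them. The system is underdetermined; the package resolves it by
fixing the *spread* between leaves to complication decrements and applying a
uniform shift: leaf value = target − (probability-weighted mean decrement) +
(leaf decrement), which reproduces every conditional target exactly (checked
to 1e-9) while keeping the ordering of health states. Targets that would
force a negative payoff raise a calibration error.

The decrements themselves are a synthetic allocation (no leaf payoffs are
printed anywhere): utility losses from the parameter table — the
immobilization loss 0.93 − 0.759 = 0.171 for displacement and non-union, the
symptom decrement 0.03 for arthritis and false positives — rescaled by the
disease-status QALY gap 0.28 (the only printed anchor on the compressed
scale), with missed fractures carrying twice the complication-weighted mean
loss to reflect delayed treatment. Unconditional strategy QALYs are then
affine in prevalence: CBCT at prevalence 0.18 is 0.82·8.8 + 0.18·9.08 =
8.8504.

A consequence worth stating: because the published per-strategy table uses
the disease-present convention, statistics computed on it (ICER 29.94 €/QALY,
NMB 9.07 / 7.89) differ from those at the base-case prevalence (ICER 37.17,
NMB 8.84 / 7.89). The package computes both; the PSA result stores
effectiveness in both conventions per iteration.

### Parameters

All uncertain probabilities and utilities take beta, costs gamma
distributions, moment-matched to (mean = point estimate, SD = dispersion ×
mean) with a default relative standard error of 0.10 — the sources publish no
standard errors, so this is the package's single documented uncertainty knob,
overridable per parameter. Test characteristics of both CT modalities,
population quality of life and the demographic parameters are held
deterministic, mirroring the analysis the model reproduces. Ranges for
deterministic sweeps follow the printed ranges where one exists (fracture
prevalence 10–25%, population pretest probability 1.5–2% — the latter is
carried as a documented, unreferenced parameter) and default to ±20% of the
point estimate otherwise.

Known source-data discrepancies, surfaced here rather than reconciled: the
narrative text gives MSCT 94%/92% and CBCT 91%/93% sensitivity/specificity
while the parameter table gives MSCT 0.90/0.98 and CBCT 0.96/0.90 (the table
values are used); the published MSCT ICER (371.15) and NMB (8.09) do not
follow from the published MSCT cost/QALY pair, which yields 265.11 and 8.17
(the recomputed values are used); a quoted reference-case expected utility of
8.891 is not reproducible from any printed prevalence.

## Comparison statistics

ICER follows the difference-quotient definition with signs preserved;
equal-effectiveness comparisons raise an undefined-ICER signal rather than
returning a number. NMB is returned in both the monetary (E·λ − C) and
λ-scaled (E − C/λ) forms; the published tables match the λ-scaled form
*truncated* (floored) to two decimals — 9.0778 → 9.07, 7.8989 → 7.89 —
so that truncation is exposed as the reporting convention while full
precision is retained internally. The ranking reference is the lowest-cost
strategy; NMB ties break by strategy name. The frontier construction removes
strictly dominated strategies (weak-inequality form, so exact ties survive,
flagged as ties by coincident coordinates) and then extendedly dominated ones
(enforcing increasing ICERs along the frontier). The frontier/ICER walk-up
rule is implemented independently of the NMB argmax and the two are checked
against each other on random configurations.

## Deterministic sensitivity analysis

One-way sweeps hold all other parameters at point estimates; grid values
outside the plausible range require an explicit `force` flag (prevalence 0
and 1 are legitimate what-ifs but should be deliberate). The tornado baseline
outcome is the λ-scaled NMB of the base-case optimal strategy (an
expected-QALY variant and an NMB-gap variant are also available), and by
default only uncertain parameters are swept — parameters the analysis holds
deterministic have no uncertainty to propagate; passing explicit ranges or
`include_fixed=True` overrides this. Switch thresholds track the optimal
strategy's NMB lead over its best rival; the crossing is solved in closed
form when the lead is affine in the parameter (verified by three-point
collinearity) and by bisection to 1e-9 otherwise.

## Probabilistic sensitivity analysis

Each iteration draws all parameters jointly (independently across
parameters), rejects and redraws any iteration in which a composite chance
probability leaves [0, 1] (impossible with plain beta draws; the count is
logged), and rolls the tree back vectorised. Seed and iteration count fully
determine every output. The CEAC evaluates all willingness-to-pay values on
the same draws using monetary NMB (well defined at λ = 0, where the cheapest
strategy wins); exact NMB ties split probability mass equally so the curve is
a probability partition at every λ. The default λ grid is 0–50,000 € in 500 €
steps.

Under the bundled model's calibration the acceptability of CBCT at 30,000
€/QALY computes to ≈ 1.00 rather than the published 0.98: with the leaf
payoffs calibrated and the test characteristics deterministic, the QALY gap
between CBCT and its rivals (≈ 0.9) dwarfs every propagated uncertainty
(complication-mix shifts of order 0.001 QALYs, cost shifts of order 0.0004
λ-scaled), so no draw flips the decision. The published 0.98 evidently rests
on dispersions that were never printed; this result is reported as computed
and is sensitive to the 0.10 dispersion default. Low-threshold behaviour
(λ below ~7,500 €) likewise cannot reproduce a "no CT" region on the
compressed QALY scale, since the effectiveness gap dominates cost at any
λ above a few tens of €/QALY.

## Microsimulation

Patients are routed through every strategy subtree by independent categorical
draws at each chance node, in fixed depth-first order, so a seed determines
the cohort bit-for-bit. Records carry fracture status, test result,
complication, terminal label, accrued cost and QALYs, plus patient sex drawn
2:1 male as metadata (no parameter in the model is sex-specific). The
generator emulates the stated cohort conditions — fracture status at the
pretest prevalence, test outcomes via sensitivity/specificity, the
complication chain — but not features of real registries (age structure,
correlated comorbidity, loss to follow-up), so agreement between
microsimulation and rollback validates the engine's internal consistency,
not the model's external validity.

## Utility machinery

The DASH→EQ-5D mapping is a linear predictor in pre-injury EQ-5D, DASH pain,
EQ-5D function and the pain×function product, clamped to [0, 1] (utilities
worse than dead are out of scope for this model family). No fitted
coefficient set for finger fractures is published; the bundled set is a
clearly-labelled synthetic placeholder that maps full pre-injury health with
zero pain to utility 1.0. QALY accumulation is utility × duration summed over
segments, with an optional continuous annual discount rate defaulting to 0
(no discount rate is stated for the model this package reproduces). The
bundled life table is synthetic except for its two anchors (49.87 remaining
years at age 30; 45 at age 35, i.e. death at 80) and interpolates linearly
between knots, erroring outside its age domain.

## Problem sizes and numerical choices

Default analysis sizes: 10,000 PSA iterations (the model family's standard),
200,000-patient microsimulation for oracle checks (3-standard-error
agreement), 1e-12 tolerance for rollback-vs-enumeration identities, 1e-9 for
calibration targets, probability sums and threshold crossings. All random
number generation uses `numpy.random.default_rng` with explicit seeds.

## Limitations

The model is one-period: no discounting within the tree, no Markov cohort
traces, no treatment-choice modelling beyond diagnosis, no EVPI. The
calibrated QALY scale reproduces the published endpoints but has no absolute
interpretation; cross-model comparisons of its QALY magnitudes are not
meaningful. The PSA dispersion default (0.10 relative SE) is an assumption,
and the headline acceptability probability is sensitive to it. Radiation-dose
considerations are outside the model entirely.
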