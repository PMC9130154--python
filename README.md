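# ceatree

Decision-tree cost-effectiveness analysis for diagnostic imaging strategies,
built around a calibrated reference model of complex phalangeal (finger)
fractures: should a suspected articular finger fracture seen on conventional
radiography (CR) be worked up with cone-beam CT (CBCT) or multi-slice CT
(MSCT), or not imaged further at all?

The package is a small, general engine for one-period decision-analytic
models in health economics, aimed at analysts who want the standard outputs —
expected costs and QALYs, ICERs, net monetary benefit, tornado diagrams,
probabilistic sensitivity analysis with acceptability curves — from an
auditable, scriptable model description rather than a GUI tool.

## The model

A one-period decision tree with a single decision node over strategies
*s* ∈ {CR, CR+CBCT, CR+MSCT}. Under each strategy the cohort passes through
chance nodes for fracture status (pretest probability *p* = 0.18 in the base
case), diagnostic result (the modality's sensitivity/specificity; CBCT
0.96/0.90, MSCT 0.90/0.98, CR 0.70 with the baseline correct-diagnosis rate
0.98 standing in for specificity), and — for treated true positives — a chain
of complication events (displacement 0.12, non-union 0.15, post-traumatic
arthritis 0.784) versus uncomplicated recovery. Terminal states carry a cost
(the strategy's unit cost: CR 32 €, CBCT 67.33 €, MSCT 106.23 €) and a QALY
payoff.

Expected-value rollback gives per-strategy cost *C_s* and effectiveness
*E_s*; comparison statistics follow the standard definitions

- ICER(s vs r) = (C_s − C_r) / (E_s − E_r), in €/QALY,
- NMB_s(λ) = E_s·λ − C_s at willingness-to-pay λ (the λ-scaled form
  E_s − C_s/λ, in QALYs, is what published tables for this model report,
  truncated to two decimals),

and the strategy with maximal NMB is optimal at λ (base case λ = 30,000
€/QALY). Probabilistic sensitivity analysis draws every uncertain parameter
from a moment-matched second-order distribution (beta for probabilities and
utilities, gamma for costs, 0.10 relative standard error by default), rolls
the tree back per draw, and summarises the decision uncertainty as a
cost-effectiveness acceptability curve.

Strategy-level QALYs in the source material sit on a compressed scale that
cannot be derived from the printed utilities, so the bundled model pins the
conditional expected QALYs given disease status to the published endpoints
(disease present: CR 7.9, CBCT 9.08, MSCT 8.18; disease absent: CBCT 8.8,
MSCT/CR 7.9) by calibrating its leaf payoffs — see `docs/methods.md`.

## Worked example

```
$ cea fixture --out model.json
$ cea run model.json
strategy   cost   qaly
      CR  32.00 7.9000
    CBCT  67.33 8.8504
    MSCT 106.23 7.9504
```

Each strategy's expected cost equals its unit cost; expected QALYs at the
base-case prevalence 0.18 interpolate the calibrated disease-absent /
disease-present endpoints (CBCT: 0.82·8.8 + 0.18·9.08 = 8.8504).

```
$ cea compare model.json --wtp 30000
strategy  expected_cost  expected_qaly  icer_vs_reference ...  nmb_reported  dominated  rank
    CBCT          67.33         8.8504          37.173822 ...          8.84      False     1
    MSCT         106.23         7.9504        1472.817460 ...          7.94       True     2
      CR          32.00         7.9000                NaN ...          7.89      False     3
```

CBCT is optimal at 30,000 €/QALY and MSCT is dominated by CBCT (more
expensive, less effective). On the published per-strategy (cost, QALY) pairs
— i.e. the disease-present convention — the same statistics give the headline
numbers: ICER(CBCT vs CR) = (67.33−32)/(9.08−7.9) = 29.94 €/QALY, λ-scaled
NMB 9.07 (CBCT) and 7.89 (CR), incremental NMB 1.17:

```python
>>> import ceatree as ct
>>> cr, cbct = ct.StrategyOutcome("CR", 32, 7.9), ct.StrategyOutcome("CBCT", 67.33, 9.08)
>>> round(ct.icer(cr, cbct), 2), ct.nmb(cbct, 30000).reported, ct.nmb(cr, 30000).reported
(29.94, 9.07, 7.89)
```

Deterministic sensitivity analysis (`cea tornado model.json`) ranks fracture
prevalence and the CBCT unit cost as the two most influential parameters;
`cea psa model.json --n 10000 --seed 20200202 --out-dir psa/` writes the
draws, per-iteration outcomes and the acceptability curve, and
`cea microsim model.json --n 200000 --seed 7 --out cohort.csv` generates a
patient-level cohort whose per-strategy means converge to the rollback
expectations.

## Layout

- `ceatree.tree`, `ceatree.expressions`, `ceatree.params` — tree model,
  validation, rollback
- `ceatree.cea` — ICER / NMB / dominance / frontier / ranking
- `ceatree.utilities` — DASH→EQ-5D mapping, trajectories, QALYs, life tables
- `ceatree.sensitivity` — one-way sweeps, tornado, switch thresholds
- `ceatree.psa` — distribution fitting, Monte-Carlo PSA, CEAC, scatter
- `ceatree.microsim` — patient-level microsimulation oracle
- `ceatree.finger` — the bundled calibrated fracture model
- `ceatree.io`, `ceatree.cli` — JSON model format and the `cea` command
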