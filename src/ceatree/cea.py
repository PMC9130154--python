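"""Cost-effectiveness statistics: ICER, net monetary benefit, dominance, ranking.

Given per-strategy expected costs C (€) and effectiveness E (QALYs):

* ICER of a comparator against a reference is ``(C_c - C_r) / (E_c - E_r)``,
  in €/QALY; undefined when the QALY difference is zero.
* Net monetary benefit at a willingness-to-pay threshold λ (€/QALY) is
  ``E·λ - C`` (monetary form, €).  Dividing through by λ gives the λ-scaled
  form ``E - C/λ`` in QALY units; published tables in this domain sometimes
  report the λ-scaled form truncated (not rounded) to two decimals, and
  :func:`truncate2` reproduces that convention.  The strategy with the highest
  NMB is optimal at λ — the two forms agree on the ordering.
* A strategy is dominated when another is both cheaper and more effective;
  extended dominance removes strategies bypassed by a convex combination of
  two others on the cost-effectiveness frontier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .tree import StrategyOutcome


class UndefinedICERError(ZeroDivisionError):
    """ICER requested between strategies with equal effectiveness."""


def truncate2(x: float) -> float:
    """Truncate toward zero to 2 decimals (9.0776 -> 9.07), the table-reporting
    convention for λ-scaled NMB."""
    return math.trunc(x * 100.0) / 100.0


def icer(reference: StrategyOutcome, comparator: StrategyOutcome) -> float:
    """Incremental cost-effectiveness ratio of ``comparator`` vs ``reference`` (€/QALY).

    The sign is preserved: a negative ICER (one strategy cheaper and more
    effective) is returned as-is and should be read together with the
    dominance flags, never in isolation.
    """
    d_qaly = comparator.expected_qaly - reference.expected_qaly
    if d_qaly == 0.0:
        raise UndefinedICERError(
            f"ICER undefined: {comparator.strategy!r} and {reference.strategy!r} "
            "have equal expected QALYs"
        )
    return (comparator.expected_cost - reference.expected_cost) / d_qaly


class NMB(NamedTuple):
    """Net monetary benefit in both conventions, plus the table-reporting form."""

    monetary: float  # E*λ - C, in €
    per_qaly: float  # E - C/λ, in QALYs (λ-scaled)
    reported: float  # λ-scaled form truncated to 2 decimals


def nmb(outcome: StrategyOutcome, wtp: float) -> NMB:
    """Net monetary benefit of an outcome at willingness-to-pay ``wtp`` (€/QALY)."""
    if wtp <= 0:
        raise ValueError(f"willingness-to-pay threshold must be positive, got {wtp}")
    monetary = outcome.expected_qaly * wtp - outcome.expected_cost
    per_qaly = outcome.expected_qaly - outcome.expected_cost / wtp
    return NMB(monetary, per_qaly, truncate2(per_qaly))


def _strictly_dominates(a: StrategyOutcome, b: StrategyOutcome) -> bool:
    """True when ``a`` is at least as cheap and as effective as ``b``, and
    strictly better on one axis."""
    return (
        a.expected_cost <= b.expected_cost
        and a.expected_qaly >= b.expected_qaly
        and (a.expected_cost < b.expected_cost or a.expected_qaly > b.expected_qaly)
    )


@dataclass
class CEAEntry:
    """One row of a cost-effectiveness comparison table."""

    strategy: str
    expected_cost: float
    expected_qaly: float
    icer_vs_reference: float | None  # None for the reference / undefined
    nmb_monetary: float
    nmb: float  # λ-scaled, full precision
    nmb_reported: float  # λ-scaled, truncated to 2 decimals
    incremental_nmb: float  # λ-scaled, vs reference
    dominated: bool
    dominated_by: str | None
    rank: int


@dataclass
class CEATable:
    """Comparison of strategies at one willingness-to-pay threshold."""

    wtp: float
    reference: str
    entries: list[CEAEntry]

    def entry(self, strategy: str) -> CEAEntry:
        for e in self.entries:
            if e.strategy == strategy:
                return e
        raise KeyError(strategy)

    def optimal(self) -> CEAEntry:
        return next(e for e in self.entries if e.rank == 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": e.strategy,
                    "expected_cost": e.expected_cost,
                    "expected_qaly": e.expected_qaly,
                    "icer_vs_reference": e.icer_vs_reference,
                    "nmb_monetary": e.nmb_monetary,
                    "nmb": e.nmb,
                    "nmb_reported": e.nmb_reported,
                    "incremental_nmb": e.incremental_nmb,
                    "dominated": e.dominated,
                    "dominated_by": e.dominated_by,
                    "rank": e.rank,
                }
                for e in self.entries
            ]
        )


def rank_strategies(
    outcomes: Sequence[StrategyOutcome],
    wtp: float,
    reference: str | None = None,
) -> CEATable:
    """Rank strategies by net monetary benefit at threshold ``wtp``.

    The reference for ICERs and incremental NMB defaults to the lowest-cost
    strategy (ties broken by name).  Rank 1 is the NMB-maximal strategy; NMB
    ties break deterministically by strategy name.  A strategy strictly
    dominated by another (higher cost, lower QALYs) is flagged.
    """
    if len(outcomes) < 2:
        raise ValueError("ranking requires at least two strategies")
    by_name = {o.strategy: o for o in outcomes}
    if len(by_name) != len(outcomes):
        raise ValueError("strategy names must be unique")
    if reference is None:
        reference = min(outcomes, key=lambda o: (o.expected_cost, o.strategy)).strategy
    ref = by_name[reference]
    ref_nmb = nmb(ref, wtp)

    order = sorted(outcomes, key=lambda o: (-nmb(o, wtp).per_qaly, o.strategy))
    ranks = {o.strategy: i + 1 for i, o in enumerate(order)}

    entries = []
    for o in outcomes:
        dominator = next(
            (
                other.strategy
                for other in sorted(outcomes, key=lambda x: x.strategy)
                if other.strategy != o.strategy
                and other.expected_cost < o.expected_cost
                and other.expected_qaly > o.expected_qaly
            ),
            None,
        )
        if o.strategy == reference:
            this_icer = None
        else:
            try:
                this_icer = icer(ref, o)
            except UndefinedICERError:
                this_icer = None
        m = nmb(o, wtp)
        entries.append(
            CEAEntry(
                strategy=o.strategy,
                expected_cost=o.expected_cost,
                expected_qaly=o.expected_qaly,
                icer_vs_reference=this_icer,
                nmb_monetary=m.monetary,
                nmb=m.per_qaly,
                nmb_reported=m.reported,
                incremental_nmb=m.per_qaly - ref_nmb.per_qaly,
                dominated=dominator is not None,
                dominated_by=dominator,
                rank=ranks[o.strategy],
            )
        )
    entries.sort(key=lambda e: e.rank)
    return CEATable(wtp=wtp, reference=reference, entries=entries)


def frontier(outcomes: Sequence[StrategyOutcome]) -> list[StrategyOutcome]:
    """Cost-effectiveness frontier: strategies neither strictly nor extendedly
    dominated, sorted by increasing cost.  ICERs between consecutive frontier
    strategies are increasing.  Outcomes with identical (cost, QALY) pairs are
    tied and all retained."""
    if not outcomes:
        raise ValueError("frontier requires at least one strategy")
    # Strict dominance (weak-inequality form, so exact ties survive).
    survivors = [
        o
        for o in outcomes
        if not any(
            other is not o
            and _strictly_dominates(other, o)
            and not (
                other.expected_cost == o.expected_cost
                and other.expected_qaly == o.expected_qaly
            )
            for other in outcomes
        )
    ]
    survivors.sort(key=lambda o: (o.expected_cost, o.expected_qaly, o.strategy))
    # Extended dominance: walking up by cost, ICERs must increase.
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            lo, mid, hi = survivors[i - 1], survivors[i], survivors[i + 1]
            try:
                if icer(lo, mid) > icer(mid, hi):
                    del survivors[i]
                    changed = True
                    break
            except UndefinedICERError:
                continue
    return survivors


def optimal_by_icer_rule(
    outcomes: Sequence[StrategyOutcome], wtp: float
) -> StrategyOutcome:
    """Frontier walk-up decision rule: starting from the cheapest frontier
    strategy, accept each successive frontier strategy whose ICER against the
    current choice is at most ``wtp``.  Equivalent to maximising NMB."""
    front = frontier(outcomes)
    current = front[0]
    for nxt in front[1:]:
        try:
            if icer(current, nxt) <= wtp:
                current = nxt
        except UndefinedICERError:
            # Same effectiveness: prefer the cheaper, i.e. keep current.
            continue
    return current
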