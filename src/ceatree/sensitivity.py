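"""Deterministic sensitivity analysis: one-way sweeps, tornado summaries,
strategy-switch thresholds.

One-way analysis re-evaluates the tree over a grid of values for a single
parameter, all others held at their point estimates.  A tornado diagram sweeps
every uncertain parameter to the ends of its plausible range and ranks
parameters by the width of the induced swing in a scalar outcome (here the
λ-scaled net monetary benefit — or, optionally, the expected QALYs — of the
base-case optimal strategy).  A switch threshold is the parameter value at
which the identity of the NMB-optimal strategy changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cea import nmb
from .tree import DecisionTree, evaluate, rollback

SWITCH_TOL = 1e-9


@dataclass
class TornadoEntry:
    """One bar of a tornado diagram."""

    parameter: str
    low: float
    high: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def width(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def one_way(
    tree: DecisionTree,
    parameter: str,
    grid: Sequence[float],
    wtp: float,
    force: bool = False,
) -> pd.DataFrame:
    """Sweep one parameter over ``grid``, all others at point estimates.

    Returns a tidy frame with one row per (grid value, strategy):
    ``value, strategy, expected_cost, expected_qaly, nmb, optimal``.
    ``nmb`` is λ-scaled (QALY units).  Grid values outside the parameter's
    stated plausible range raise unless ``force=True`` (extrapolating a
    probability to 0 or 1 is a legitimate what-if, but should be deliberate).
    """
    if parameter not in tree.parameters:
        raise KeyError(f"unknown parameter {parameter!r}")
    spec = tree.parameters[parameter]
    if not force:
        for v in grid:
            if not (spec.low <= v <= spec.high):
                raise ValueError(
                    f"{parameter}={v} outside plausible range "
                    f"[{spec.low}, {spec.high}]; pass force=True to sweep anyway"
                )
    base_env = tree.point_estimates()
    rows = []
    for v in grid:
        env = dict(base_env, **{parameter: v})
        outcomes = evaluate(tree, env)
        scored = {
            s: (float(c), float(q), float(q) - float(c) / wtp)
            for s, (c, q) in outcomes.items()
        }
        best = max(scored, key=lambda s: (scored[s][2], s))
        for s in tree.strategies:
            c, q, m = scored[s]
            rows.append(
                {
                    "parameter": parameter,
                    "value": v,
                    "strategy": s,
                    "expected_cost": c,
                    "expected_qaly": q,
                    "nmb": m,
                    "optimal": s == best,
                }
            )
    return pd.DataFrame(rows)


def _optimal_strategy(tree: DecisionTree, wtp: float) -> str:
    base = rollback(tree)
    return max(
        base, key=lambda s: (nmb(base[s], wtp).per_qaly, s)
    )


def _outcome_for(
    tree: DecisionTree, env: dict, strategy: str, wtp: float, outcome: str
) -> float:
    c, q = evaluate(tree, env)[strategy]
    c, q = float(c), float(q)
    if outcome == "qaly":
        return q
    if outcome == "nmb":
        return q - c / wtp
    if outcome == "nmb_gap":
        scored = {
            s: float(qq) - float(cc) / wtp for s, (cc, qq) in evaluate(tree, env).items()
        }
        rival = max((v for s, v in scored.items() if s != strategy), default=0.0)
        return scored[strategy] - rival
    raise ValueError(f"unknown tornado outcome {outcome!r}")


def tornado(
    tree: DecisionTree,
    wtp: float,
    ranges: dict[str, tuple[float, float]] | None = None,
    outcome: str = "nmb",
    include_fixed: bool = False,
) -> list[TornadoEntry]:
    """Tornado analysis around the base-case optimal strategy.

    Each parameter is set to the ends of its range (default: the spec's
    ``(low, high)``), all others at point estimates, and the chosen outcome of
    the base-case optimal strategy is recomputed.  ``outcome`` is ``"nmb"``
    (λ-scaled NMB), ``"qaly"`` (expected QALYs) or ``"nmb_gap"`` (NMB lead
    over the best rival).  By default only uncertain parameters — those with a
    non-degenerate PSA distribution — are swept; parameters the analysis holds
    deterministic (``dist_family="fixed"``) are included only with
    ``include_fixed=True``.  Entries are sorted by width, widest first.
    """
    if ranges is None:
        ranges = {
            name: (spec.low, spec.high)
            for name, spec in tree.parameters.items()
            if include_fixed or spec.dist_family != "fixed"
        }
    for name in ranges:
        if name not in tree.parameters:
            raise KeyError(f"unknown parameter {name!r}")
    strategy = _optimal_strategy(tree, wtp)
    base_env = tree.point_estimates()
    entries = []
    for name, (lo, hi) in ranges.items():
        at_lo = _outcome_for(tree, dict(base_env, **{name: lo}), strategy, wtp, outcome)
        at_hi = _outcome_for(tree, dict(base_env, **{name: hi}), strategy, wtp, outcome)
        entries.append(TornadoEntry(name, lo, hi, at_lo, at_hi))
    entries.sort(key=lambda e: (-e.width, e.parameter))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "outcome_at_low": e.outcome_at_low,
                "outcome_at_high": e.outcome_at_high,
                "width": e.width,
            }
            for e in entries
        ]
    )


def _nmb_lead(tree: DecisionTree, env: dict, strategy: str, wtp: float) -> float:
    """λ-scaled NMB of ``strategy`` minus the best rival NMB under ``env``."""
    scored = {
        s: float(q) - float(c) / wtp for s, (c, q) in evaluate(tree, env).items()
    }
    rival = max(v for s, v in scored.items() if s != strategy)
    return scored[strategy] - rival


def switch_threshold(
    tree: DecisionTree,
    parameter: str,
    wtp: float,
    bounds: tuple[float, float] | None = None,
    tol: float = SWITCH_TOL,
) -> float | None:
    """Value of ``parameter`` at which the optimal strategy changes, or None.

    The lead of the base-case optimal strategy (its λ-scaled NMB minus the
    best rival's) is tracked over ``bounds`` (default: the parameter's
    plausible range).  If the lead changes sign, the crossing is returned: in
    closed form when the lead is affine in the parameter (verified by
    three-point collinearity), otherwise by bisection to absolute ``tol``.
    """
    if parameter not in tree.parameters:
        raise KeyError(f"unknown parameter {parameter!r}")
    spec = tree.parameters[parameter]
    lo, hi = bounds if bounds is not None else (spec.low, spec.high)
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    strategy = _optimal_strategy(tree, wtp)
    base_env = tree.point_estimates()

    def lead(x: float) -> float:
        return _nmb_lead(tree, dict(base_env, **{parameter: x}), strategy, wtp)

    g_lo, g_hi = lead(lo), lead(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if (g_lo > 0) == (g_hi > 0):
        return None
    mid = 0.5 * (lo + hi)
    g_mid = lead(mid)
    # Affine check: midpoint must interpolate the endpoints.
    if abs(g_mid - 0.5 * (g_lo + g_hi)) <= tol * max(1.0, abs(g_lo), abs(g_hi)):
        return lo + (hi - lo) * (-g_lo) / (g_hi - g_lo)
    a, b, g_a = lo, hi, g_lo
    while b - a > tol:
        m = 0.5 * (a + b)
        g_m = lead(m)
        if g_m == 0.0:
            return m
        if (g_m > 0) == (g_a > 0):
            a, g_a = m, g_m
        else:
            b = m
    return 0.5 * (a + b)
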