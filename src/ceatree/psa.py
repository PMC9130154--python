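"""Probabilistic sensitivity analysis: second-order distributions, Monte-Carlo
propagation, acceptability curves, incremental scatter.

Parameter uncertainty is expressed through moment-matched second-order
distributions: probabilities and utilities take beta distributions (bounded by
0 and 1), costs take gamma distributions (non-negative), and parameters the
analysis holds deterministic are degenerate.  Each PSA iteration draws one
joint parameter vector, rolls the tree back under it, and stores per-strategy
costs and QALYs.  The cost-effectiveness acceptability curve (CEAC) then
reports, for each willingness-to-pay value λ, the fraction of iterations in
which each strategy attains the maximal net monetary benefit — all λ values
are evaluated on the same draws, so curves are comparable across thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ParameterSpec
from .tree import DecisionTree, TreeStructureError, chance_probabilities, evaluate, validate_tree

MAX_REJECTION_ROUNDS = 1000


class InfeasibleDispersionError(ValueError):
    """The requested (mean, relative SE) pair admits no beta distribution."""


@dataclass(frozen=True)
class Sampler:
    """A fitted second-order distribution for one parameter."""

    family: str  # "beta" | "gamma" | "fixed"
    mean: float
    sd: float
    a: float = 0.0  # beta alpha / gamma shape
    b: float = 0.0  # beta beta / gamma scale

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.mean)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=n)
        if self.family == "gamma":
            return rng.gamma(shape=self.a, scale=self.b, size=n)
        raise ValueError(f"unknown family {self.family!r}")


def fit_distribution(spec: ParameterSpec) -> Sampler:
    """Moment-match a sampler to a parameter's (mean, relative SE).

    beta: with mean m and sd s, ``ν = m(1-m)/s² - 1``, ``α = mν``, ``β = (1-m)ν``
    (requires ``s² < m(1-m)``, otherwise no beta distribution has these moments).
    gamma: ``shape = 1/dispersion²``, ``scale = m·dispersion²``.
    fixed: degenerate at the point estimate.
    """
    m = spec.point_estimate
    if spec.dist_family == "fixed":
        return Sampler("fixed", m, 0.0)
    if spec.dispersion <= 0:
        raise InfeasibleDispersionError(
            f"{spec.name}: {spec.dist_family} sampling needs dispersion > 0"
        )
    s = spec.dispersion * m
    if spec.dist_family == "beta":
        if m <= 0.0 or m >= 1.0:
            # A boundary mean admits no beta spread; treat as degenerate only
            # if explicitly fixed — here it is an error.
            raise InfeasibleDispersionError(
                f"{spec.name}: beta mean must lie strictly in (0, 1), got {m}"
            )
        if s * s >= m * (1.0 - m):
            raise InfeasibleDispersionError(
                f"{spec.name}: sd {s:.4g} infeasible for beta mean {m:.4g} "
                f"(requires s² < m(1-m) = {m * (1 - m):.4g})"
            )
        nu = m * (1.0 - m) / (s * s) - 1.0
        return Sampler("beta", m, s, a=m * nu, b=(1.0 - m) * nu)
    if spec.dist_family == "gamma":
        if m <= 0.0:
            raise InfeasibleDispersionError(
                f"{spec.name}: gamma mean must be positive, got {m}"
            )
        shape = 1.0 / (spec.dispersion**2)
        return Sampler("gamma", m, s, a=shape, b=m * spec.dispersion**2)
    raise ValueError(f"unknown dist_family {spec.dist_family!r}")


@dataclass
class PSAResult:
    """Draws and per-iteration, per-strategy outcomes of one PSA run."""

    n_iterations: int
    seed: int
    strategies: list[str]
    parameter_names: list[str]
    draws: pd.DataFrame  # n_iterations × parameters
    costs: np.ndarray  # (n_iterations, n_strategies), €
    qalys: np.ndarray  # (n_iterations, n_strategies), unconditional QALYs
    qalys_disease_present: np.ndarray | None  # conditional on disease, or None
    n_rejected: int = 0

    def strategy_index(self, strategy: str) -> int:
        return self.strategies.index(strategy)

    def outcomes_frame(self) -> pd.DataFrame:
        rows = {
            "iteration": np.repeat(np.arange(self.n_iterations), len(self.strategies)),
            "strategy": np.tile(self.strategies, self.n_iterations),
            "cost": self.costs.ravel(),
            "qaly": self.qalys.ravel(),
        }
        if self.qalys_disease_present is not None:
            rows["qaly_disease_present"] = self.qalys_disease_present.ravel()
        return pd.DataFrame(rows)

    def _measure(self, measure: str) -> np.ndarray:
        if measure == "qaly":
            return self.qalys
        if measure == "disease_present":
            if self.qalys_disease_present is None:
                raise ValueError("result carries no disease-present conditional QALYs")
            return self.qalys_disease_present
        raise ValueError(f"unknown effectiveness measure {measure!r}")


def run_psa(
    tree: DecisionTree,
    n: int,
    seed: int,
    disease_parameter: str | None = "prevalence",
) -> PSAResult:
    """Draw ``n`` joint parameter vectors and roll the tree back under each.

    Parameters with a degenerate (``fixed``) family stay at their point
    estimates.  A draw under which any chance-node probability leaves [0, 1]
    is rejected and redrawn (the count is recorded); with beta-distributed
    probabilities this cannot trigger, but composite probability expressions
    can escape the unit interval.

    If ``disease_parameter`` names a parameter of the tree, each iteration
    additionally records effectiveness conditional on disease being present
    (that parameter forced to 1, all other draws unchanged) — the convention
    in which the published strategy-level QALYs of this model family are
    reported.  The run is bit-for-bit reproducible from ``(seed, n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    violations = validate_tree(tree)
    if violations:
        raise TreeStructureError("; ".join(violations))
    samplers = {name: fit_distribution(spec) for name, spec in tree.parameters.items()}
    names = list(tree.parameters)
    rng = np.random.default_rng(seed)

    draws = {name: samplers[name].sample(rng, n) for name in names}
    n_rejected = 0
    for _ in range(MAX_REJECTION_ROUNDS):
        bad = np.zeros(n, dtype=bool)
        for _, _, p in chance_probabilities(tree, draws):
            p = np.broadcast_to(np.asarray(p, dtype=float), (n,))
            bad |= (p < 0.0) | (p > 1.0)
        if not bad.any():
            break
        idx = np.flatnonzero(bad)
        n_rejected += idx.size
        for name in names:
            redrawn = samplers[name].sample(rng, idx.size)
            draws[name][idx] = redrawn
    else:
        raise RuntimeError(
            "rejection sampling failed to produce admissible chance probabilities"
        )

    outcomes = evaluate(tree, draws)
    strategies = tree.strategies
    costs = np.column_stack(
        [np.broadcast_to(np.asarray(outcomes[s][0], dtype=float), (n,)) for s in strategies]
    )
    qalys = np.column_stack(
        [np.broadcast_to(np.asarray(outcomes[s][1], dtype=float), (n,)) for s in strategies]
    )
    qalys_dpos = None
    if disease_parameter is not None and disease_parameter in tree.parameters:
        env = dict(draws)
        env[disease_parameter] = 1.0
        cond = evaluate(tree, env)
        qalys_dpos = np.column_stack(
            [np.broadcast_to(np.asarray(cond[s][1], dtype=float), (n,)) for s in strategies]
        )
    return PSAResult(
        n_iterations=n,
        seed=seed,
        strategies=list(strategies),
        parameter_names=names,
        draws=pd.DataFrame(draws),
        costs=costs,
        qalys=qalys,
        qalys_disease_present=qalys_dpos,
        n_rejected=n_rejected,
    )


def ceac(
    result: PSAResult,
    wtp_grid: Sequence[float],
    measure: str = "qaly",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over ``wtp_grid``.

    For each λ, the fraction of iterations in which each strategy attains the
    maximal net monetary benefit (monetary form ``E·λ - C``, well defined at
    λ = 0 where the cheapest strategy wins).  Exact NMB ties within an
    iteration split the probability mass equally, so the probabilities at
    every λ sum to one.  All λ values reuse the same draws.
    """
    if len(wtp_grid) == 0:
        raise ValueError("empty willingness-to-pay grid")
    eff = result._measure(measure)
    rows = []
    for lam in wtp_grid:
        score = eff * lam - result.costs
        best = score.max(axis=1, keepdims=True)
        is_best = score == best
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        rows.append({"wtp": lam, **dict(zip(result.strategies, probs))})
    return pd.DataFrame(rows)


def probability_optimal(
    result: PSAResult, strategy: str, wtp: float, measure: str = "qaly"
) -> float:
    """Probability that ``strategy`` is NMB-optimal at one threshold."""
    curve = ceac(result, [wtp], measure=measure)
    return float(curve[strategy].iloc[0])


def incremental_scatter(
    result: PSAResult, reference: str, measure: str = "qaly"
) -> pd.DataFrame:
    """Per-iteration (ΔQALY, Δcost) pairs of every strategy vs ``reference``,
    for cost-effectiveness-plane plots."""
    if reference not in result.strategies:
        raise KeyError(f"reference strategy {reference!r} not in result")
    eff = result._measure(measure)
    r = result.strategy_index(reference)
    frames = []
    for s in result.strategies:
        if s == reference:
            continue
        j = result.strategy_index(s)
        frames.append(
            pd.DataFrame(
                {
                    "strategy": s,
                    "iteration": np.arange(result.n_iterations),
                    "delta_qaly": eff[:, j] - eff[:, r],
                    "delta_cost": result.costs[:, j] - result.costs[:, r],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_wtp_grid(stop: float = 50_000.0, step: float = 500.0) -> np.ndarray:
    """λ grid 0..stop inclusive (default 0–50,000 € by 500 €)."""
    return np.arange(0.0, stop + step / 2, step)
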