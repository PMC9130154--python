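"""Health-utility machinery: DASH→EQ-5D mapping, utility trajectories, QALYs.

Hand function after a finger fracture is usually measured with the DASH
questionnaire (Disabilities of the Arm, Shoulder and Hand), while economic
models need a preference-based utility on the EQ-5D scale (0 = dead,
1 = full health).  The bridge is a linear mapping fitted on a population with
comparable injuries: the predicted EQ-5D index is a linear combination of the
pre-injury EQ-5D score, the DASH pain component, the EQ-5D function component
and their product, clamped to [0, 1].

QALYs accumulate as utility × time: a trajectory is an ordered list of health
states, each with a utility and a duration in years, and its QALY total is the
sum of the products (optionally discounted).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class MappingCoefficients:
    """Coefficients of the linear DASH→EQ-5D mapping.

    The predictor is ``intercept + b_eq5d_pre * eq5d_pre + b_dash_pain *
    dash_pain + b_eq5d_function * eq5d_function + b_interaction * (dash_pain *
    eq5d_function)``.  ``provenance`` records where a named coefficient set
    came from.
    """

    intercept: float
    beta_eq5d_pre: float
    beta_dash_pain: float
    beta_eq5d_function: float
    beta_interaction: float
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for name in (
            "intercept",
            "beta_eq5d_pre",
            "beta_dash_pain",
            "beta_eq5d_function",
            "beta_interaction",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"mapping coefficient {name} must be finite")


def map_dash_to_eq5d(
    eq5d_pre: float,
    dash_pain: float,
    eq5d_function: float,
    coefficients: MappingCoefficients,
):
    """Predicted EQ-5D utility index, clamped to [0, 1].  Accepts arrays."""
    predictor = (
        coefficients.intercept
        + coefficients.beta_eq5d_pre * np.asarray(eq5d_pre, dtype=float)
        + coefficients.beta_dash_pain * np.asarray(dash_pain, dtype=float)
        + coefficients.beta_eq5d_function * np.asarray(eq5d_function, dtype=float)
        + coefficients.beta_interaction
        * np.asarray(dash_pain, dtype=float)
        * np.asarray(eq5d_function, dtype=float)
    )
    clamped = np.clip(predictor, 0.0, 1.0)
    return float(clamped) if clamped.ndim == 0 else clamped


@dataclass
class UtilityTrajectory:
    """Ordered health-state segments of (utility in [0, 1], duration in years)."""

    segments: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for utility, duration in self.segments:
            if not (0.0 <= utility <= 1.0):
                raise ValueError(f"utility {utility} outside [0, 1]")
            if duration <= 0:
                raise ValueError(f"segment duration must be > 0, got {duration}")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)

    def check_against_life_expectancy(self, remaining: float) -> None:
        if self.total_duration > remaining + 1e-12:
            raise ValueError(
                f"trajectory spans {self.total_duration:.4g} years but only "
                f"{remaining:.4g} remaining years are available"
            )


def qalys(trajectory: UtilityTrajectory, discount_rate: float = 0.0) -> float:
    """Quality-adjusted life years of a trajectory: Σ utility × duration.

    With a positive annual ``discount_rate`` r each segment contributes its
    continuously discounted integral ``u * (e^{-r t0} - e^{-r t1}) / r``.  The
    default is no discounting.
    """
    if discount_rate < 0:
        raise ValueError("discount rate must be >= 0")
    if discount_rate == 0.0:
        return sum(u * d for u, d in trajectory.segments)
    total = 0.0
    t = 0.0
    r = discount_rate
    for u, d in trajectory.segments:
        total += u * (math.exp(-r * t) - math.exp(-r * (t + d))) / r
        t += d
    return total


class LifeTable:
    """Remaining life expectancy by age, with linear interpolation between knots."""

    def __init__(self, ages: Sequence[float], remaining: Sequence[float]):
        ages = np.asarray(ages, dtype=float)
        remaining = np.asarray(remaining, dtype=float)
        if ages.ndim != 1 or ages.shape != remaining.shape or ages.size < 2:
            raise ValueError("life table needs matching 1-d age/remaining arrays (>= 2 knots)")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("life-table ages must be strictly increasing")
        self.ages = ages
        self.remaining = remaining

    def remaining_years(self, age: float) -> float:
        """Remaining life expectancy at ``age`` (linear between tabulated ages)."""
        if not (self.ages[0] <= age <= self.ages[-1]):
            raise ValueError(
                f"age {age} outside life-table domain "
                f"[{self.ages[0]:g}, {self.ages[-1]:g}]"
            )
        return float(np.interp(age, self.ages, self.remaining))

    @classmethod
    def from_json(cls, obj: dict) -> "LifeTable":
        return cls(obj["ages"], obj["remaining_years"])


def remaining_years(age: float, life_table: LifeTable) -> float:
    """Functional form of :meth:`LifeTable.remaining_years`."""
    return life_table.remaining_years(age)


def _load_data(filename: str) -> dict:
    with resources.files("ceatree.data").joinpath(filename).open() as fh:
        return json.load(fh)


def load_default_life_table() -> LifeTable:
    """Bundled European-style period life table (synthetic knots anchored at a
    remaining expectancy of 49.87 years at age 30 and 45 years at age 35)."""
    return LifeTable.from_json(_load_data("life_table.json"))


def load_default_mapping() -> MappingCoefficients:
    """Bundled placeholder DASH→EQ-5D coefficient set.

    The coefficients are synthetic (no published set exists for this injury);
    they are plausible in sign and scale but must be replaced with a fitted
    set for any real analysis.
    """
    d = _load_data("dash_eq5d_coefficients.json")
    return MappingCoefficients(
        intercept=d["intercept"],
        beta_eq5d_pre=d["beta_eq5d_pre"],
        beta_dash_pain=d["beta_dash_pain"],
        beta_eq5d_function=d["beta_eq5d_function"],
        beta_interaction=d["beta_interaction"],
        provenance=d.get("provenance", ""),
    )
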