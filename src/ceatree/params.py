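"""Model parameters: point estimates, plausible ranges, and PSA distribution families.

Every model input — a branch probability, a health-state utility, a unit cost —
is described by a :class:`ParameterSpec`.  The point estimate drives the base
case, the ``(low, high)`` range drives deterministic one-way sweeps, and the
distribution family plus relative standard error drive probabilistic
sensitivity analysis (probabilities and utilities take beta distributions,
which are bounded by [0, 1]; costs take gamma distributions, bounded below by
zero; ``fixed`` parameters are held deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

ROLES = frozenset({"probability", "utility", "cost", "other"})
DIST_FAMILIES = frozenset({"beta", "gamma", "fixed"})


class ParameterError(ValueError):
    """An inadmissible parameter specification."""


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input.

    Parameters
    ----------
    name : str
        Identifier used by tree expressions.
    point_estimate : float
        Base-case value.
    low, high : float
        Plausible range for deterministic sensitivity analysis;
        ``low <= point_estimate <= high``.
    role : {"probability", "utility", "cost", "other"}
        Semantic role; constrains admissible values and distribution family.
    dist_family : {"beta", "gamma", "fixed"}
        Second-order distribution used in probabilistic sensitivity analysis.
    dispersion : float
        Relative standard error (standard deviation as a fraction of the
        mean), dimensionless.  Ignored for ``fixed`` parameters.
    description : str
        Free-text provenance / meaning.
    """

    name: str
    point_estimate: float
    low: float
    high: float
    role: str = "other"
    dist_family: str = "fixed"
    dispersion: float = 0.0
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ParameterError("parameter name must be a non-empty string")
        if self.role not in ROLES:
            raise ParameterError(
                f"{self.name}: unknown role {self.role!r}; expected one of {sorted(ROLES)}"
            )
        if self.dist_family not in DIST_FAMILIES:
            raise ParameterError(
                f"{self.name}: unknown dist_family {self.dist_family!r}; "
                f"expected one of {sorted(DIST_FAMILIES)}"
            )
        if not (self.low <= self.point_estimate <= self.high):
            raise ParameterError(
                f"{self.name}: require low <= point_estimate <= high, "
                f"got ({self.low}, {self.point_estimate}, {self.high})"
            )
        if self.role in ("probability", "utility"):
            if not (0.0 <= self.point_estimate <= 1.0):
                raise ParameterError(
                    f"{self.name}: {self.role} point estimate must lie in [0, 1], "
                    f"got {self.point_estimate}"
                )
            if self.dist_family not in ("beta", "fixed"):
                raise ParameterError(
                    f"{self.name}: {self.role} parameters take beta or fixed "
                    f"distributions, not {self.dist_family}"
                )
        if self.role == "cost":
            if self.point_estimate < 0:
                raise ParameterError(
                    f"{self.name}: cost point estimate must be >= 0, "
                    f"got {self.point_estimate}"
                )
            if self.dist_family not in ("gamma", "fixed"):
                raise ParameterError(
                    f"{self.name}: cost parameters take gamma or fixed "
                    f"distributions, not {self.dist_family}"
                )
        if self.dispersion < 0:
            raise ParameterError(f"{self.name}: dispersion must be >= 0")

    def with_point(self, value: float) -> "ParameterSpec":
        """Copy of this spec with the point estimate (and, if the new value
        escapes the stated range, the range) moved to ``value``."""
        return replace(
            self,
            point_estimate=value,
            low=min(self.low, value),
            high=max(self.high, value),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "point_estimate": self.point_estimate,
            "low": self.low,
            "high": self.high,
            "role": self.role,
            "dist_family": self.dist_family,
            "dispersion": self.dispersion,
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpec":
        return cls(
            name=d["name"],
            point_estimate=float(d["point_estimate"]),
            low=float(d["low"]),
            high=float(d["high"]),
            role=d.get("role", "other"),
            dist_family=d.get("dist_family", "fixed"),
            dispersion=float(d.get("dispersion", 0.0)),
            description=d.get("description", ""),
        )
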