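"""A deliberately small expression language for tree probabilities and payoffs.

Branch probabilities and terminal payoffs are restricted to sums, products and
complements (``1 - x``) of parameter references and numeric literals.  This is
sufficient to express every probability that arises in a diagnostic decision
tree (joint probabilities are products, complements give the "other branch"),
and keeping the language closed makes model files auditable: an expression can
always be read off as a piece of probability arithmetic.

Expressions evaluate against an environment mapping parameter names to values.
Values may be scalars or NumPy arrays (all operations broadcast), which is how
the probabilistic sensitivity analysis evaluates thousands of parameter draws
in one pass.

JSON forms::

    0.18                                   # literal
    {"param": "prevalence"}                # parameter reference
    {"complement": {"param": "sens_cbct"}} # 1 - x
    {"product": [e1, e2, ...]}
    {"sum": [e1, e2, ...]}
"""

from __future__ import annotations

from typing import Iterable, Mapping, Union

Number = Union[int, float]


class UnboundParameterError(KeyError):
    """An expression referenced a parameter missing from the environment."""


class Expression:
    """Abstract base; concrete nodes implement eval/params/to_json."""

    def eval(self, env: Mapping[str, object]):
        raise NotImplementedError

    def params(self) -> set[str]:
        raise NotImplementedError

    def to_json(self):
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"{type(self).__name__}({self.to_json()!r})"


class Const(Expression):
    def __init__(self, value: Number):
        self.value = float(value)

    def eval(self, env):
        return self.value

    def params(self):
        return set()

    def to_json(self):
        return self.value


class Param(Expression):
    def __init__(self, name: str):
        self.name = name

    def eval(self, env):
        try:
            return env[self.name]
        except KeyError as exc:
            raise UnboundParameterError(self.name) from exc

    def params(self):
        return {self.name}

    def to_json(self):
        return {"param": self.name}


class Complement(Expression):
    """``1 - inner``; the probability of the opposite branch."""

    def __init__(self, inner: Expression):
        self.inner = as_expression(inner)

    def eval(self, env):
        return 1.0 - self.inner.eval(env)

    def params(self):
        return self.inner.params()

    def to_json(self):
        return {"complement": self.inner.to_json()}


class Product(Expression):
    def __init__(self, factors: Iterable):
        self.factors = [as_expression(f) for f in factors]

    def eval(self, env):
        out = 1.0
        for f in self.factors:
            out = out * f.eval(env)
        return out

    def params(self):
        return set().union(*(f.params() for f in self.factors)) if self.factors else set()

    def to_json(self):
        return {"product": [f.to_json() for f in self.factors]}


class Sum(Expression):
    def __init__(self, terms: Iterable):
        self.terms = [as_expression(t) for t in terms]

    def eval(self, env):
        out = 0.0
        for t in self.terms:
            out = out + t.eval(env)
        return out

    def params(self):
        return set().union(*(t.params() for t in self.terms)) if self.terms else set()

    def to_json(self):
        return {"sum": [t.to_json() for t in self.terms]}


def as_expression(obj) -> Expression:
    """Coerce a number, parameter name, Expression or JSON form to an Expression."""
    if isinstance(obj, Expression):
        return obj
    if isinstance(obj, (int, float)):
        return Const(obj)
    if isinstance(obj, str):
        return Param(obj)
    if isinstance(obj, Mapping):
        return from_json(obj)
    raise TypeError(f"cannot interpret {obj!r} as an expression")


def from_json(obj) -> Expression:
    """Parse the JSON form of an expression."""
    if isinstance(obj, (int, float)):
        return Const(obj)
    if isinstance(obj, Mapping):
        if len(obj) != 1:
            raise ValueError(f"expression object must have exactly one key: {obj!r}")
        (key, val), = obj.items()
        if key == "param":
            return Param(val)
        if key == "complement":
            return Complement(from_json(val))
        if key == "product":
            return Product(from_json(v) for v in val)
        if key == "sum":
            return Sum(from_json(v) for v in val)
        raise ValueError(f"unknown expression operator {key!r}")
    raise ValueError(f"cannot parse expression from {obj!r}")


# Short constructors, convenient when building trees in code.
def P(name: str) -> Param:
    return Param(name)


def one_minus(expr) -> Complement:
    return Complement(expr)
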