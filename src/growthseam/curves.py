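"""Single-phase growth-curve families.

Each family is a frozen dataclass of parameters with eager validation,
plus closed-form evaluation, an analytic first derivative, and (where the
curve is strictly monotone) an analytic inverse.  Ages are in months of
exactly 28 days for every family except the linear pouch head-growth
model and the legacy log-hyperbola, which operate on days; each parameter
record carries its ``age_unit`` so downstream reports stay explicit.

The logistic family is the "four-parameter" Verhulst form

    L(t) = A + K*L0 / ((K - L0) * exp(-r*t) + L0)

i.e. a lower-asymptote offset ``A`` plus a three-parameter logistic core
whose span is ``K``: the curve runs from ``A + L0`` at birth to the upper
asymptote ``A + K``, with inflection at ``A + K/2`` and maximum slope
``r*K/4``.  ``A`` may be negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import ClassVar, Union

import numpy as np

__all__ = [
    "ParameterDomainError",
    "CurveDomainError",
    "LogisticParams",
    "BrodyParams",
    "BrodyOffsetParams",
    "VonBertalanffyParams",
    "LinearParams",
    "PostPouchHyperbolaParams",
    "CurveParams",
    "FAMILIES",
    "eval_curve",
    "eval_logistic",
    "eval_brody",
    "eval_brody_offset",
    "eval_von_bertalanffy",
    "eval_linear",
    "eval_log_hyperbola",
    "slope",
    "params_from_dict",
]

#: guard tolerance for near-degenerate logistic cores (L0 -> K)
_DEGENERACY_RTOL = 1e-9


class ParameterDomainError(ValueError):
    """A parameter record violates its family's domain invariants."""


class CurveDomainError(ValueError):
    """An age lies outside the curve's domain."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterDomainError(msg)


def _finite(*values: float) -> bool:
    return all(math.isfinite(v) for v in values)


@dataclass(frozen=True)
class _Params:
    """Shared plumbing: field order, dict round-trip, array access."""

    family: ClassVar[str] = ""
    age_unit: ClassVar[str] = "month28"

    @classmethod
    def param_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.param_names()], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "_Params":
        return cls(*(float(v) for v in theta))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": {n: float(getattr(self, n)) for n in self.param_names()},
            "age_unit": self.age_unit,
        }

    def evaluate(self, age):
        raise NotImplementedError

    def slope(self, age):
        raise NotImplementedError

    def asymptote(self) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class LogisticParams(_Params):
    """Verhulst logistic with lower-asymptote offset.

    A: lower asymptote (mm; may be negative); K: logistic span (mm);
    L0: core value at age 0 (mm), 0 < L0 < K; r: intrinsic rate (per month).
    """

    A: float
    K: float
    L0: float
    r: float

    family: ClassVar[str] = "logistic"

    def __post_init__(self):
        _require(_finite(self.A, self.K, self.L0, self.r), "non-finite parameter")
        _require(self.K > 0, f"K must be > 0, got {self.K}")
        _require(self.L0 > 0, f"L0 must be > 0, got {self.L0}")
        _require(
            self.L0 < self.K * (1.0 - _DEGENERACY_RTOL),
            f"L0 must be < K (got L0={self.L0}, K={self.K})",
        )
        _require(self.r > 0, f"r must be > 0, got {self.r}")

    def core(self, age):
        """Offset-free logistic core K*L0 / ((K-L0) e^{-r t} + L0)."""
        age = np.asarray(age, dtype=float)
        return self.K * self.L0 / ((self.K - self.L0) * np.exp(-self.r * age) + self.L0)

    def evaluate(self, age):
        return self.A + self.core(age)

    def slope(self, age):
        core = self.core(age)
        return self.r * core * (1.0 - core / self.K)

    def asymptote(self) -> float:
        return self.A + self.K

    @property
    def inflection_age(self) -> float:
        """Age of maximum growth rate, ln((K-L0)/L0)/r."""
        return math.log((self.K - self.L0) / self.L0) / self.r

    @property
    def inflection_value(self) -> float:
        """Measurement at the inflection point, A + K/2."""
        return self.A + self.K / 2.0

    @property
    def max_slope(self) -> float:
        """Maximum growth rate r*K/4."""
        return self.r * self.K / 4.0

    def inverse(self, value: float) -> float:
        lo, hi = self.A + self.L0, self.asymptote()
        if not (lo <= value < hi):
            raise CurveDomainError(
                f"value {value} outside invertible range [{lo}, {hi})"
            )
        core = value - self.A
        return -math.log(self.L0 * (self.K - core) / (core * (self.K - self.L0))) / self.r


@dataclass(frozen=True)
class BrodyParams(_Params):
    """Brody (monomolecular) curve B*(1 - C*exp(-k*age)).

    B: mature asymptote (mm); C: adjustment for L(0) != 0, in [0, 1);
    k: maturing rate index (per month).
    """

    B: float
    C: float
    k: float

    family: ClassVar[str] = "brody"

    def __post_init__(self):
        _require(_finite(self.B, self.C, self.k), "non-finite parameter")
        _require(self.B > 0, f"B must be > 0, got {self.B}")
        _require(0 <= self.C < 1, f"C must be in [0, 1), got {self.C}")
        _require(self.k > 0, f"k must be > 0, got {self.k}")

    def evaluate(self, age):
        age = np.asarray(age, dtype=float)
        return self.B * (1.0 - self.C * np.exp(-self.k * age))

    def slope(self, age):
        age = np.asarray(age, dtype=float)
        return self.B * self.C * self.k * np.exp(-self.k * age)

    def asymptote(self) -> float:
        return self.B

    def inverse(self, value: float) -> float:
        lo = self.B * (1.0 - self.C)
        if not (lo <= value < self.B):
            raise CurveDomainError(
                f"value {value} outside invertible range [{lo}, {self.B})"
            )
        if self.C == 0:
            raise CurveDomainError("constant curve (C=0) is not invertible")
        return -math.log((1.0 - value / self.B) / self.C) / self.k


@dataclass(frozen=True)
class BrodyOffsetParams(_Params):
    """Offset Brody variant a + b*(1 - exp(-k*age)) used for whole-of-life fits."""

    a: float
    b: float
    k: float

    family: ClassVar[str] = "brody-offset"

    def __post_init__(self):
        _require(_finite(self.a, self.b, self.k), "non-finite parameter")
        _require(self.b > 0, f"b must be > 0, got {self.b}")
        _require(self.k > 0, f"k must be > 0, got {self.k}")

    def evaluate(self, age):
        age = np.asarray(age, dtype=float)
        return self.a + self.b * (1.0 - np.exp(-self.k * age))

    def slope(self, age):
        age = np.asarray(age, dtype=float)
        return self.b * self.k * np.exp(-self.k * age)

    def asymptote(self) -> float:
        return self.a + self.b

    def inverse(self, value: float) -> float:
        hi = self.a + self.b
        if not (self.a <= value < hi):
            raise CurveDomainError(
                f"value {value} outside invertible range [{self.a}, {hi})"
            )
        return -math.log(1.0 - (value - self.a) / self.b) / self.k


@dataclass(frozen=True)
class VonBertalanffyParams(_Params):
    """von Bertalanffy growth, the solution of dL/dt = a - b*L with L(0) = L0.

    Closed form a/b - (a/b - L0)*exp(-b*age); asymptote a/b; no inflection.
    """

    L0: float
    a: float
    b: float

    family: ClassVar[str] = "vb"

    def __post_init__(self):
        _require(_finite(self.L0, self.a, self.b), "non-finite parameter")
        _require(self.a > 0, f"a must be > 0, got {self.a}")
        _require(self.b > 0, f"b must be > 0, got {self.b}")
        _require(self.a / self.b > self.L0, "asymptote a/b must exceed L0")

    def evaluate(self, age):
        age = np.asarray(age, dtype=float)
        linf = self.a / self.b
        return linf - (linf - self.L0) * np.exp(-self.b * age)

    def slope(self, age):
        age = np.asarray(age, dtype=float)
        return self.b * (self.a / self.b - self.L0) * np.exp(-self.b * age)

    def asymptote(self) -> float:
        return self.a / self.b

    def inverse(self, value: float) -> float:
        linf = self.a / self.b
        if not (self.L0 <= value < linf):
            raise CurveDomainError(
                f"value {value} outside invertible range [{self.L0}, {linf})"
            )
        return -math.log((linf - value) / (linf - self.L0)) / self.b


@dataclass(frozen=True)
class LinearParams(_Params):
    """Linear pouch head-growth model, intercept + slope*age with age in days."""

    intercept: float
    slope_per_day: float

    family: ClassVar[str] = "linear"
    age_unit: ClassVar[str] = "day"

    def __post_init__(self):
        _require(_finite(self.intercept, self.slope_per_day), "non-finite parameter")

    def evaluate(self, age):
        age = np.asarray(age, dtype=float)
        return self.intercept + self.slope_per_day * age

    def slope(self, age):
        age = np.asarray(age, dtype=float)
        return np.full_like(age, self.slope_per_day)

    def asymptote(self) -> float:
        return math.inf

    def inverse(self, value: float) -> float:
        if self.slope_per_day == 0:
            raise CurveDomainError("constant line is not invertible")
        return (value - self.intercept) / self.slope_per_day


@dataclass(frozen=True)
class PostPouchHyperbolaParams(_Params):
    """Legacy broken-stick post-pouch hyperbola on the log scale.

    ln m = b4 + b3/age - b3/j for age > j days; at the join age j the fitted
    log-measurement is b4, and the large-age limit is b4 - b3/j.
    """

    b3: float
    b4: float
    j: float

    family: ClassVar[str] = "hyperbola"
    age_unit: ClassVar[str] = "day"

    def __post_init__(self):
        _require(_finite(self.b3, self.b4, self.j), "non-finite parameter")
        _require(self.j > 0, f"join age j must be > 0, got {self.j}")

    def evaluate(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < self.j):
            raise CurveDomainError(f"log-hyperbola defined only for age >= j = {self.j}")
        return self.b4 + self.b3 / age - self.b3 / self.j

    def slope(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < self.j):
            raise CurveDomainError(f"log-hyperbola defined only for age >= j = {self.j}")
        return -self.b3 / age**2

    def asymptote(self) -> float:
        return self.b4 - self.b3 / self.j


CurveParams = Union[
    LogisticParams,
    BrodyParams,
    BrodyOffsetParams,
    VonBertalanffyParams,
    LinearParams,
    PostPouchHyperbolaParams,
]

FAMILIES: dict[str, type] = {
    cls.family: cls
    for cls in (
        LogisticParams,
        BrodyParams,
        BrodyOffsetParams,
        VonBertalanffyParams,
        LinearParams,
        PostPouchHyperbolaParams,
    )
}


def params_from_dict(d: dict) -> CurveParams:
    """Rebuild a parameter record from its ``to_dict`` serialization."""
    try:
        cls = FAMILIES[d["family"]]
    except KeyError as e:
        raise ParameterDomainError(f"unknown curve family {d.get('family')!r}") from e
    return cls(**d["params"])


def eval_curve(params: CurveParams, age):
    """Evaluate any family at ``age`` (scalar or array, in the family's unit)."""
    return params.evaluate(age)


def slope(params: CurveParams, age):
    """Analytic first derivative of any family at ``age``."""
    if not isinstance(params, tuple(FAMILIES.values())):
        raise ParameterDomainError(f"unknown curve family {type(params).__name__}")
    return params.slope(age)


# thin functional aliases, matching the family names used in reports
def eval_logistic(p: LogisticParams, age):
    return p.evaluate(age)


def eval_brody(p: BrodyParams, age):
    return p.evaluate(age)


def eval_brody_offset(p: BrodyOffsetParams, age):
    return p.evaluate(age)


def eval_von_bertalanffy(p: VonBertalanffyParams, age):
    return p.evaluate(age)


def eval_linear(p: LinearParams, age):
    return p.evaluate(age)


def eval_log_hyperbola(p: PostPouchHyperbolaParams, age):
    return p.evaluate(age)
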