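"""Smoothly-joining two-phase (SJ2P) growth model.

A Verhulst logistic pouch-phase curve and a Brody post-pouch curve are
composed into one lifetime curve that is continuous and once-differentiable
at the join age ``j`` (pouch vacation).  Six parameters are free —
``(C, K, L0, k, j, r)`` — and the two remaining constants are derived from
the smooth-join constraints:

* slope continuity fixes the Brody asymptote:  the logistic core slope
  ``s`` at ``j`` must equal the Brody slope ``B*C*k*exp(-k*j)``, so
  ``B = s * exp(k*j) / (C*k)``;
* value continuity then fixes the logistic offset:
  ``A = B*(1 - C*exp(-k*j)) - core(j)``.

The solve order is deliberate: the slope condition does not involve ``A``,
so the system is triangular and closed-form.  Because the logistic core
slope is strictly positive for valid parameters, ``B`` is positive whenever
the free parameters satisfy their domain; the infeasible-join error guards
only numeric underflow at extreme rate/age combinations.

The canonical age unit is the month of exactly 28 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import ClassVar

import numpy as np
from scipy.optimize import brentq

from .curves import BrodyParams, LogisticParams, ParameterDomainError, _finite, _require

__all__ = [
    "DAYS_PER_MONTH",
    "InfeasibleJoinError",
    "AgeingRangeError",
    "SJ2PFreeParams",
    "SJ2PModel",
    "derive_joined",
    "eval_sj2p",
    "slope_sj2p",
    "invert_sj2p",
    "months_to_days",
    "days_to_months",
]

#: exact conversion used throughout (7.86 months == 220.08 days)
DAYS_PER_MONTH = 28.0


class InfeasibleJoinError(ValueError):
    """The smooth-join constraints admit no valid Brody phase."""


class AgeingRangeError(ValueError):
    """A measurement lies outside the model's invertible range."""


def months_to_days(age_months: float) -> float:
    """Convert an age in 28-day months to days (exact multiplication)."""
    if age_months < 0:
        raise ValueError(f"age must be >= 0, got {age_months}")
    return age_months * DAYS_PER_MONTH


def days_to_months(age_days: float) -> float:
    """Convert an age in days to 28-day months (exact division)."""
    if age_days < 0:
        raise ValueError(f"age must be >= 0, got {age_days}")
    return age_days / DAYS_PER_MONTH


@dataclass(frozen=True)
class SJ2PFreeParams:
    """The six free SJ2P parameters.

    C: Brody adjustment (dimensionless, 0 < C < 1); K: logistic span (mm);
    L0: logistic core value at birth (mm); k: Brody rate (per month);
    j: join age (months); r: logistic intrinsic rate (per month).
    """

    C: float
    K: float
    L0: float
    k: float
    j: float
    r: float

    names: ClassVar[tuple[str, ...]] = ("C", "K", "L0", "k", "j", "r")

    def __post_init__(self):
        _require(_finite(self.C, self.K, self.L0, self.k, self.j, self.r),
                 "non-finite parameter")
        _require(self.K > 0, f"K must be > 0, got {self.K}")
        _require(0 < self.L0 < self.K, f"need 0 < L0 < K, got L0={self.L0}, K={self.K}")
        _require(0 < self.C < 1, f"C must be in (0, 1), got {self.C}")
        _require(self.k > 0, f"k must be > 0, got {self.k}")
        _require(self.r > 0, f"r must be > 0, got {self.r}")
        _require(self.j > 0, f"j must be > 0, got {self.j}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "SJ2PFreeParams":
        return cls(*(float(v) for v in theta))


@dataclass(frozen=True)
class SJ2PModel:
    """A fully-derived SJ2P model: free parameters plus (A, B) from the join."""

    free: SJ2PFreeParams
    A: float  # derived logistic offset (mm)
    B: float  # derived Brody asymptote (mm)

    @property
    def logistic(self) -> LogisticParams:
        f = self.free
        return LogisticParams(A=self.A, K=f.K, L0=f.L0, r=f.r)

    @property
    def brody(self) -> BrodyParams:
        f = self.free
        return BrodyParams(B=self.B, C=f.C, k=f.k)

    def evaluate(self, age):
        return eval_sj2p(self, age)

    def slope(self, age):
        return slope_sj2p(self, age)

    def invert(self, length: float) -> float:
        return invert_sj2p(self, length)

    def to_dict(self) -> dict:
        f = self.free
        return {
            "free": {n: float(getattr(f, n)) for n in f.names},
            "derived": {"A": float(self.A), "B": float(self.B)},
            "age_unit": "month28",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SJ2PModel":
        model = derive_joined(SJ2PFreeParams(**d["free"]))
        return model


def derive_joined(free: SJ2PFreeParams) -> SJ2PModel:
    """Solve the smooth-join constraints for (A, B) given the six free parameters.

    Raises :class:`InfeasibleJoinError` when the logistic slope at the join
    underflows to zero or the implied Brody asymptote is non-positive.
    """
    C, K, L0, k, j, r = free.C, free.K, free.L0, free.k, free.j, free.r
    # logistic core and its slope at the join (independent of the offset A)
    denom = (K - L0) * math.exp(-r * j) + L0
    core_j = K * L0 / denom
    s = r * core_j * (1.0 - core_j / K)
    if not (s > 0.0 and math.isfinite(s)):
        raise InfeasibleJoinError(
            f"logistic slope at join is {s}; no Brody phase can match it"
        )
    B = s * math.exp(k * j) / (C * k)
    if not (B > 0.0 and math.isfinite(B)):
        raise InfeasibleJoinError(f"derived Brody asymptote B={B} is not positive")
    A = B * (1.0 - C * math.exp(-k * j)) - core_j
    return SJ2PModel(free=free, A=A, B=B)


def eval_sj2p(m: SJ2PModel, age):
    """Evaluate the joined curve: logistic branch for age <= j, Brody after."""
    age = np.asarray(age, dtype=float)
    left = m.logistic.evaluate(age)
    right = m.brody.evaluate(age)
    out = np.where(age <= m.free.j, left, right)
    return out if out.ndim else float(out)


def slope_sj2p(m: SJ2PModel, age):
    """Analytic growth rate of the joined curve (mm per month)."""
    age = np.asarray(age, dtype=float)
    left = m.logistic.slope(age)
    right = m.brody.slope(age)
    out = np.where(age <= m.free.j, left, right)
    return out if out.ndim else float(out)


def invert_sj2p(m: SJ2PModel, length: float) -> float:
    """Age an animal from a measurement: the unique age with curve(age) = length.

    Uses a deterministic bracketing root search; the bracket is chosen by
    comparing the measurement to the value at the join, so behaviour near
    the asymptote stays robust.
    """
    j, k = m.free.j, m.free.k
    at_birth = float(eval_sj2p(m, 0.0))
    if not (at_birth <= length < m.B):
        raise AgeingRangeError(
            f"measurement {length} mm is outside the ageing range "
            f"[{at_birth:.6g}, {m.B:.6g}) mm for this model"
        )
    at_join = float(eval_sj2p(m, j))
    if length == at_birth:
        return 0.0
    if math.isclose(length, at_join, rel_tol=0, abs_tol=1e-12):
        return j
    if length < at_join:
        lo, hi = 0.0, j
    else:
        lo, hi = j, j + 50.0 / k
        # extend if the Brody tail has not yet passed the target
        while eval_sj2p(m, hi) < length:
            hi += 50.0 / k
    return float(brentq(lambda t: eval_sj2p(m, t) - length, lo, hi, xtol=1e-10))
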