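"""Synthetic cross-sectional morphometric data.

The generator emulates the two-cohort study design behind the model: a
captive pouch-young cohort measured at known ages with low noise, plus a
cross-sectional cull cohort of post-weaned animals whose (molar-eruption)
ages carry much higher residual variability.  Noise is Gaussian,
homoscedastic within a cohort and heteroscedastic across cohorts, with the
standard deviations of the shipped scenarios set to the published phase
RMSEs.  Values are truncated below at 0.1 mm so every record satisfies the
positive-measurement invariant.

What this does not emulate: molar-eruption ageing error, sampling bias of
culls, cohort effects, or within-animal correlation — each record is an
independent animal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from .curves import CurveParams, LinearParams, ParameterDomainError
from .records import MorphRecord
from .sj2p import DAYS_PER_MONTH, SJ2PFreeParams, SJ2PModel, derive_joined

__all__ = ["Cohort", "SimConfig", "simulate_cross_sectional", "default_scenarios"]

_MIN_VALUE_MM = 0.1


@dataclass(frozen=True)
class Cohort:
    """One sampling cohort: size, age distribution, noise level, sex label."""

    n: int
    age_lo: Optional[float] = None  # months; uniform draw bounds
    age_hi: Optional[float] = None
    ages: Optional[tuple[float, ...]] = None  # fixed age list (months), overrides
    sd: float = 0.0  # mm
    sex: str = "indifferent"
    label: str = ""

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort n must be >= 1")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.ages is None:
            if self.age_lo is None or self.age_hi is None:
                raise ValueError("cohort needs either fixed ages or uniform bounds")
            if self.age_lo < 0 or self.age_hi < self.age_lo:
                raise ValueError("need 0 <= age_lo <= age_hi")
        elif any(a < 0 for a in self.ages):
            raise ValueError("ages must be >= 0")


Truth = Union[CurveParams, SJ2PModel, SJ2PFreeParams]


@dataclass(frozen=True)
class SimConfig:
    """A stated synthetic world: true curve, cohorts, measure, seed."""

    truth: Truth
    cohorts: tuple[Cohort, ...]
    measure: str = "pes"
    seed: int = 0
    noiseless: bool = False
    name: str = ""

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _resolve_truth(truth: Truth):
    """Return an object with .evaluate(age_months)."""
    if isinstance(truth, SJ2PFreeParams):
        return derive_joined(truth)
    if hasattr(truth, "evaluate"):
        return truth
    raise ParameterDomainError(f"cannot evaluate truth of type {type(truth).__name__}")


def simulate_cross_sectional(cfg: SimConfig) -> list[MorphRecord]:
    """Draw one synthetic cross-sectional dataset, reproducible from the seed.

    Ages are sampled per cohort (uniform between the bounds, or the fixed
    list); values are the true curve plus Gaussian noise, truncated below
    at 0.1 mm.  With ``noiseless=True`` values equal the curve exactly.
    """
    model = _resolve_truth(cfg.truth)
    # the linear head model works on days internally; ages stay in months here
    days_scale = DAYS_PER_MONTH if isinstance(model, LinearParams) else 1.0
    rng = np.random.default_rng(cfg.seed)
    records: list[MorphRecord] = []
    idx = 0
    for c_i, cohort in enumerate(cfg.cohorts):
        if cohort.ages is not None:
            ages = np.asarray(cohort.ages, dtype=float)
            if ages.size != cohort.n:
                raise ValueError("fixed age list length must equal cohort n")
        else:
            ages = rng.uniform(cohort.age_lo, cohort.age_hi, size=cohort.n)
        truth_vals = np.asarray(model.evaluate(ages * days_scale), dtype=float)
        if cfg.noiseless or cohort.sd == 0:
            values = truth_vals
        else:
            values = truth_vals + rng.normal(0.0, cohort.sd, size=cohort.n)
        values = np.maximum(values, _MIN_VALUE_MM)
        tag = cohort.label or f"c{c_i}"
        for a, v in zip(ages, values):
            records.append(
                MorphRecord(
                    animal_id=f"{cfg.name or 'sim'}-{tag}-{idx:04d}",
                    sex=cohort.sex,
                    age_months=float(a),
                    measure=cfg.measure,
                    value_mm=float(v),
                )
            )
            idx += 1
    return records


def default_scenarios(seed: int = 0) -> dict[str, SimConfig]:
    """The shipped study-design scenarios keyed by name.

    Each scenario's truth is a published sex-specific parameter row and its
    cohort noise levels are the published per-phase RMSEs:

    * ``male_pes`` / ``female_pes`` — SJ2P pes-length truths; a captive
      pouch cohort (n=68, 0.7–7.4 months, sd 4.91 mm) plus a cull cohort
      (n=97, 17–80 months, sd 9.85 / 9.19 mm).
    * ``pouch_logistic_pes`` — pouch-phase logistic pes growth alone.
    * ``male_pp_brody`` — post-pouch male Brody pes growth alone.
    * ``pouch_head_linear`` — linear head growth over pouch life
      (slope per day; cohort ages quoted in months of 28 days).

    Scenario seeds are offsets of ``seed`` so they differ pairwise.
    """
    from .curves import BrodyParams, LogisticParams  # local to avoid clutter

    pouch = Cohort(n=68, age_lo=0.7, age_hi=7.4, sd=4.91, sex="indifferent",
                   label="pouch")

    scenarios = {
        "male_pes": SimConfig(
            truth=SJ2PFreeParams(C=0.57, K=95.21, L0=1.22, k=0.078, j=7.85, r=0.78),
            cohorts=(pouch,
                     Cohort(n=97, age_lo=17.0, age_hi=80.0, sd=9.85, sex="male",
                            label="cull")),
            measure="pes", seed=seed + 1, name="male_pes",
        ),
        "female_pes": SimConfig(
            truth=SJ2PFreeParams(C=0.22, K=111.42, L0=4.34, k=0.024, j=11.56, r=0.94),
            cohorts=(pouch,
                     Cohort(n=97, age_lo=17.0, age_hi=80.0, sd=9.19, sex="female",
                            label="cull")),
            measure="pes", seed=seed + 2, name="female_pes",
        ),
        "pouch_logistic_pes": SimConfig(
            truth=LogisticParams(A=16.06, K=93.92, L0=1.11, r=0.96),
            cohorts=(pouch,),
            measure="pes", seed=seed + 3, name="pouch_logistic_pes",
        ),
        "male_pp_brody": SimConfig(
            truth=BrodyParams(B=154.91, C=0.567, k=0.077),
            cohorts=(Cohort(n=97, age_lo=17.0, age_hi=80.0, sd=9.85, sex="male",
                            label="cull"),),
            measure="pes", seed=seed + 4, name="male_pp_brody",
        ),
        "pouch_head_linear": SimConfig(
            truth=LinearParams(intercept=0.8643, slope_per_day=0.2452),
            cohorts=(Cohort(n=68, age_lo=20.0 / DAYS_PER_MONTH,
                            age_hi=207.0 / DAYS_PER_MONTH, sd=4.32,
                            sex="indifferent", label="pouch"),),
            measure="head", seed=seed + 5, name="pouch_head_linear",
        ),
    }
    return scenarios
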