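"""Closed forms, derivatives, asymptotes and inverses of the curve families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import growthseam as gs
from growthseam.curves import (
    BrodyOffsetParams,
    BrodyParams,
    CurveDomainError,
    LinearParams,
    LogisticParams,
    ParameterDomainError,
    PostPouchHyperbolaParams,
    VonBertalanffyParams,
    params_from_dict,
    slope,
)


# ---------------------------------------------------------------------------
# pointwise values frozen from independent arithmetic on the closed forms

@pytest.mark.parametrize(
    "params, age, expected",
    [
        # logistic at birth is A + L0; large-age limit is A + K
        (LogisticParams(A=16.06, K=93.92, L0=1.11, r=0.96), 0.0, 17.17),
        (LogisticParams(A=16.06, K=93.92, L0=1.11, r=0.96), 1e3, 109.98),
        # Brody at birth is B(1-C); large-age limit is B
        (BrodyParams(B=154.91, C=0.567, k=0.077), 0.0, 154.91 * (1 - 0.567)),
        (BrodyParams(B=154.91, C=0.567, k=0.077), 1e3, 154.91),
        # offset Brody: value at 0, half-span point, and limit
        (BrodyOffsetParams(a=10.0, b=137.0, k=0.120), 0.0, 10.0),
        (BrodyOffsetParams(a=10.0, b=137.0, k=0.120), math.log(2) / 0.120, 78.5),
        (BrodyOffsetParams(a=10.0, b=137.0, k=0.120), 1e3, 147.0),
        # von Bertalanffy: birth value, half-way age ln2/b, limit a/b
        (VonBertalanffyParams(L0=2.42, a=13.79, b=0.022), 0.0, 2.42),
        (VonBertalanffyParams(L0=2.42, a=13.79, b=0.022), math.log(2) / 0.022,
         (2.42 + 13.79 / 0.022) / 2),
        # linear head growth (age in days)
        (LinearParams(intercept=0.8643, slope_per_day=0.2452), 0.0, 0.8643),
        (LinearParams(intercept=0.8643, slope_per_day=0.2452), 100.0, 25.3843),
    ],
)
def test_pointwise_values(params, age, expected):
    assert params.evaluate(age) == pytest.approx(expected, rel=1e-9, abs=1e-6)


def test_vb_large_age_limit_is_a_over_b():
    p = VonBertalanffyParams(L0=2.42, a=13.79, b=0.022)
    assert p.evaluate(2e3) == pytest.approx(13.79 / 0.022, rel=1e-3)


def test_log_hyperbola_values_and_domain():
    p = PostPouchHyperbolaParams(b3=-5.0, b4=5.0, j=207.0)
    # at age = j the two b3 terms cancel, leaving b4
    assert p.evaluate(207.0) == pytest.approx(5.0, abs=1e-12)
    # large-age limit b4 - b3/j
    assert p.evaluate(1e9) == pytest.approx(5.0 + 5.0 / 207.0, rel=1e-6)
    with pytest.raises(CurveDomainError):
        p.evaluate(103.5)


def test_logistic_inflection_matches_numeric_argmax(pouch_logistic):
    p = pouch_logistic
    ages = np.linspace(0.0, 20.0, 200001)
    vals = p.evaluate(ages)
    fd = np.diff(vals) / np.diff(ages)
    i = np.argmax(fd)
    age_star = (ages[i] + ages[i + 1]) / 2
    assert age_star == pytest.approx(p.inflection_age, abs=1e-3)
    assert p.evaluate(p.inflection_age) == pytest.approx(p.A + p.K / 2, rel=1e-12)
    assert fd.max() == pytest.approx(p.r * p.K / 4, rel=1e-6)
    assert p.max_slope == pytest.approx(p.r * p.K / 4)


@pytest.mark.parametrize(
    "bad",
    [
        lambda: LogisticParams(A=0, K=-1, L0=0.5, r=1),
        lambda: LogisticParams(A=0, K=10, L0=11, r=1),   # L0 >= K
        lambda: LogisticParams(A=0, K=10, L0=0.5, r=-1),
        lambda: BrodyParams(B=100, C=1.2, k=0.1),
        lambda: BrodyParams(B=-5, C=0.5, k=0.1),
        lambda: BrodyOffsetParams(a=0, b=-1, k=0.1),
        lambda: VonBertalanffyParams(L0=10, a=1, b=0.5),  # a/b < L0
        lambda: PostPouchHyperbolaParams(b3=-5, b4=5, j=-1),
        lambda: LogisticParams(A=float("nan"), K=10, L0=1, r=1),
    ],
)
def test_invalid_parameters_rejected_eagerly(bad):
    with pytest.raises(ParameterDomainError):
        bad()


def test_near_degenerate_logistic_core_guard():
    # L0 within the 1e-9*K guard of K is rejected
    with pytest.raises(ParameterDomainError):
        LogisticParams(A=0.0, K=100.0, L0=100.0 * (1 - 1e-12), r=1.0)


# ---------------------------------------------------------------------------
# family-wide property tests

_families = st.sampled_from(["logistic", "brody", "brody-offset", "vb", "linear"])


def _draw_params(family, rng):
    if family == "logistic":
        K = rng.uniform(10, 200)
        return LogisticParams(A=rng.uniform(-20, 50), K=K,
                              L0=rng.uniform(0.01, 0.9) * K,
                              r=rng.uniform(0.05, 3.0))
    if family == "brody":
        return BrodyParams(B=rng.uniform(10, 300), C=rng.uniform(0.01, 0.99),
                           k=rng.uniform(0.01, 1.0))
    if family == "brody-offset":
        return BrodyOffsetParams(a=rng.uniform(-20, 50), b=rng.uniform(10, 300),
                                 k=rng.uniform(0.01, 1.0))
    if family == "vb":
        b = rng.uniform(0.01, 1.0)
        linf = rng.uniform(50, 500)
        return VonBertalanffyParams(L0=rng.uniform(0, 0.8) * linf,
                                    a=linf * b, b=b)
    return LinearParams(intercept=rng.uniform(0, 10), slope_per_day=rng.uniform(0.01, 1))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(family=_families, seed=st.integers(0, 10_000))
def test_monotone_and_asymptote(family, seed):
    """Valid curves are non-decreasing on age >= 0 and approach their asymptote."""
    rng = np.random.default_rng(seed)
    p = _draw_params(family, rng)
    ages = np.linspace(0.0, 100.0, 1000)
    vals = np.asarray(p.evaluate(ages))
    assert np.all(np.diff(vals) > -1e-9)
    asym = p.asymptote()
    if math.isfinite(asym):
        assert abs(float(p.evaluate(1e3)) - asym) < 1e-3 * abs(asym)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(family=_families, seed=st.integers(0, 10_000),
       age=st.floats(0.01, 50.0))
def test_slope_matches_central_finite_difference(family, seed, age):
    rng = np.random.default_rng(seed)
    p = _draw_params(family, rng)
    h = 1e-6
    fd = (float(p.evaluate(age + h)) - float(p.evaluate(age - h))) / (2 * h)
    an = float(slope(p, age))
    assert an == pytest.approx(fd, rel=1e-4, abs=1e-8)


def test_brody_with_zero_C_is_constant_with_zero_slope():
    p = BrodyParams(B=120.0, C=0.0, k=0.3)
    ages = np.linspace(0, 50, 11)
    assert np.allclose(p.evaluate(ages), 120.0)
    assert np.allclose(p.slope(ages), 0.0)


def test_linearity_doubles_increment():
    p = LinearParams(intercept=0.8643, slope_per_day=0.2452)
    inc1 = p.evaluate(50.0) - p.evaluate(0.0)
    inc2 = p.evaluate(100.0) - p.evaluate(0.0)
    assert inc2 == pytest.approx(2 * inc1)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(family=st.sampled_from(["logistic", "brody", "brody-offset", "vb"]),
       seed=st.integers(0, 10_000), frac=st.floats(0.05, 0.95))
def test_inverse_round_trip(family, seed, frac):
    """inverse(evaluate(age)) recovers the age for every monotone family."""
    rng = np.random.default_rng(seed)
    p = _draw_params(family, rng)
    if isinstance(p, BrodyParams) and p.C < 0.05:
        return
    lo = float(p.evaluate(0.0))
    hi = p.asymptote()
    value = lo + frac * (hi - lo)
    age = p.inverse(value)
    assert float(p.evaluate(age)) == pytest.approx(value, rel=1e-9, abs=1e-9)


def test_inverse_out_of_range_raises(pouch_logistic):
    with pytest.raises(CurveDomainError):
        pouch_logistic.inverse(pouch_logistic.asymptote())  # unattainable


def test_serialization_round_trip(pouch_logistic, male_pp_brody):
    for p in (pouch_logistic, male_pp_brody):
        d = p.to_dict()
        assert d["age_unit"] == "month28"
        assert params_from_dict(d) == p
    with pytest.raises(ParameterDomainError):
        params_from_dict({"family": "gompertz", "params": {}})


def test_slope_dispatch_rejects_unknown_type():
    with pytest.raises(ParameterDomainError):
        slope(object(), 1.0)
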