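"""Least-squares estimation: noiseless recovery, join-point profiling,
invariance, and failure reporting."""

import numpy as np
import pytest

import growthseam as gs
from growthseam.fitting import (
    DataError,
    FitConfig,
    fit_curve,
    fit_sj2p,
    profile_join,
)
from growthseam.records import MorphRecord


def _records(ages, values, measure="pes"):
    return [
        MorphRecord(animal_id=f"a{i}", sex="indifferent", age_months=float(a),
                    measure=measure, value_mm=float(v))
        for i, (a, v) in enumerate(zip(ages, values))
    ]


# ---------------------------------------------------------------------------
# noiseless generate-then-fit recovery

@pytest.mark.parametrize(
    "family, truth, ages",
    [
        ("logistic", gs.LogisticParams(A=16.06, K=93.92, L0=1.11, r=0.96),
         np.linspace(0.3, 7.4, 30)),
        ("brody", gs.BrodyParams(B=154.91, C=0.567, k=0.077),
         np.linspace(1.0, 80.0, 30)),
        ("brody-offset", gs.BrodyOffsetParams(a=10.0, b=137.0, k=0.120),
         np.linspace(0.0, 60.0, 30)),
        ("vb", gs.VonBertalanffyParams(L0=2.42, a=13.79, b=0.022),
         np.linspace(0.0, 120.0, 30)),
        ("linear", gs.LinearParams(intercept=0.8643, slope_per_day=0.2452),
         np.linspace(0.5, 7.4, 30)),
    ],
)
def test_noiseless_recovery_all_families(family, truth, ages):
    """Fitting a family to its own noiseless curve recovers the truth."""
    eval_ages = ages * 28.0 if truth.age_unit == "day" else ages
    values = np.asarray(truth.evaluate(eval_ages))
    res = fit_curve((ages, values), FitConfig(family=family, seed=0))
    assert res.converged
    est, tru = res.estimates.as_array(), truth.as_array()
    assert np.allclose(est, tru, rtol=1e-4)
    assert res.rss <= 1e-8


def test_noiseless_logistic_recovery_tight():
    truth = gs.LogisticParams(A=16.06, K=93.92, L0=1.11, r=0.96)
    ages = np.linspace(0.3, 7.4, 30)
    res = fit_curve((ages, np.asarray(truth.evaluate(ages))),
                    FitConfig(family="logistic", seed=0))
    assert np.allclose(res.estimates.as_array(), truth.as_array(), rtol=1e-6)


def test_hyperbola_comparator_fit():
    truth = gs.PostPouchHyperbolaParams(b3=-40.0, b4=5.0, j=207.0)
    ages_days = np.linspace(220, 2240, 40)
    values = np.exp(np.asarray(truth.evaluate(ages_days)))
    res = fit_curve((ages_days / 28.0, values), FitConfig(family="hyperbola", seed=0))
    assert res.converged
    assert res.estimates.b3 == pytest.approx(-40.0, rel=1e-4)
    assert res.estimates.b4 == pytest.approx(5.0, rel=1e-4)
    assert res.fixed["j"] == 207.0


def test_rss_at_optimum_not_worse_than_truth(male_pp_brody):
    ages = np.linspace(1.0, 80.0, 40)
    values = np.asarray(male_pp_brody.evaluate(ages))
    res = fit_curve((ages, values), FitConfig(family="brody", seed=1))
    rss_truth = float(np.sum((values - male_pp_brody.evaluate(ages)) ** 2))
    assert res.rss <= rss_truth + 1e-8


def test_estimates_invariant_to_record_order_and_ids(pouch_logistic):
    rng = np.random.default_rng(21)
    ages = np.linspace(0.5, 7.4, 40)
    values = np.asarray(pouch_logistic.evaluate(ages)) + rng.normal(0, 3, 40)
    recs = _records(ages, values)
    shuffled = [recs[i] for i in rng.permutation(len(recs))]
    relabeled = [
        MorphRecord(animal_id=f"zz{i}", sex=r.sex, age_months=r.age_months,
                    measure=r.measure, value_mm=r.value_mm)
        for i, r in enumerate(shuffled)
    ]
    cfg = FitConfig(family="logistic", seed=5)
    a = fit_curve(recs, cfg).estimates.as_array()
    b = fit_curve(relabeled, cfg).estimates.as_array()
    assert np.array_equal(a, b)


def test_large_sample_rmse_approaches_noise_sd(male_pp_brody):
    """With n=2000 and sd=6, the fitted model's RMSE estimates the noise sd."""
    rng = np.random.default_rng(8)
    ages = rng.uniform(1.0, 80.0, 2000)
    values = np.asarray(male_pp_brody.evaluate(ages)) + rng.normal(0, 6.0, 2000)
    res = fit_curve((ages, values), FitConfig(family="brody", seed=2))
    assert res.rmse == pytest.approx(6.0, rel=0.05)


# ---------------------------------------------------------------------------
# failure modes

def test_constant_data_reports_nonconvergence():
    ages = np.linspace(0.5, 7.0, 20)
    res = fit_curve((ages, np.full(20, 50.0)), FitConfig(family="logistic"))
    assert not res.converged and res.estimates is None


def test_insufficient_data_raises():
    with pytest.raises(DataError):
        fit_curve((np.array([1.0, 2.0]), np.array([5.0, 6.0])),
                  FitConfig(family="logistic"))


def test_single_age_raises():
    with pytest.raises(DataError):
        fit_curve((np.full(10, 3.0), np.linspace(1, 10, 10)),
                  FitConfig(family="brody"))


def test_records_without_age_are_ignored():
    ages = np.linspace(1.0, 80.0, 30)
    truth = gs.BrodyParams(B=150.0, C=0.5, k=0.1)
    recs = _records(ages, np.asarray(truth.evaluate(ages)))
    recs.append(MorphRecord(animal_id="x", sex="male", age_months=None,
                            measure="pes", value_mm=140.0))
    res = fit_curve(recs, FitConfig(family="brody", seed=0))
    assert res.n == 30


# ---------------------------------------------------------------------------
# SJ2P join-point estimation

def test_profile_join_recovers_noiseless_join(male_sj2p_free, study_ages):
    model = gs.derive_joined(male_sj2p_free)
    values = np.asarray(model.evaluate(study_ages))
    profile, j_star = profile_join((study_ages, values), FitConfig(family="sj2p", seed=0))
    assert j_star == pytest.approx(7.85, abs=1e-3)
    js = [j for j, _ in profile]
    assert js == sorted(js)
    rss_min = min(r for _, r in profile)
    assert all(r >= rss_min - 1e-12 for _, r in profile)


def test_profile_grid_outside_data_raises(male_sj2p_free):
    ages = np.linspace(0.5, 40.0, 60)
    values = np.asarray(gs.derive_joined(male_sj2p_free).evaluate(ages))
    cfg = FitConfig(family="sj2p", j_grid=(50.0, 60.0, 5))
    with pytest.raises(DataError):
        profile_join((ages, values), cfg)


def test_sj2p_noiseless_recovery(male_sj2p_free, study_ages):
    model = gs.derive_joined(male_sj2p_free)
    values = np.asarray(model.evaluate(study_ages))
    res = fit_sj2p((study_ages, values), FitConfig(family="sj2p", seed=0))
    assert res.converged
    est = res.estimates.free.as_array()
    assert np.allclose(est, male_sj2p_free.as_array(), rtol=1e-4)


def test_sj2p_fixed_join(male_sj2p_free, study_ages):
    model = gs.derive_joined(male_sj2p_free)
    values = np.asarray(model.evaluate(study_ages))
    j_fixed = 207.0 / 28.0  # 207 days
    res = fit_sj2p((study_ages, values),
                   FitConfig(family="sj2p", fix_j=j_fixed, seed=0))
    assert res.converged
    assert res.estimates.free.j == j_fixed
    assert res.fixed == {"j": j_fixed}
    assert set(res.std_errors) == {"C", "K", "L0", "k", "r"}


def test_sj2p_one_sided_data_raises(male_sj2p_free):
    ages = np.linspace(0.5, 3.0, 30)
    values = np.asarray(gs.derive_joined(male_sj2p_free).evaluate(ages))
    with pytest.raises(DataError):
        fit_sj2p((ages, values), FitConfig(family="sj2p"))


def test_fit_report_serializes(male_sj2p_free, study_ages):
    import json

    model = gs.derive_joined(male_sj2p_free)
    rng = np.random.default_rng(2)
    values = np.asarray(model.evaluate(study_ages)) + rng.normal(0, 3, study_ages.size)
    res = fit_sj2p((study_ages, values), FitConfig(family="sj2p", seed=4))
    report = res.to_dict()
    assert report["schema"] == "growthseam/1"
    text = json.dumps(report)
    assert "free" in text and "derived" in text
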