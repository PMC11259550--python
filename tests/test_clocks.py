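import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import ElasticNet

from methylaging import clocks
from methylaging.clocks import (
    ClockModel,
    evaluate_clock,
    inverse_transform_age,
    predict_age,
    stepwise_reduce,
    stratified_split,
    train_clock,
    train_multimodal_clock,
    transform_age,
)


def test_transform_printed_values():
    assert transform_age(20) == pytest.approx(0.0, abs=1e-15)
    assert transform_age(41) == pytest.approx(1.0, abs=1e-12)
    assert transform_age(9.5) == pytest.approx(np.log(10.5 / 21), abs=1e-12)
    assert transform_age(9.5) == pytest.approx(-0.6931, abs=1e-4)
    assert inverse_transform_age(0) == pytest.approx(20.0, abs=1e-15)
    assert inverse_transform_age(1) == pytest.approx(41.0, abs=1e-12)


def test_transform_round_trip_reference_ages():
    for x in (1, 19.99, 20, 55, 87):
        assert inverse_transform_age(transform_age(x)) == pytest.approx(x, abs=1e-10)


@settings(max_examples=50, derandomize=True)
@given(st.floats(min_value=-0.99, max_value=120, allow_nan=False))
def test_transform_round_trip_property(age):
    assert inverse_transform_age(transform_age(age)) == pytest.approx(age, abs=1e-9)


def test_transform_rejects_impossible_age():
    with pytest.raises(ValueError):
        transform_age(-1.0)


def _signal_cohort(seed=7, n=200, p=300, noise=0.02):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, (p, n))
    w = np.array([1.2, -0.8, 0.9, 0.7, -1.1])
    t = x[:5].T @ w + 0.5 + rng.normal(0, noise, n)
    ages = inverse_transform_age(t)
    beta = pd.DataFrame(x, index=[f"cg{i}" for i in range(p)], columns=[f"S{i}" for i in range(n)])
    return beta, pd.Series(ages, index=beta.columns)


def test_train_clock_recovers_linear_transformed_age_signal():
    beta, targets = _signal_cohort(noise=0.0)
    train = list(beta.columns[:100])
    valid = list(beta.columns[100:])
    model = train_clock(beta, targets, train, valid, seed=0)
    assert model.meta["validation_mae"] < 0.5
    assert model.meta["validation_r"] > 0.99


def test_train_clock_deterministic_given_seed():
    beta, targets = _signal_cohort()
    train = list(beta.columns[:100])
    valid = list(beta.columns[100:])
    m1 = train_clock(beta, targets, train, valid, seed=3, alpha_grid=(0.3, 0.7))
    m2 = train_clock(beta, targets, train, valid, seed=3, alpha_grid=(0.3, 0.7))
    assert m1.weights == m2.weights and m1.intercept == m2.intercept


def test_train_clock_rejects_overlapping_split():
    beta, targets = _signal_cohort(n=40, p=20)
    with pytest.raises(ValueError):
        train_clock(beta, targets, list(beta.columns[:25]), list(beta.columns[20:]))


def test_stratified_split_halves_of_250():
    rng = np.random.default_rng(0)
    samples = pd.DataFrame(
        {"age": rng.uniform(20, 87, 250), "sex": rng.integers(0, 2, 250)},
        index=[f"S{i:04d}" for i in range(250)],
    )
    train, valid = stratified_split(samples, seed=1)
    assert len(train) == 125 and len(valid) == 125
    assert not set(train) & set(valid)


def test_predict_age_arithmetic_chain_and_contracts():
    model = ClockModel(name="toy", intercept=0.0, weights={"cgA": 21.0})
    beta = pd.DataFrame({"s1": [1.0]}, index=["cgA"])
    # score 21 -> inverse transform 21*21 + 20 = 461
    assert predict_age(model, beta)["s1"] == pytest.approx(461.0, abs=1e-9)
    with pytest.raises(ValueError):
        predict_age(model, pd.DataFrame({"s1": [0.5]}, index=["other"]))


def test_predict_age_invariant_to_row_order_and_extra_probes():
    rng = np.random.default_rng(4)
    model = ClockModel(
        name="toy", intercept=0.2, weights={"cgA": 1.0, "cgB": -2.0},
        train_means={"cgA": 0.5, "cgB": 0.5},
    )
    beta = pd.DataFrame(
        rng.uniform(0, 1, (3, 5)), index=["cgB", "junk", "cgA"],
        columns=[f"s{i}" for i in range(5)],
    )
    p1 = predict_age(model, beta)
    p2 = predict_age(model, beta.iloc[::-1])
    p3 = predict_age(model, beta.drop(index="junk"))
    assert np.allclose(p1, p2) and np.allclose(p1, p3)


def test_predict_age_imputes_missing_probe_with_train_mean():
    model = ClockModel(
        name="toy", intercept=0.0, weights={"cgA": 1.0, "cgB": 1.0},
        transform="identity", train_means={"cgA": 0.5, "cgB": 0.25},
    )
    beta = pd.DataFrame({"s1": [0.1]}, index=["cgA"])
    assert predict_age(model, beta)["s1"] == pytest.approx(0.1 + 0.25)


def test_model_json_round_trip_bit_identical_predictions(tmp_path):
    beta, targets = _signal_cohort(n=60, p=40)
    model = train_clock(
        beta, targets, list(beta.columns[:40]), list(beta.columns[40:]),
        alpha_grid=(0.5,), seed=0,
    )
    path = tmp_path / "model.json"
    model.to_json(path)
    back = ClockModel.from_json(path)
    p1 = predict_age(model, beta)
    p2 = predict_age(back, beta)
    assert (p1.to_numpy() == p2.to_numpy()).all()


def test_evaluate_clock_identity_offset_and_constant():
    truth = pd.Series([30.0, 40.0, 50.0, 60.0], index=list("abcd"))
    ev = evaluate_clock(truth.copy(), truth)
    assert ev.r == pytest.approx(1.0) and ev.mae == pytest.approx(0.0)
    ev2 = evaluate_clock(truth + 2, truth)
    assert ev2.r == pytest.approx(1.0) and ev2.mae == pytest.approx(2.0)
    ev3 = evaluate_clock(pd.Series(45.0, index=truth.index), truth)
    assert np.isnan(ev3.r) and ev3.mae == pytest.approx(10.0)


def test_nonzero_weights_weakly_decrease_with_lambda():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, (80, 30))
    y = x[:, :5] @ rng.normal(1, 0.2, 5) + rng.normal(0, 0.5, 80)
    counts = []
    for lam in (1e-3, 1e-2, 1e-1, 1.0, 10.0):
        fit = ElasticNet(alpha=lam, l1_ratio=0.5, max_iter=50_000).fit(x, y)
        counts.append(int((fit.coef_ != 0).sum()))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def _stepwise_bruteforce(beta, targets, start, stop_k):
    """Reference single-deletion backward elimination on AIC."""
    ids = list(beta.columns)
    y = targets.loc[ids].to_numpy(dtype=float)

    def aic(probe_list):
        x = sm.add_constant(beta.loc[probe_list, ids].to_numpy(dtype=float).T)
        return sm.OLS(y, x).fit().aic

    current = list(start)
    order = []
    while len(current) > stop_k:
        best = min(
            ((aic([p for p in current if p != drop]), drop) for drop in current),
            key=lambda t: (t[0], t[1]),
        )
        current = [p for p in current if p != best[1]]
        order.append(best[1])
    return current, order


def test_stepwise_identity_when_start_equals_stop():
    beta, targets = _signal_cohort(n=60, p=10)
    start = list(beta.index[:5])
    model = stepwise_reduce(beta, targets, start, stop_k=5)
    assert set(model.weights) == set(start)
    assert model.meta["eliminated"] == []


def test_stepwise_recovers_signal_and_matches_bruteforce():
    rng = np.random.default_rng(12)
    n = 120
    x = rng.uniform(0, 1, (7, n))
    w = np.array([1.0, -0.9, 0.8, 1.1, -0.7])
    y = x[:5].T @ w + rng.normal(0, 0.05, n)
    beta = pd.DataFrame(x, index=[f"cg{i}" for i in range(7)], columns=[f"S{i}" for i in range(n)])
    targets = pd.Series(y, index=beta.columns)
    start = list(beta.index)
    model = stepwise_reduce(beta, targets, start, stop_k=5)
    ref_kept, ref_order = _stepwise_bruteforce(beta, targets, start, 5)
    assert sorted(model.weights) == sorted(ref_kept) == [f"cg{i}" for i in range(5)]
    assert model.meta["eliminated"] == ref_order


def test_multimodal_loo_recovers_exact_signal_and_is_order_invariant():
    rng = np.random.default_rng(9)
    n, p = 40, 60
    x = rng.uniform(0, 1, (p, n))
    beta = pd.DataFrame(x, index=[f"cg{i}" for i in range(p)], columns=[f"S{i:02d}" for i in range(n)])
    target = pd.Series(3 * x[0] - 2 * x[1] + 1.5 * x[2] + 50, index=beta.columns)
    model, ev = train_multimodal_clock(beta, target, alpha_grid=(0.5,), seed=0)
    assert ev.r > 0.99
    perm = beta[list(beta.columns[::-1])]
    model2, ev2 = train_multimodal_clock(perm, target, alpha_grid=(0.5,), seed=0)
    pd.testing.assert_series_equal(ev.predictions, ev2.predictions)


def test_multimodal_null_target_has_no_skill():
    rng = np.random.default_rng(10)
    n, p = 40, 60
    beta = pd.DataFrame(
        rng.uniform(0, 1, (p, n)),
        index=[f"cg{i}" for i in range(p)],
        columns=[f"S{i:02d}" for i in range(n)],
    )
    target = pd.Series(rng.normal(50, 5, n), index=beta.columns)
    _, ev = train_multimodal_clock(beta, target, alpha_grid=(0.5,), seed=0)
    assert np.isnan(ev.r) or ev.r < 0.5


def test_multimodal_requires_enough_samples():
    beta = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("wxyz"))
    target = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
    with pytest.raises(ValueError):
        train_multimodal_clock(beta, target, loo=True)
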