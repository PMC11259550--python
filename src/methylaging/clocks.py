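"""Elastic-net epigenetic clocks on transformed age.

A clock is a sparse linear predictor of (transformed) age from CpG beta
values.  Chronological-age clocks are trained on the piecewise age
transform

    f(age) = (age + 1)/(adult + 1) - 1          for age >= adult
           = ln((age + 1)/(adult + 1))          for age <  adult

with adult age 20, which makes age linear above adulthood and logarithmic
below it; predictions are mapped back through the exact inverse

    f^-1(t) = t*(adult + 1) + adult             for t >= 0
            = (adult + 1)*exp(t) - 1            for t <  0.

Training follows the elastic-net protocol: for each mixing parameter alpha
in a grid (0.1..0.9), the penalty strength lambda is chosen by 10-fold
cross-validation on the training set; the candidate with the lowest mean
absolute error (in years, after inverse transform) on a held-out
validation set becomes the final model.  Missing model probes at
prediction time are imputed with the training-set mean beta.  The module
also provides backward stepwise reduction to a small fixed probe panel and
leave-one-out training against multi-modal (non-DNAm) age targets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
_ENET_TOL = 1e-7
_CV_TOL = 1e-4
_ENET_MAX_ITER = 20_000


def transform_age(age, adult_age: float = 20.0):
    """Piecewise age transform: linear above ``adult_age``, log below."""
    a = np.asarray(age, dtype=float)
    if np.any(a <= -1):
        raise ValueError("age must be greater than -1")
    ratio = (a + 1.0) / (adult_age + 1.0)
    out = np.where(a >= adult_age, ratio - 1.0, np.log(ratio))
    return float(out) if np.isscalar(age) else out


def inverse_transform_age(t, adult_age: float = 20.0):
    """Exact inverse of :func:`transform_age`."""
    tt = np.asarray(t, dtype=float)
    out = np.where(
        tt >= 0,
        tt * (adult_age + 1.0) + adult_age,
        (adult_age + 1.0) * np.exp(tt) - 1.0,
    )
    return float(out) if np.isscalar(t) else out


@dataclass
class ClockModel:
    """Sparse linear age predictor.

    ``weights`` maps probe id -> coefficient on the beta scale;
    ``train_means`` holds training-set mean betas used to impute model
    probes missing at prediction time; ``transform`` is
    ``"horvath_piecewise"`` or ``"identity"``.
    """

    name: str
    intercept: float
    weights: dict[str, float]
    transform: str = "horvath_piecewise"
    adult_age: float = 20.0
    train_means: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.transform not in ("horvath_piecewise", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not all(np.isfinite(list(self.weights.values()) + [self.intercept])):
            raise ValueError("model coefficients must be finite")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "transform": self.transform,
            "adult_age": self.adult_age,
            "intercept": self.intercept,
            "weights": [{"probe": k, "coef": v} for k, v in sorted(self.weights.items())],
            "train_means": {k: v for k, v in sorted(self.train_means.items())},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClockModel":
        return cls(
            name=d["name"],
            intercept=d["intercept"],
            weights={w["probe"]: w["coef"] for w in d["weights"]},
            transform=d.get("transform", "horvath_piecewise"),
            adult_age=d.get("adult_age", 20.0),
            train_means=d.get("train_means", {}),
            meta=d.get("meta", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ClockEvaluation:
    r: float
    mae: float
    n: int
    predictions: pd.Series


def evaluate_clock(predictions: pd.Series, truth: pd.Series) -> ClockEvaluation:
    """Pearson r and mean absolute error (years) of paired predictions."""
    shared = predictions.index.intersection(truth.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 paired samples")
    pred = predictions.loc[shared].to_numpy(dtype=float)
    tru = truth.loc[shared].to_numpy(dtype=float)
    mae = float(np.mean(np.abs(pred - tru)))
    if np.std(pred) == 0 or np.std(tru) == 0:
        log.warning("evaluate_clock: constant input, correlation undefined")
        r = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(stats.pearsonr(pred, tru)[0])
    return ClockEvaluation(r=r, mae=mae, n=len(shared), predictions=predictions.loc[shared])


def stratified_split(
    samples: pd.DataFrame,
    frac: float = 0.5,
    seed: int = 0,
    sex_col: str = "sex",
    n_age_bins: int = 10,
) -> tuple[list[str], list[str]]:
    """Train/validation split stratified by sex and age decile.

    With ``frac=0.5`` and an even cohort, the two halves are exactly
    equal: strata of odd size donate their extra sample to whichever side
    is currently smaller.
    """
    rng = np.random.default_rng(seed)
    age_bin = pd.qcut(samples["age"], q=n_age_bins, duplicates="drop", labels=False)
    strata = samples.groupby([samples[sex_col], age_bin], observed=True, sort=True)
    train: list[str] = []
    valid: list[str] = []
    for _, sub in strata:
        ids = list(sub.index)
        rng.shuffle(ids)
        k = int(np.floor(frac * len(ids)))
        extra = len(ids) - 2 * k if abs(frac - 0.5) < 1e-12 else 0
        if extra and len(train) > len(valid):
            valid.extend(ids[: k + extra])
            train.extend(ids[k + extra:])
        else:
            train.extend(ids[: k + extra])
            valid.extend(ids[k + extra:])
    return train, valid


def _standardized_fit(x: np.ndarray, y: np.ndarray, model) -> tuple:
    """Fit an sklearn linear model on standardized predictors; return the
    fitted model plus (mu, sd) needed to express coefficients on the
    original beta scale."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    model.fit((x - mu) / sd_safe, y)
    return model, mu, sd_safe


def _unscale(coef: np.ndarray, intercept: float, mu: np.ndarray, sd: np.ndarray):
    w = coef / sd
    b = intercept - float(np.dot(coef, mu / sd))
    return w, b


def train_clock(
    beta: pd.DataFrame,
    targets: pd.Series,
    train_ids,
    valid_ids,
    alpha_grid=DEFAULT_ALPHA_GRID,
    cv_folds: int = 10,
    seed: int = 0,
    transform: str = "horvath_piecewise",
    adult_age: float = 20.0,
    name: str = "clock",
    select_scale: str = "age",
) -> ClockModel:
    """Elastic-net clock: lambda by internal CV, alpha by validation MAE.

    ``targets`` are ages in years (transformed internally when
    ``transform="horvath_piecewise"``).  ``select_scale`` controls whether
    validation MAE is computed in years after inverse transform
    (``"age"``, default) or on the transformed scale
    (``"transformed"``).
    """
    train_ids, valid_ids = list(train_ids), list(valid_ids)
    if not valid_ids:
        raise ValueError("validation set is empty")
    if set(train_ids) & set(valid_ids):
        raise ValueError("train and validation sets must be disjoint")
    y_raw = targets.loc[train_ids].to_numpy(dtype=float)
    if not np.all(np.isfinite(y_raw)):
        raise ValueError("non-finite training targets")
    horvath = transform == "horvath_piecewise"
    y_train = transform_age(y_raw, adult_age) if horvath else y_raw
    x_train = beta[train_ids].to_numpy(dtype=float).T
    x_valid = beta[valid_ids].to_numpy(dtype=float).T
    y_valid_age = targets.loc[valid_ids].to_numpy(dtype=float)

    best = None
    for l1 in alpha_grid:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        # the lambda search runs at a looser tolerance; the selected model
        # is refit to the full coordinate-descent tolerance below
        encv = ElasticNetCV(
            l1_ratio=float(l1),
            cv=cv,
            alphas=40,
            tol=_CV_TOL,
            max_iter=_ENET_MAX_ITER,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _standardized_fit(x_train, y_train, encv)
        enet = ElasticNet(
            alpha=float(encv.alpha_), l1_ratio=float(l1), tol=_ENET_TOL, max_iter=_ENET_MAX_ITER
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fitted, mu, sd = _standardized_fit(x_train, y_train, enet)
        fitted.alpha_ = float(encv.alpha_)
        w, b = _unscale(fitted.coef_, float(fitted.intercept_), mu, sd)
        score_valid = b + x_valid @ w
        if select_scale == "transformed" and horvath:
            mae = float(np.mean(np.abs(score_valid - transform_age(y_valid_age, adult_age))))
        else:
            pred_valid = inverse_transform_age(score_valid, adult_age) if horvath else score_valid
            mae = float(np.mean(np.abs(pred_valid - y_valid_age)))
        if best is None or mae < best["mae"]:
            best = {
                "mae": mae,
                "l1": float(l1),
                "lambda": float(fitted.alpha_),
                "w": w,
                "b": b,
            }

    nz = np.flatnonzero(best["w"])
    probe_ids = list(beta.index[nz])
    weights = {p: float(best["w"][i]) for p, i in zip(probe_ids, nz)}
    train_means = {p: float(beta.loc[p, train_ids].mean()) for p in probe_ids}
    pred_valid = predict_age(
        _bare_model(name, best, weights, train_means, transform, adult_age), beta[valid_ids]
    )
    ev = evaluate_clock(pred_valid, targets.loc[valid_ids])
    model = _bare_model(name, best, weights, train_means, transform, adult_age)
    model.meta.update(
        {
            "alpha": best["l1"],
            "lambda": best["lambda"],
            "validation_mae": ev.mae,
            "validation_r": ev.r,
            "n_train": len(train_ids),
            "n_valid": len(valid_ids),
            "target": name,
        }
    )
    return model


def _bare_model(name, best, weights, train_means, transform, adult_age) -> ClockModel:
    return ClockModel(
        name=name,
        intercept=best["b"],
        weights=dict(weights),
        transform=transform,
        adult_age=adult_age,
        train_means=dict(train_means),
        meta={},
    )


def predict_age(model: ClockModel, beta: pd.DataFrame) -> pd.Series:
    """Predicted age in years for each sample of ``beta``.

    Model probes absent from the matrix are imputed with the training-set
    mean beta (count logged); if no model probe is present, an error is
    raised.  The linear score is inverse-transformed when the model was
    trained on the piecewise transform.
    """
    probes = sorted(model.weights)
    if not probes:
        # intercept-only model (e.g. a null fit where the penalty removed
        # every probe): constant prediction
        score = np.full(beta.shape[1], model.intercept)
        if model.transform == "horvath_piecewise":
            score = inverse_transform_age(score, model.adult_age)
        return pd.Series(score, index=beta.columns, name="predicted_age")
    present = [p for p in probes if p in beta.index]
    if not present:
        raise ValueError("none of the model probes are present in the beta matrix")
    missing = [p for p in probes if p not in beta.index]
    if missing:
        log.info("predict_age: imputing %d missing model probes with training means", len(missing))
    x = np.empty((beta.shape[1], len(probes)))
    for j, p in enumerate(probes):
        if p in beta.index:
            x[:, j] = beta.loc[p].to_numpy(dtype=float)
        else:
            if p not in model.train_means:
                raise ValueError(f"missing probe {p!r} has no stored training mean")
            x[:, j] = model.train_means[p]
    w = np.array([model.weights[p] for p in probes])
    score = model.intercept + x @ w
    if model.transform == "horvath_piecewise":
        score = inverse_transform_age(score, model.adult_age)
    return pd.Series(score, index=beta.columns, name="predicted_age")


def stepwise_reduce(
    beta: pd.DataFrame,
    targets: pd.Series,
    start_probes,
    stop_k: int = 5,
    criterion: str = "aic",
) -> ClockModel:
    """Backward elimination from an OLS fit down to ``stop_k`` probes.

    At each step every single-probe deletion is evaluated and the probe
    whose removal yields the best (lowest) criterion is dropped; ties
    break on probe id.  The returned model is an untransformed-target OLS
    fit on the surviving probes; the elimination order is recorded in
    ``meta``.
    """
    start_probes = list(start_probes)
    if len(start_probes) <= stop_k:
        current = start_probes
    else:
        current = list(start_probes)
    missing = [p for p in current if p not in beta.index]
    if missing:
        raise ValueError(f"start probes absent from beta: {missing}")
    ids = list(beta.columns)
    y = targets.loc[ids].to_numpy(dtype=float)
    x_all = beta.loc[current, ids].to_numpy(dtype=float).T
    if np.linalg.cond(np.column_stack([np.ones(len(ids)), x_all])) > 1e10:
        raise ValueError("start probe set is collinear")

    def _crit(probe_list):
        x = sm.add_constant(beta.loc[probe_list, ids].to_numpy(dtype=float).T)
        fit = sm.OLS(y, x).fit()
        if criterion == "aic":
            return fit.aic
        if criterion == "bic":
            return fit.bic
        raise ValueError(f"unknown criterion {criterion!r}")

    eliminated: list[str] = []
    while len(current) > stop_k:
        options = sorted(
            ((_crit([p for p in current if p != drop]), drop) for drop in current),
            key=lambda t: (t[0], t[1]),
        )
        _, drop = options[0]
        current = [p for p in current if p != drop]
        eliminated.append(drop)

    x = sm.add_constant(beta.loc[current, ids].to_numpy(dtype=float).T)
    fit = sm.OLS(y, x).fit()
    model = ClockModel(
        name="stepwise",
        intercept=float(fit.params[0]),
        weights={p: float(c) for p, c in zip(current, fit.params[1:])},
        transform="identity",
        train_means={p: float(beta.loc[p, ids].mean()) for p in current},
        meta={
            "criterion": criterion,
            "eliminated": eliminated,
            "final_criterion": float(fit.aic if criterion == "aic" else fit.bic),
        },
    )
    return model


def train_multimodal_clock(
    beta: pd.DataFrame,
    targets: pd.Series,
    loo: bool = True,
    alpha_grid=DEFAULT_ALPHA_GRID,
    cv_folds: int = 10,
    seed: int = 0,
    name: str = "multimodal",
) -> tuple[ClockModel, ClockEvaluation]:
    """Elastic-net clock against a multi-modal age target, scored by LOO.

    Samples without a target are dropped.  For each alpha the penalty is
    fixed by cross-validation on the full set; leave-one-out refits then
    yield an out-of-sample prediction for every sample, and the alpha with
    the lowest LOO MAE wins.  The final model is refit on all samples with
    the selected alpha/lambda.  Multi-modal targets are fit on the
    identity scale.
    """
    # canonical sample order (sorted ids) so results are invariant to the
    # column order of the inputs
    ids = sorted(s for s in beta.columns if s in targets.index and np.isfinite(targets[s]))
    n = len(ids)
    if loo and n < 10:
        raise ValueError("need at least 10 samples for leave-one-out training")
    x = beta[ids].to_numpy(dtype=float).T
    y = targets.loc[ids].to_numpy(dtype=float)

    best = None
    for l1 in alpha_grid:
        cv = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=seed)
        encv = ElasticNetCV(
            l1_ratio=float(l1), cv=cv, alphas=40, tol=_CV_TOL, max_iter=_ENET_MAX_ITER
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _standardized_fit(x, y, encv)
        lam = float(encv.alpha_)
        if loo:
            preds = np.empty(n)
            for i in range(n):
                keep = np.arange(n) != i
                enet = ElasticNet(
                    alpha=lam, l1_ratio=float(l1), tol=_ENET_TOL, max_iter=_ENET_MAX_ITER
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    fitted, mu, sd = _standardized_fit(x[keep], y[keep], enet)
                w, b = _unscale(fitted.coef_, float(fitted.intercept_), mu, sd)
                preds[i] = b + x[i] @ w
            mae = float(np.mean(np.abs(preds - y)))
        else:
            enet = ElasticNet(alpha=lam, l1_ratio=float(l1), tol=_ENET_TOL, max_iter=_ENET_MAX_ITER)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                fitted, mu, sd = _standardized_fit(x, y, enet)
            w, b = _unscale(fitted.coef_, float(fitted.intercept_), mu, sd)
            preds = b + x @ w
            mae = float(np.mean(np.abs(preds - y)))
        if best is None or mae < best["mae"]:
            best = {"mae": mae, "l1": float(l1), "lambda": lam, "preds": preds}

    pred_series = pd.Series(best["preds"], index=ids, name="predicted_age")
    ev = evaluate_clock(pred_series, targets.loc[ids])

    enet = ElasticNet(
        alpha=best["lambda"], l1_ratio=best["l1"], tol=_ENET_TOL, max_iter=_ENET_MAX_ITER
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fitted, mu, sd = _standardized_fit(x, y, enet)
    w, b = _unscale(fitted.coef_, float(fitted.intercept_), mu, sd)
    nz = np.flatnonzero(w)
    probe_ids = list(beta.index[nz])
    model = ClockModel(
        name=name,
        intercept=float(b),
        weights={p: float(w[i]) for p, i in zip(probe_ids, nz)},
        transform="identity",
        train_means={p: float(beta.loc[p, ids].mean()) for p in probe_ids},
        meta={
            "alpha": best["l1"],
            "lambda": best["lambda"],
            "loo_mae": ev.mae,
            "loo_r": ev.r,
            "n": n,
            "target": name,
        },
    )
    return model, ev
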