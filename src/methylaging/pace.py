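"""Age-pace computation and pace-group differential analysis.

The *age pace* of a sample is the residual of its predicted age after
regressing predicted age on chronological age (OLS), so paces are mean
zero and uncorrelated with chronological age by construction; a positive
pace marks accelerated aging.  Samples in the top and bottom 20% of the
pace distribution are labelled accelerators and decelerators, and the two
groups are compared feature by feature: Welch t-tests for numeric
phenotypes/lifestyle scores, chi-squared (Fisher fallback) for dichotomous
factors, and a detection-filtered fold-change + t-test rule for
protein/metabolite/transcript abundance matrices.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

ACCELERATOR = "accelerator"
DECELERATOR = "decelerator"
MIDDLE = "middle"


def compute_age_pace(predicted: pd.Series, chronological: pd.Series) -> pd.DataFrame:
    """Residual age pace from one common predicted-on-chronological OLS.

    Returns a table (sample id index) with predicted age, chronological
    age, pace (residual, years), and the accelerated-aging sign
    (pace > 0).
    """
    shared = predicted.index.intersection(chronological.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 paired samples")
    pred = predicted.loc[shared].to_numpy(dtype=float)
    chron = chronological.loc[shared].to_numpy(dtype=float)
    if np.std(chron) == 0:
        raise ValueError("chronological ages are constant; pace regression undefined")
    slope, intercept = np.polyfit(chron, pred, 1)
    pace = pred - (intercept + slope * chron)
    return pd.DataFrame(
        {
            "predicted_age": pred,
            "chronological_age": chron,
            "pace": pace,
            "accelerated": pace > 0,
        },
        index=pd.Index(shared, name="sample_id"),
    )


def classify_pace_groups(pace: pd.DataFrame, q: float = 0.20) -> pd.DataFrame:
    """Label the top/bottom q of paces accelerator/decelerator.

    Each tail holds exactly ``ceil(q*n)`` samples; ties break
    deterministically on sample id.
    """
    n = len(pace)
    k = math.ceil(q * n)
    if k < 2:
        raise ValueError(f"tail size {k} too small (n={n}, q={q})")
    if 2 * k > n:
        raise ValueError(f"tails overlap: 2*ceil(q*n)={2 * k} exceeds n={n}")
    out = pace.copy()
    by_pace = out.reset_index().sort_values(
        ["pace", "sample_id"], ascending=[True, True], kind="mergesort"
    )["sample_id"]
    group = pd.Series(MIDDLE, index=out.index, name="group")
    group.loc[by_pace.iloc[:k]] = DECELERATOR
    group.loc[by_pace.iloc[-k:]] = ACCELERATOR
    out["group"] = group
    return out


def _group_values(samples: pd.DataFrame, groups: pd.Series, feature: str):
    acc = samples.loc[groups.index[groups == ACCELERATOR], feature].dropna()
    dec = samples.loc[groups.index[groups == DECELERATOR], feature].dropna()
    return acc.to_numpy(dtype=float), dec.to_numpy(dtype=float)


def compare_numeric_features(
    samples: pd.DataFrame,
    groups: pd.Series,
    features=None,
    p_cut: float = 0.05,
    test: str = "t",
) -> pd.DataFrame:
    """Accelerator-vs-decelerator tests for numeric features.

    Welch two-sided t-test by default (``test="wilcoxon"`` switches to the
    rank-sum test).  Effect is the accelerator-minus-decelerator mean
    difference; features with p below ``p_cut`` are flagged.  Features
    with zero variance in both groups are skipped (logged).
    """
    if features is None:
        features = [c for c in samples.columns if pd.api.types.is_numeric_dtype(samples[c])]
    rows = []
    for feat in features:
        acc, dec = _group_values(samples, groups, feat)
        if len(acc) < 3 or len(dec) < 3:
            log.info("compare_numeric_features: %r skipped (too few values)", feat)
            continue
        if np.ptp(acc) == 0 and np.ptp(dec) == 0:
            log.info("compare_numeric_features: %r skipped (zero variance)", feat)
            continue
        if test == "t":
            stat, p = stats.ttest_ind(acc, dec, equal_var=False)
            used = "welch_t"
        elif test == "wilcoxon":
            stat, p = stats.ranksums(acc, dec)
            used = "wilcoxon_rank_sum"
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "feature": feat,
                "modality": "phenotype",
                "effect": float(acc.mean() - dec.mean()),
                "statistic": float(stat),
                "p": float(p),
                "significant": bool(p < p_cut),
                "test": used,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature", "modality", "effect", "statistic", "p", "significant", "test"],
    )


def compare_binary_features(
    samples: pd.DataFrame,
    groups: pd.Series,
    features=None,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Chi-squared accelerator-vs-decelerator tests for dichotomous factors.

    Tables with an expected cell below 5 fall back to Fisher's exact test
    (noted in the ``test`` column).  Single-level features are skipped.
    """
    if features is None:
        features = [c for c in samples.columns]
    rows = []
    for feat in features:
        acc = samples.loc[groups.index[groups == ACCELERATOR], feat].dropna()
        dec = samples.loc[groups.index[groups == DECELERATOR], feat].dropna()
        levels = sorted(set(acc.unique()) | set(dec.unique()))
        if len(levels) != 2:
            log.info("compare_binary_features: %r skipped (not dichotomous)", feat)
            continue
        table = np.array(
            [
                [(acc == levels[0]).sum(), (acc == levels[1]).sum()],
                [(dec == levels[0]).sum(), (dec == levels[1]).sum()],
            ],
            dtype=float,
        )
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        if (expected < 5).any():
            stat = float("nan")
            _, p = stats.fisher_exact(table)
            used = "fisher_exact"
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            stat = float(stat)
            used = "chi_squared"
        p_acc = table[0, 1] / table[0].sum()
        p_dec = table[1, 1] / table[1].sum()
        rows.append(
            {
                "feature": feat,
                "modality": "lifestyle",
                "effect": float(p_acc - p_dec),
                "statistic": stat,
                "p": float(p),
                "significant": bool(p < p_cut),
                "test": used,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature", "modality", "effect", "statistic", "p", "significant", "test"],
    )


def differential_omics(
    matrix: pd.DataFrame,
    groups: pd.Series,
    detect_frac: float = 2.0 / 3.0,
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
    normalize: str = "sample_mean_log",
    adjust: bool = False,
    modality: str = "protein",
) -> pd.DataFrame:
    """Fold-change + t-test differential features between pace groups.

    ``matrix`` holds non-negative abundances (features x samples); zeros
    and NaN count as undetected.  Features detected in more than
    ``detect_frac`` of the accelerator+decelerator samples are retained;
    with ``normalize="sample_mean_log"`` each sample is divided by the
    mean of its detected values before log2 transformation (which makes
    the analysis invariant to per-run scale factors).  Each retained
    feature gets a Welch t-test on log2 values and a log2 fold change
    (accelerator vs decelerator group means); a feature passes when
    p < ``p_cut`` (BH-adjusted when ``adjust``, as used for transcripts)
    and |lfc| > ``lfc_cut``.
    """
    if (matrix.fillna(0) < 0).any().any():
        raise ValueError("abundances must be non-negative")
    acc_ids = [s for s in groups.index[groups == ACCELERATOR] if s in matrix.columns]
    dec_ids = [s for s in groups.index[groups == DECELERATOR] if s in matrix.columns]
    selected = acc_ids + dec_ids
    if len(acc_ids) < 2 or len(dec_ids) < 2:
        raise ValueError("need at least 2 samples per pace group")
    sub = matrix[selected]
    detected = sub.notna() & (sub > 0)
    keep = detected.sum(axis=1) > detect_frac * len(selected)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("differential_omics: %d features below detection threshold", n_drop)
    sub = sub.loc[keep]
    detected = detected.loc[keep]
    if sub.empty:
        return pd.DataFrame(
            columns=["feature", "modality", "effect", "statistic", "p", "p_adj", "significant", "test"]
        )

    vals = sub.where(detected)
    if normalize == "sample_mean_log":
        vals = vals / vals.mean(axis=0, skipna=True)
    elif normalize != "none":
        raise ValueError(f"unknown normalize {normalize!r}")
    logged = np.log2(vals)

    rows = []
    for feat in logged.index:
        acc = logged.loc[feat, acc_ids].dropna().to_numpy(dtype=float)
        dec = logged.loc[feat, dec_ids].dropna().to_numpy(dtype=float)
        if len(acc) < 2 or len(dec) < 2:
            log.info("differential_omics: %r skipped (too few detected values)", feat)
            continue
        lfc = float(acc.mean() - dec.mean())
        if np.ptp(acc) == 0 and np.ptp(dec) == 0:
            stat, p = float("nan"), 1.0 if lfc == 0 else 0.0
        else:
            stat, p = stats.ttest_ind(acc, dec, equal_var=False)
        rows.append(
            {
                "feature": feat,
                "modality": modality,
                "effect": lfc,
                "statistic": float(stat),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows, columns=["feature", "modality", "effect", "statistic", "p"])
    if out.empty:
        out["p_adj"] = []
        out["significant"] = []
        out["test"] = []
        return out
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    gate_p = out["p_adj"] if adjust else out["p"]
    out["significant"] = (gate_p < p_cut) & (out["effect"].abs() > lfc_cut)
    out["test"] = "welch_t_log2"
    return out
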