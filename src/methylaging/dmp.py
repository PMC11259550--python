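"""Age-related differential methylation position (DMP) calling.

Per-probe ordinary least squares of beta on age plus covariates (cell
proportions, sex, BMI), Benjamini-Hochberg correction across probes, and
joint effect-size/significance gating: a probe is an age-related DMP when
its BH-adjusted p-value is below ``alpha`` (default 0.01) and its absolute
age slope exceeds ``slope_threshold`` beta/year (default 0.002).  The
module also provides genomic-context composition of the called DMPs, a
1-Mb density scan for hotspots, and a sliding-window scan for the ages at
which methylation change concentrates.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_COND_LIMIT = 1e8


def fit_site_models(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = (),
) -> pd.DataFrame:
    """Per-probe OLS of beta on [age, covariates]; returns slope/se/t/p.

    The reported slope is the age coefficient in beta units per year; the
    p-value is the two-sided t-test on that coefficient.  Covariate columns
    must be numeric (sex encoded 0/1).  A near-collinear design raises an
    error naming the offending columns.
    """
    cols = ["age", *covariates]
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    sub = samples.loc[list(beta.columns), cols].astype(float)
    if sub.isna().any().any():
        raise ValueError("covariate table contains missing values")
    n = len(sub)
    if n <= len(cols) + 2:
        raise ValueError("need n > number of covariates + 2")

    x = np.column_stack([np.ones(n), sub.to_numpy()])
    cond = np.linalg.cond(x)
    if cond > _COND_LIMIT:
        raise ValueError(
            f"design matrix near-collinear (condition number {cond:.3g}); columns: {cols}"
        )
    y = beta.to_numpy(dtype=float).T  # n x p
    if np.isnan(y).any():
        raise ValueError("beta matrix contains missing values; impute upstream")

    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = xtx_inv @ x.T @ y  # (k+1) x p
    resid = y - x @ coefs
    dof = n - x.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coefs[1] / np.where(se > 0, se, 1.0), np.inf * np.sign(coefs[1]))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    out = pd.DataFrame(
        {"slope": coefs[1], "se": se, "t": t, "p": p}, index=beta.index
    )
    out.attrs["n"] = n
    out.attrs["dof"] = dof
    return out


def call_dmps(
    fits: pd.DataFrame,
    annot: pd.DataFrame | None = None,
    slope_threshold: float = 0.002,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Gate fitted probes into up/down/ns DMP records.

    BH adjustment is applied once across all tested probes; direction is
    the slope sign among probes passing both the adjusted-p and the
    absolute-slope gates.  Genomic context columns are attached from the
    annotation when provided.
    """
    out = fits.copy()
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    passing = (out["p_adj"] < alpha) & (out["slope"].abs() > slope_threshold)
    out["direction"] = np.where(
        passing, np.where(out["slope"] > 0, "up", "down"), "ns"
    )
    if annot is not None:
        for col in ("island_class", "feature_class", "chromosome", "position"):
            if col in annot.columns:
                out[col] = annot[col].reindex(out.index)
    return out


def context_composition(dmps: pd.DataFrame) -> pd.DataFrame:
    """Proportions of called DMPs by genomic context class and direction.

    Returns a long table (direction, class_type, cls, count, proportion);
    within each direction x class_type the proportions sum to 1.  Empty
    directions are logged and omitted.
    """
    rows = []
    for direction in ("up", "down"):
        sub = dmps.loc[dmps["direction"] == direction]
        if sub.empty:
            log.info("context_composition: no %s DMPs", direction)
            continue
        for class_type in ("island_class", "feature_class"):
            if class_type not in sub.columns:
                continue
            counts = sub[class_type].value_counts()
            total = counts.sum()
            for cls, cnt in counts.items():
                rows.append((direction, class_type, cls, int(cnt), cnt / total))
    return pd.DataFrame(
        rows, columns=["direction", "class_type", "cls", "count", "proportion"]
    )


def genomic_density(
    dmps: pd.DataFrame,
    annot: pd.DataFrame | None = None,
    bin_size: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.Series]:
    """DMP counts in half-open genomic bins [k*bin, (k+1)*bin) per chromosome.

    Returns the per-bin table and per-chromosome totals.  Probes without a
    position are excluded with a logged count.
    """
    called = dmps.loc[dmps["direction"].isin(["up", "down"])].copy()
    if annot is not None:
        for col in ("chromosome", "position"):
            if col not in called.columns:
                called[col] = annot[col].reindex(called.index)
    if called.empty:
        return (
            pd.DataFrame(columns=["chromosome", "bin_start", "count"]),
            pd.Series(dtype=int, name="count"),
        )
    has_pos = called["position"].notna() & called["chromosome"].notna()
    n_drop = int((~has_pos).sum())
    if n_drop:
        log.info("genomic_density: %d DMPs without position excluded", n_drop)
    called = called.loc[has_pos]
    called["bin_start"] = (called["position"].astype(np.int64) // bin_size) * bin_size
    bins = (
        called.groupby(["chromosome", "bin_start"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    per_chrom = called.groupby("chromosome", observed=True).size().rename("count")
    return bins, per_chrom


def sliding_window_dmp(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    window: float = 5.0,
    parcel: float = 5.0,
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Counts of probes changing significantly at each age, by sliding window.

    Candidate centers are placed every ``parcel`` years.  At center ``c``
    samples within ``window`` years of the center are dichotomised at the
    center (ages in [c-window, c) vs [c, c+window)), each probe is tested
    with a two-sample Welch t-test, and BH adjustment is applied across
    probes within the center.  A center with fewer than ``min_per_group``
    samples on either side is skipped (logged).  Returns one row per
    evaluated center: center age, significant-probe count, and the up/down
    split (up = higher methylation in the older group).
    """
    ages = samples.loc[list(beta.columns), "age"].to_numpy(dtype=float)
    y = beta.to_numpy(dtype=float)
    lo, hi = math.floor(ages.min()), math.ceil(ages.max())
    centers = np.arange(lo, hi + parcel / 2, parcel)
    rows = []
    for c in centers:
        young = (ages >= c - window) & (ages < c)
        old = (ages >= c) & (ages < c + window)
        if young.sum() < min_per_group or old.sum() < min_per_group:
            log.debug("sliding_window_dmp: center %.1f skipped (degenerate group)", c)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(y[:, old], y[:, young], axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        p_adj = multipletests(p, method="fdr_bh")[1]
        sig = p_adj < alpha
        diff = y[:, old].mean(axis=1) - y[:, young].mean(axis=1)
        n_up = int((sig & (diff > 0)).sum())
        n_down = int((sig & (diff <= 0)).sum())
        rows.append(
            {
                "center": float(c),
                "n_significant": int(sig.sum()),
                "n_up": n_up,
                "n_down": n_down,
                "n_younger": int(young.sum()),
                "n_older": int(old.sum()),
            }
        )
    return pd.DataFrame(rows)
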