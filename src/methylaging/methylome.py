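"""Beta-value computation, global methylome summaries, probe filtering, and
reference-based cell-type deconvolution.

The central substrate is the *beta matrix*: a ``pandas.DataFrame`` of
methylation fractions in [0, 1] with CpG probe ids as the row index and
sample ids as columns.  A probe's beta value is the fraction of methylated
signal, ``M / (M + U)``, where M and U are the methylated and unmethylated
intensities.

Cell-type composition is estimated by constrained projection of each
sample's methylome onto purified reference profiles (the projection step of
reference-based deconvolution): non-negative least squares with a
sum-to-one constraint.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

log = logging.getLogger(__name__)

ISLAND_CLASSES = ("Island", "Shore", "Shelf", "OpenSea")
FEATURE_CLASSES = (
    "TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "ExonBnd", "3'UTR", "IGR",
)
PROMOTER_FEATURES = ("TSS200", "TSS1500")

#: The six whole-blood leukocyte types resolved by the reference panel.
BLOOD_CELL_TYPES = ("CD8T", "CD4T", "NK", "Mono", "Bcell", "Neu")

_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

# weight of the sum-to-one penalty row in the deconvolution NNLS
_SUM_PENALTY = 1000.0


def compute_beta(m, u):
    """Methylation fraction M/(M+U).

    Accepts scalars or arrays.  Negative intensities raise ``ValueError``;
    positions with M + U == 0 yield NaN (missing) and are counted in a log
    message.
    """
    m_arr = np.asarray(m, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if np.any(m_arr < 0) or np.any(u_arr < 0):
        raise ValueError("intensities must be non-negative")
    total = m_arr + u_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m_arr / np.where(total > 0, total, 1.0), np.nan)
    n_missing = int(np.sum(total == 0))
    if n_missing:
        log.info("compute_beta: %d positions with M+U=0 set to missing", n_missing)
    if np.isscalar(m) and np.isscalar(u):
        return float(beta)
    return beta


def filter_probes(
    beta: pd.DataFrame,
    annot: pd.DataFrame | None = None,
    exclude: Mapping[str, Iterable[str]] | Iterable[str] = (),
    drop_sex: bool = False,
) -> pd.DataFrame:
    """Remove excluded probe ids and, optionally, sex-chromosome probes.

    ``exclude`` is either a mapping of named exclusion lists (e.g.
    ``{"snp": [...], "multihit": [...]}``) or a flat iterable of probe ids.
    Excluded ids absent from the matrix are ignored (count logged).  Row
    order of the surviving probes is preserved, which also makes the
    operation idempotent.  An empty result raises an error naming the
    filter responsible.
    """
    if isinstance(exclude, Mapping):
        named = {str(k): set(v) for k, v in exclude.items()}
    else:
        named = {"exclude": set(exclude)} if len(list(exclude)) else {}

    out = beta
    for name, ids in named.items():
        missing = len(ids - set(out.index))
        if missing:
            log.info("filter_probes: %d ids in list %r not present", missing, name)
        out = out.loc[~out.index.isin(ids)]
        if out.shape[0] == 0:
            raise ValueError(f"probe filter {name!r} removed all probes")
    if drop_sex:
        if annot is None:
            raise ValueError("drop_sex=True requires a probe annotation")
        chrom = annot["chromosome"].reindex(out.index)
        out = out.loc[~chrom.isin(_SEX_CHROMS)]
        if out.shape[0] == 0:
            raise ValueError("sex-chromosome filter removed all probes")
    return out


def mean_methylation(beta: pd.DataFrame) -> pd.Series:
    """Per-sample arithmetic mean beta over non-missing probes."""
    all_missing = beta.isna().all(axis=0)
    if all_missing.any():
        bad = list(beta.columns[all_missing])
        raise ValueError(f"samples with no non-missing probes: {bad}")
    return beta.mean(axis=0, skipna=True)


def methylation_entropy(beta: pd.DataFrame, eps: float = 1e-6) -> pd.Series:
    """Per-sample mean binary Shannon entropy of the methylome, in [0, 1].

    For each probe the entropy of a Bernoulli(beta) variable,
    ``-(b*log2(b) + (1-b)*log2(1-b))``, is computed after clipping betas to
    ``[eps, 1-eps]``; the per-sample value is the mean over non-missing
    probes.  Fully polarised methylomes (all betas 0/1) have entropy -> 0,
    a fully intermediate methylome (all 0.5) has entropy 1.  The measure is
    symmetric under beta -> 1 - beta.
    """
    vals = beta.to_numpy(dtype=float)
    b = np.clip(vals, eps, 1.0 - eps)
    h = -(b * np.log2(b) + (1.0 - b) * np.log2(1.0 - b))
    h = np.where(np.isnan(vals), np.nan, h)
    return pd.Series(np.nanmean(h, axis=0), index=beta.columns, name="entropy")


def estimate_cell_proportions(beta: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Reference-based cell-proportion estimates (samples x cell types).

    Solves, per sample, a least-squares projection of the sample's marker
    betas on the reference profiles subject to non-negativity and a
    sum-to-one constraint (implemented as NNLS with a heavily weighted
    sum row, then exact renormalisation).
    """
    k = ref.shape[1]
    if k < 2:
        raise ValueError("reference must contain at least 2 cell types")
    shared = ref.index.intersection(beta.index)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} marker probes shared between beta and reference; need >= {k}"
        )
    r_full = ref.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(r_full) < k:
        raise ValueError("reference matrix is rank-deficient")

    sub = beta.loc[shared]
    out = np.empty((beta.shape[1], k))
    penalty = np.full(k, _SUM_PENALTY)
    for j, sample in enumerate(sub.columns):
        y = sub[sample].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < k:
            raise ValueError(f"sample {sample!r} has fewer than {k} usable markers")
        a = np.vstack([r_full[ok], penalty])
        b = np.concatenate([y[ok], [_SUM_PENALTY]])
        props, _ = nnls(a, b)
        total = props.sum()
        if total <= 0:
            raise ValueError(f"deconvolution degenerate for sample {sample!r}")
        out[j] = props / total
    return pd.DataFrame(out, index=beta.columns, columns=ref.columns)
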