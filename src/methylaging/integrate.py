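"""Methylome-transcriptome integration.

Links differentially methylated probes to candidate target genes with an
extreme-group design: for each probe, the 20% highest-methylated samples
(group M) and 20% lowest-methylated samples (group U) are compared on the
expression of the nearest candidate genes with a one-sided Mann-Whitney
U-test (alternative: expression lower in M, i.e. methylation and
expression anti-correlated).  Significance is assessed against an
empirical null built by recomputing the same statistic for randomly drawn
non-candidate genes, with the add-one rule so the empirical p-value is
never zero.  Motif enrichment in direction-specific probe sets is scored
with Fisher's exact test, a Wald 95% CI on the log odds ratio, and a
minimum occurrence count; transcription-factor involvement is checked by
correlating the motif's mean methylation with the TF gene's expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylome import PROMOTER_FEATURES

log = logging.getLogger(__name__)


def select_feature_probes(dmps: pd.DataFrame, annot: pd.DataFrame) -> pd.Index:
    """Called DMPs in distal or promoter (TSS200/TSS1500) regions."""
    called = dmps.loc[dmps["direction"].isin(["up", "down"])]
    distal = annot["distal_flag"].reindex(called.index).fillna(False).astype(bool)
    promoter = annot["feature_class"].reindex(called.index).isin(PROMOTER_FEATURES)
    return called.index[distal | promoter]


def build_gene_order(
    probe_coords: pd.DataFrame,
    gene_meta: pd.DataFrame,
    probes=None,
    n_each: int = 10,
) -> dict[str, pd.DataFrame]:
    """Rank the nearest genes up/downstream of each probe.

    ``probe_coords`` and ``gene_meta`` need ``chromosome`` and ``position``
    columns.  For each probe the ``n_each`` nearest genes on each side get
    signed ranks -n..-1 (upstream) and +1..+n (downstream).  Returns a
    mapping probe id -> DataFrame(gene_id, rank).
    """
    if probes is None:
        probes = probe_coords.index
    by_chrom = {
        c: sub.sort_values("position")
        for c, sub in gene_meta.reset_index().groupby("chromosome", observed=True)
    }
    out: dict[str, pd.DataFrame] = {}
    for probe in probes:
        chrom = probe_coords.at[probe, "chromosome"]
        pos = probe_coords.at[probe, "position"]
        genes = by_chrom.get(chrom)
        if genes is None:
            out[probe] = pd.DataFrame(columns=["gene_id", "rank"])
            continue
        up = genes.loc[genes["position"] < pos].iloc[::-1].head(n_each)
        down = genes.loc[genes["position"] >= pos].head(n_each)
        rows = [
            (g, -(i + 1)) for i, g in enumerate(up["gene_id"])
        ] + [
            (g, i + 1) for i, g in enumerate(down["gene_id"])
        ]
        out[probe] = pd.DataFrame(rows, columns=["gene_id", "rank"])
    return out


def _extreme_groups(bvec: pd.Series, q: float) -> tuple[list, list]:
    """Sample ids of the top/bottom q fractions by beta (deterministic ties)."""
    n = len(bvec)
    m = int(np.floor(q * n))
    if m < 2:
        raise ValueError(f"extreme-group size {m} too small (n={n}, q={q})")
    ordered = bvec.sort_values(kind="mergesort")  # stable: ties by sample order
    low = list(ordered.index[:m])
    high = list(ordered.index[-m:])
    return high, low


def probe_gene_pairs(
    probes,
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    gene_order: dict[str, pd.DataFrame],
    directions: pd.Series,
    q: float = 0.20,
    n_perm: int = 1000,
    seed: int | None = None,
    emp_alpha: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Probe-gene pairs with one-sided rank-sum and empirical p-values.

    For each probe, samples are ranked by its beta; the top/bottom ``q``
    fractions form groups M and U, and each candidate gene is tested for
    lower expression in M (one-sided Mann-Whitney).  The empirical p-value
    re-computes the same test on ``n_perm`` genes drawn at random from the
    non-candidate pool (one draw set per probe) and applies the add-one
    rule, so it lies in (0, 1].  Pairs with empirical p below
    ``emp_alpha`` are returned (all tested pairs when ``return_all``),
    labelled ``repressed`` for hypermethylating probes and ``activated``
    for hypomethylating ones.
    """
    shared = [s for s in beta.columns if s in set(expr.columns)]
    if len(shared) < 10:
        raise ValueError("need at least 10 samples shared between beta and expression")
    rng = np.random.default_rng(seed)
    expr_sub = expr[shared]
    all_genes = expr_sub.index
    rows = []
    for probe in probes:
        if probe not in beta.index or probe not in gene_order:
            log.info("probe_gene_pairs: probe %r skipped (no data/candidates)", probe)
            continue
        cand = gene_order[probe]
        if cand.empty:
            continue
        high, low = _extreme_groups(beta.loc[probe, shared], q)
        e_m_all = expr_sub[high]
        e_u_all = expr_sub[low]

        pool = all_genes.difference(cand["gene_id"])
        if len(pool) == 0 or n_perm <= 0:
            raise ValueError("empty permutation gene pool")
        draw = pool[rng.integers(0, len(pool), size=n_perm)]
        with np.errstate(invalid="ignore"):
            null_p = stats.mannwhitneyu(
                e_m_all.loc[draw].to_numpy(),
                e_u_all.loc[draw].to_numpy(),
                alternative="less",
                axis=1,
            ).pvalue
        null_p = null_p[~np.isnan(null_p)]
        n_null = len(null_p)
        if n_null == 0:
            raise ValueError("all permutation draws degenerate")

        direction = directions.get(probe, "up")
        for _, crow in cand.iterrows():
            gene = crow["gene_id"]
            if gene not in expr_sub.index:
                log.info("probe_gene_pairs: gene %r absent from expression", gene)
                continue
            e_m = e_m_all.loc[gene].to_numpy(dtype=float)
            e_u = e_u_all.loc[gene].to_numpy(dtype=float)
            if np.ptp(np.concatenate([e_m, e_u])) == 0:
                log.info("probe_gene_pairs: gene %r constant in extreme groups", gene)
                continue
            p_u = stats.mannwhitneyu(e_m, e_u, alternative="less").pvalue
            emp = (1 + int(np.sum(null_p <= p_u))) / (1 + n_null)
            rows.append(
                {
                    "probe_id": probe,
                    "gene_id": gene,
                    "rank": int(crow["rank"]),
                    "u_p": float(p_u),
                    "empirical_p": float(emp),
                    "pair_class": "repressed" if direction == "up" else "activated",
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["probe_id", "gene_id", "rank", "u_p", "empirical_p", "pair_class"],
    )
    if return_all:
        return out
    return out.loc[out["empirical_p"] < emp_alpha].reset_index(drop=True)


def motif_enrichment(
    probe_set,
    motif_table: pd.DataFrame,
    background,
    min_count: int = 10,
    or_lower: float = 1.1,
    alpha: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Motif over-representation in a probe set vs the remaining background.

    Per motif a 2x2 table (probe in set vs rest of background x motif
    present vs absent) yields a one-sided Fisher exact p (BH-adjusted
    across motifs), an odds ratio with Haldane-Anscombe 0.5 correction
    when a cell is zero, and a Wald 95% CI on the log odds ratio.  A motif
    is enriched when its in-set occurrence count is at least
    ``min_count``, the CI lower bound exceeds ``or_lower``, and the
    adjusted p is below ``alpha``.
    """
    probe_set = set(probe_set)
    background = set(background)
    if not probe_set <= background:
        raise ValueError("probe_set must be a subset of background")
    rest = background - probe_set
    n_set, n_rest = len(probe_set), len(rest)

    tab = motif_table.loc[motif_table["probe_id"].isin(background)]
    rows = []
    for motif, sub in sorted(tab.groupby("motif_id", observed=True), key=lambda kv: kv[0]):
        hits = set(sub["probe_id"])
        a = len(hits & probe_set)
        c = len(hits & rest)
        b, d = n_set - a, n_rest - c
        if a + c == 0:
            log.info("motif_enrichment: motif %r absent from background", motif)
            continue
        if b == 0 and d == 0:
            # motif present in every probe of both groups: no association
            odds, ci_lo, ci_hi = 1.0, 0.0, float("inf")
        else:
            cells = np.array([a, b, c, d], dtype=float)
            if np.any(cells == 0):
                cells = cells + 0.5
            odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
            se_log = float(np.sqrt(np.sum(1.0 / cells)))
            ci_lo = float(np.exp(np.log(odds) - 1.96 * se_log))
            ci_hi = float(np.exp(np.log(odds) + 1.96 * se_log))
        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        rows.append(
            {
                "motif_id": motif,
                "count": a,
                "odds_ratio": float(odds),
                "or_ci_low": ci_lo,
                "or_ci_high": ci_hi,
                "p": float(p),
            }
        )
    out = pd.DataFrame(
        rows, columns=["motif_id", "count", "odds_ratio", "or_ci_low", "or_ci_high", "p"]
    )
    if out.empty:
        out["p_adj"] = []
        out["enriched"] = []
        return out
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["enriched"] = (
        (out["count"] >= min_count)
        & (out["or_ci_low"] > or_lower)
        & (out["p_adj"] < alpha)
    )
    if return_all:
        return out.reset_index(drop=True)
    return out.loc[out["enriched"]].reset_index(drop=True)


def tf_methylation_correlation(
    motif_probes,
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    tf_gene: str,
) -> tuple[float, float]:
    """Pearson correlation of a motif's mean methylation with TF expression.

    The per-sample mean beta over the motif's member probes is correlated
    with the expression of the TF-coding gene; returns (r, two-sided p).
    """
    if tf_gene not in expr.index:
        raise ValueError(f"TF gene {tf_gene!r} absent from expression matrix")
    probes = [p for p in motif_probes if p in beta.index]
    if not probes:
        raise ValueError("no motif probes present in beta matrix")
    shared = [s for s in beta.columns if s in set(expr.columns)]
    mean_beta = beta.loc[probes, shared].mean(axis=0)
    if mean_beta.std() == 0:
        raise ValueError("mean methylation constant across samples; correlation undefined")
    r, p = stats.pearsonr(mean_beta.to_numpy(), expr.loc[tf_gene, shared].to_numpy())
    return float(r), float(p)
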