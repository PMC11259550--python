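import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylaging import integrate, simulate
from methylaging.integrate import (
    _extreme_groups,
    build_gene_order,
    motif_enrichment,
    probe_gene_pairs,
    select_feature_probes,
    tf_methylation_correlation,
)

from oracles import fisher_greater_p, log_or_ci, pearson_r, ranksum_enumeration_p


def test_select_feature_probes_rule_enumerated():
    dmps = pd.DataFrame(
        {"direction": ["up", "up", "down", "down", "up", "ns"]},
        index=list("abcdef"),
    )
    annot = pd.DataFrame(
        {
            "feature_class": ["TSS200", "Body", "TSS1500", "Body", "Body", "TSS200"],
            "distal_flag": [False, False, False, True, False, False],
        },
        index=list("abcdef"),
    )
    kept = set(select_feature_probes(dmps, annot))
    # by hand: a (promoter), c (promoter), d (distal) pass; b, e fail the
    # predicate; f is not a called DMP
    assert kept == {"a", "c", "d"}


def _toy_pairing(expr_extreme_values, n_perm=2000, seed=0):
    """20 samples; probe beta strictly increasing; one candidate gene whose
    8 extreme-sample expression values are given, plus a null pool of all
    70 arrangements of those values over the extreme samples."""
    n = 20
    samples = [f"S{i:02d}" for i in range(n)]
    beta = pd.DataFrame([np.linspace(0.1, 0.9, n)], index=["cg1"], columns=samples)
    low4, high4 = samples[:4], samples[-4:]
    mid = samples[4:-4]
    base = pd.Series(5.0, index=samples)

    import itertools

    vals = list(expr_extreme_values)  # first 4 -> U samples, last 4 -> M samples
    extreme = low4 + high4
    rows = {}
    gene0 = "g_obs"
    obs = base.copy()
    obs[extreme] = vals
    rows[gene0] = obs
    k = 0
    for combo in itertools.combinations(range(8), 4):
        k += 1
        arr = base.copy()
        m_vals = [vals[i] for i in combo]
        u_vals = [vals[i] for i in range(8) if i not in combo]
        arr[high4] = m_vals
        arr[low4] = u_vals
        rows[f"perm{k:02d}"] = arr
    expr = pd.DataFrame(rows).T
    gene_order = {"cg1": pd.DataFrame({"gene_id": [gene0], "rank": [1]})}
    directions = pd.Series({"cg1": "up"})
    res = probe_gene_pairs(
        ["cg1"], beta, expr, gene_order, directions,
        q=0.2, n_perm=n_perm, seed=seed, return_all=True,
    )
    m_vals_obs = obs[high4].to_numpy()
    u_vals_obs = obs[low4].to_numpy()
    return res, m_vals_obs, u_vals_obs


def test_rank_sum_p_matches_exhaustive_enumeration():
    # expression anti-correlated with beta: M group holds the 4 lowest values
    res, m_vals, u_vals = _toy_pairing([8, 7, 6, 5, 1, 2, 3, 4])
    exact = ranksum_enumeration_p(m_vals, u_vals)
    assert exact == pytest.approx(1 / 70)
    assert res["u_p"].iloc[0] == pytest.approx(exact, rel=1e-10)


def test_empirical_p_converges_to_enumeration_on_permutation_pool():
    # moderately anti-correlated arrangement: exact p = k/70 with k > 1
    arrangement = [8, 7, 5, 6, 1, 3, 2, 4]
    res, m_vals, u_vals = _toy_pairing(arrangement, n_perm=6000, seed=1)
    exact = ranksum_enumeration_p(m_vals, u_vals)
    emp = res["empirical_p"].iloc[0]
    assert 0 < emp <= 1
    assert emp == pytest.approx(exact, abs=0.02)


def test_identical_expression_in_groups_is_rejected():
    res, _, _ = _toy_pairing([5.5, 5.5, 5.5, 5.5, 5.6, 5.6, 5.6, 5.6], n_perm=200)
    # M group holds the larger values: one-sided (less) p must be >= 0.5
    assert res["u_p"].iloc[0] >= 0.5


def test_extreme_groups_swap_under_beta_flip():
    bvec = pd.Series([0.1, 0.9, 0.3, 0.7, 0.5, 0.2, 0.8, 0.4, 0.6, 0.35],
                     index=[f"S{i}" for i in range(10)])
    m1, u1 = _extreme_groups(bvec, 0.2)
    m2, u2 = _extreme_groups(1.0 - bvec, 0.2)
    assert set(m1) == set(u2) and set(u1) == set(m2)


def test_linked_cohort_pair_recovery(linked_cohort):
    beta, samples, annot, truth, expr, gene_meta = linked_cohort
    coords = simulate.shared_coordinates(truth)
    probes = list(truth.links["probe_id"])
    gene_order = build_gene_order(coords, gene_meta, probes=probes)
    directions = truth.probes["cls"].map({"up": "up", "down": "down"}).fillna("up")
    pairs = probe_gene_pairs(
        probes, beta, expr, gene_order, directions, n_perm=500, seed=5
    )
    true_pairs = set(zip(truth.links["probe_id"], truth.links["gene_id"]))
    found = set(zip(pairs["probe_id"], pairs["gene_id"]))
    recovered = len(found & true_pairs) / len(true_pairs)
    n_tested = sum(len(gene_order[p]) for p in probes)
    n_null_tested = n_tested - len(true_pairs)
    false_rate = (len(found) - len(found & true_pairs)) / n_null_tested
    assert recovered >= 0.8
    assert false_rate <= 0.10


def test_motif_or_one_when_uniform():
    probes = [f"p{i}" for i in range(40)]
    table = pd.DataFrame({"motif_id": "M1", "probe_id": probes})
    out = motif_enrichment(probes[:10], table, probes, return_all=True)
    assert out["odds_ratio"].iloc[0] == pytest.approx(1.0)
    assert not out["enriched"].iloc[0]


def test_motif_oracle_table_and_gates():
    # in-set: 30 of 100 carry the motif; rest of background: 50 of 1000
    probe_set = [f"s{i}" for i in range(100)]
    rest = [f"r{i}" for i in range(1000)]
    hits = probe_set[:30] + rest[:50]
    table = pd.DataFrame({"motif_id": "M1", "probe_id": hits})
    out = motif_enrichment(probe_set, table, probe_set + rest, return_all=True)
    row = out.iloc[0]
    or_ref, lo_ref, hi_ref = log_or_ci(30, 70, 50, 950)
    assert row["odds_ratio"] == pytest.approx(or_ref, rel=1e-12)
    assert row["or_ci_low"] == pytest.approx(lo_ref, rel=1e-9)
    assert row["or_ci_high"] == pytest.approx(hi_ref, rel=1e-9)
    assert row["p"] == pytest.approx(fisher_greater_p(30, 70, 50, 950), rel=1e-9)
    assert row["count"] == 30 and row["enriched"]


def test_motif_min_count_gate_rejects_rare_motif():
    probe_set = [f"s{i}" for i in range(50)]
    rest = [f"r{i}" for i in range(2000)]
    # 9 in-set occurrences, none outside: enormous OR but below min_count
    table = pd.DataFrame({"motif_id": "M1", "probe_id": probe_set[:9]})
    out = motif_enrichment(probe_set, table, probe_set + rest, return_all=True)
    assert out["odds_ratio"].iloc[0] > 5
    assert not out["enriched"].iloc[0]


def test_motif_output_invariant_to_table_row_order():
    rng = np.random.default_rng(3)
    probes = [f"p{i}" for i in range(300)]
    rows = []
    for m in range(5):
        hit = rng.random(300) < (0.3 if m == 0 else 0.05)
        rows += [(f"M{m}", p) for p, h in zip(probes, hit) if h]
    table = pd.DataFrame(rows, columns=["motif_id", "probe_id"])
    shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = motif_enrichment(probes[:60], table, probes, return_all=True)
    b = motif_enrichment(probes[:60], shuffled, probes, return_all=True)
    pd.testing.assert_frame_equal(a, b)


def test_tf_correlation_exact_and_textbook_oracle():
    rng = np.random.default_rng(2)
    samples = [f"S{i}" for i in range(50)]
    beta = pd.DataFrame(rng.uniform(0, 1, (3, 50)), index=["a", "b", "c"], columns=samples)
    mean_beta = beta.mean(axis=0)
    expr = pd.DataFrame({"TF1": -mean_beta, "TF2": rng.normal(0, 1, 50)}).T
    r, p = tf_methylation_correlation(["a", "b", "c"], beta, expr, "TF1")
    assert r == pytest.approx(-1.0, abs=1e-12) and p < 1e-10
    r2, _ = tf_methylation_correlation(["a", "b", "c"], beta, expr, "TF2")
    assert r2 == pytest.approx(
        pearson_r(mean_beta.to_numpy(), expr.loc["TF2"].to_numpy()), abs=1e-12
    )


def test_tf_correlation_constant_beta_errors():
    beta = pd.DataFrame(0.5, index=["a"], columns=[f"S{i}" for i in range(20)])
    expr = pd.DataFrame(
        np.random.default_rng(0).normal(size=(1, 20)), index=["TF1"], columns=beta.columns
    )
    with pytest.raises(ValueError, match="constant"):
        tf_methylation_correlation(["a"], beta, expr, "TF1")
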