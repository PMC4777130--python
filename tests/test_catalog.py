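"""Fisher combination, two-tier calls, breadth classes, Jaccard, GO."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecdyatlas.catalog import (CatalogError, call_responsive, fisher_combine,
                               fisher_survival_series, go_enrichment,
                               jaccard_cluster, jaccard_matrix,
                               summarize_catalog)

from conftest import make_de_table


# ---------------------------------------------------------------------------
# Fisher statistic against the closed-form chi-square oracle
# ---------------------------------------------------------------------------

def test_fisher_worked_example_against_series_oracle():
    """u = (0.1, 0.2, 0.5) -> X = 9.2103, p ~ 0.162 (chi2_6 upper tail)."""
    u = np.array([0.1, 0.2, 0.5])
    x = float(-2 * np.log(u).sum())
    assert x == pytest.approx(9.2103, abs=1e-4)
    oracle = fisher_survival_series(x, 6)
    half = x / 2
    assert oracle == pytest.approx(
        math.exp(-half) * (1 + half + half**2 / 2), rel=1e-12)
    assert oracle == pytest.approx(0.162, abs=5e-4)
    assert stats.chi2.sf(x, 6) == pytest.approx(oracle, rel=1e-10)


def test_all_u_one_gives_zero_statistic_and_p_one():
    u = np.ones(5)
    x = float(-2 * np.log(u).sum())
    assert x == 0.0
    assert fisher_survival_series(x, 10) == pytest.approx(1.0)


def test_fisher_combine_ranks_wrong_direction_at_bottom():
    """A repressed gene must score worse for induction than any induced gene."""
    genes = [f"g{i}" for i in range(30)]
    rng = np.random.default_rng(0)
    tables = {}
    for line in ("L1", "L2", "L3"):
        lfc = rng.standard_normal(30)
        lfc[0] = 2.0   # g0 always induced with tiny p
        lfc[1] = -2.0  # g1 always repressed
        p = rng.uniform(0.2, 1.0, 30)
        p[0] = 1e-6
        p[1] = 1e-6
        tables[line] = make_de_table(genes, lfc, p, line=line)
    fi = fisher_combine(tables, "induction")
    # g0 achieves the best attainable combination at this universe size
    assert fi.loc["g0", "p_fisher"] == fi["p_fisher"].min()
    assert fi.loc["g1", "p_fisher"] > 0.1


def test_fisher_monotone_in_single_line_evidence():
    genes = [f"g{i}" for i in range(50)]
    rng = np.random.default_rng(1)
    base_p = rng.uniform(0, 1, 50)
    lfc = np.abs(rng.standard_normal(50))  # all induced
    tables = {"L1": make_de_table(genes, lfc, base_p, line="L1"),
              "L2": make_de_table(genes, lfc, rng.uniform(0, 1, 50), line="L2")}
    before = fisher_combine(tables, "induction").loc["g5", "p_fisher"]
    improved = base_p.copy()
    improved[5] = base_p[5] / 100
    tables["L1"] = make_de_table(genes, lfc, improved, line="L1")
    after = fisher_combine(tables, "induction").loc["g5", "p_fisher"]
    assert after < before


def test_fisher_requires_nonempty_inputs():
    with pytest.raises(CatalogError):
        fisher_combine({}, "induction")
    with pytest.raises(CatalogError):
        fisher_combine({"L": make_de_table([], [], [])}, "induction")


# ---------------------------------------------------------------------------
# two-tier per-line calls
# ---------------------------------------------------------------------------

def _call_one(lfc, p_raw, p_adj, p_fisher_ind=1.0, p_fisher_rep=1.0):
    genes = ["g"]
    tab = make_de_table(genes, [lfc], [p_raw], [p_adj])
    fi = pd.DataFrame({"p_fisher": [p_fisher_ind]}, index=genes)
    fr = pd.DataFrame({"p_fisher": [p_fisher_rep]}, index=genes)
    return int(call_responsive({"L1": tab}, fi, fr).iloc[0, 0])


@pytest.mark.parametrize("lfc,p_raw,p_adj,pf_ind,expected", [
    (0.9, 1e-6, 1e-6, 1e-12, 0),    # fails the two-fold gate
    (1.5, 0.005, 0.5, 1e-12, 1),    # relaxed tier rescue
    (1.5, 0.05, 0.5, 1e-12, 0),     # both tiers fail regardless of Fisher
    (1.5, 0.5, 0.005, 1.0, 1),      # strict tier alone
    (-1.5, 0.005, 0.5, 1e-12, 0),   # relaxed tier needs same-direction Fisher
])
def test_two_tier_call_rules(lfc, p_raw, p_adj, pf_ind, expected):
    assert _call_one(lfc, p_raw, p_adj, p_fisher_ind=pf_ind) == expected


def test_repressed_relaxed_tier_uses_repression_fisher():
    assert _call_one(-1.5, 0.005, 0.5, p_fisher_rep=1e-12) == -1


# ---------------------------------------------------------------------------
# catalog summary
# ---------------------------------------------------------------------------

def _dummy_fisher(genes, p=1.0):
    return pd.DataFrame({"p_fisher": p}, index=pd.Index(genes, name="gene_id"))


def test_widespread_needs_more_than_half_of_lines():
    genes = ["g_wide", "g_half", "g_restricted"]
    n_lines = 41
    calls = pd.DataFrame(0, index=genes,
                         columns=[f"L{i}" for i in range(n_lines)],
                         dtype=np.int8)
    calls.iloc[0, :21] = 1   # 21 of 41 -> widespread
    calls.iloc[1, :20] = 1   # 20 of 41 -> restricted (not > half)
    calls.iloc[2, :3] = 1
    cat = summarize_catalog(calls, _dummy_fisher(genes), _dummy_fisher(genes))
    assert cat.gene_summary.loc["g_wide", "breadth_induced"] == "widespread"
    assert cat.gene_summary.loc["g_half", "breadth_induced"] == "restricted"
    assert cat.gene_summary.loc["g_restricted", "breadth_induced"] == "restricted"


def test_weak_flag_requires_fisher_without_any_call():
    genes = ["g_weak", "g_called"]
    calls = pd.DataFrame(0, index=genes, columns=["L1", "L2", "L3"],
                         dtype=np.int8)
    calls.loc["g_called", "L1"] = 1
    fi = _dummy_fisher(genes, p=[1e-10, 1e-10])
    cat = summarize_catalog(calls, fi, _dummy_fisher(genes))
    assert bool(cat.gene_summary.loc["g_weak", "weak_induced"])
    assert not bool(cat.gene_summary.loc["g_called", "weak_induced"])


def test_bidirectional_and_rgc_conservation():
    genes = ["g1", "g2", "g3"]
    calls = pd.DataFrame([[1, -1, 0], [1, 1, 0], [0, 0, -1]],
                         index=genes, columns=["L1", "L2", "L3"]).astype(np.int8)
    cat = summarize_catalog(calls, _dummy_fisher(genes), _dummy_fisher(genes))
    assert bool(cat.gene_summary.loc["g1", "bidirectional"])
    assert not bool(cat.gene_summary.loc["g2", "bidirectional"])
    assert cat.line_summary["rgc"].sum() == int((calls != 0).sum().sum())


def test_weak_partition_disjoint_from_calls(small_analysis):
    gs = small_analysis["catalog"].gene_summary
    assert not (gs["weak_induced"] & (gs["n_induced_lines"] > 0)).any()
    assert not (gs["weak_repressed"] & (gs["n_repressed_lines"] > 0)).any()
    # every called gene-direction is exactly one of widespread/restricted
    called = gs[gs["n_induced_lines"] > 0]
    assert set(called["breadth_induced"]) <= {"widespread", "restricted"}


# ---------------------------------------------------------------------------
# Jaccard clustering
# ---------------------------------------------------------------------------

def test_jaccard_values():
    m = jaccard_matrix({"a": {"g1", "g2"}, "b": {"g2", "g3"},
                        "c": {"g1", "g2"}, "d": set()})
    assert m.loc["a", "b"] == pytest.approx(1 / 3)
    assert m.loc["a", "c"] == 1.0
    assert m.loc["d", "d"] == 0.0  # both empty -> 0 by convention


def test_planted_line_blocks_recovered_by_clustering():
    """Two groups of lines sharing restricted programs split at the top."""
    genes = [f"g{i}" for i in range(40)]
    lines = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
    calls = pd.DataFrame(0, index=genes, columns=lines, dtype=np.int8)
    rng = np.random.default_rng(5)
    for l in lines[:4]:
        calls.loc[[f"g{i}" for i in rng.choice(20, 12, replace=False)], l] = 1
    for l in lines[4:]:
        calls.loc[[f"g{i}" for i in 20 + rng.choice(20, 12, replace=False)], l] = 1
    cat = summarize_catalog(calls, _dummy_fisher(genes), _dummy_fisher(genes))
    sims, z, order = jaccard_cluster(cat)
    from scipy.cluster.hierarchy import fcluster
    labels = fcluster(z, t=2, criterion="maxclust")
    groups = {}
    for line, lab in zip(sims["combined"].index, labels):
        groups.setdefault(lab, set()).add(line)
    assert set(frozenset(g) for g in groups.values()) == {
        frozenset(lines[:4]), frozenset(lines[4:])}


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def test_hypergeometric_matches_bruteforce_sum():
    """Universe 100, term 10, set 10, overlap 5 vs exact combinatorial sum."""
    universe = [f"g{i}" for i in range(100)]
    term_genes = universe[:10]
    gene_set = universe[:5] + universe[50:55]
    gene2go = pd.DataFrame({"gene_id": universe, "term": "T0"})
    gene2go = pd.concat([
        gene2go,
        pd.DataFrame({"gene_id": term_genes, "term": "T1"})])
    res = go_enrichment(gene_set, universe, gene2go)
    exact = sum(math.comb(10, i) * math.comb(90, 10 - i)
                for i in range(5, 11)) / math.comb(100, 10)
    assert res.loc["T1", "p"] == pytest.approx(exact, rel=1e-12)
    assert res.loc["T1", "overlap"] == 5


def test_term_covering_universe_is_unenriched():
    universe = [f"g{i}" for i in range(50)]
    gene2go = pd.DataFrame({"gene_id": universe, "term": "ALL"})
    res = go_enrichment(universe[:7], universe, gene2go)
    assert res.loc["ALL", "fold_enrichment"] == pytest.approx(1.0)
    assert res.loc["ALL", "p"] == pytest.approx(1.0)


def test_random_sets_give_uniform_term_p_values():
    rng = np.random.default_rng(11)
    universe = [f"g{i}" for i in range(400)]
    rows = []
    for t in range(150):
        size = int(rng.integers(10, 40))
        for g in rng.choice(universe, size, replace=False):
            rows.append({"gene_id": g, "term": f"T{t}"})
    gene2go = pd.DataFrame(rows)
    gene2go = pd.concat([gene2go, pd.DataFrame({"gene_id": universe,
                                                "term": "ANCHOR"})])
    gene_set = list(rng.choice(universe, 60, replace=False))
    res = go_enrichment(gene_set, universe, gene2go)
    # mid-p style check of near-uniformity: discrete p-values are stochastically
    # larger than uniform, so only test the lower tail is not inflated
    assert (res["p"] < 0.05).mean() <= 0.10
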