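"""Directional scores, orientation, TSS selection, profiles, enrichments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecdyatlas.genome import Gene, GeneAnnotation, Transcript
from ecdyatlas.motifs import PWM
from ecdyatlas.positional import (classify_orientation, directional_score,
                                  build_profiles, motif_enrichment,
                                  neighbor_pairs, proximity_enrichment,
                                  select_ecdysone_tss)


# ---------------------------------------------------------------------------
# directional score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,lfc,expected", [
    (1e-15, 2.0, 10.0),
    (0.01, -0.5, -2.0),
    (1.0, 3.0, 0.0),
    (0.0, 1.0, 10.0),      # p exactly zero maps to the clamp
    (1e-3, 0.0, 0.0),      # zero fold change scores zero
])
def test_directional_score_examples(p, lfc, expected):
    assert directional_score(p, lfc) == pytest.approx(expected)


@settings(max_examples=200, deadline=None)
@given(p=st.floats(1e-300, 1.0), lfc=st.floats(-50, 50,
                                               allow_nan=False))
def test_directional_score_clamped(p, lfc):
    s = directional_score(p, lfc)
    assert -10.0 <= s <= 10.0
    assert np.sign(s) in (0.0, np.sign(lfc))


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

@settings(max_examples=200, deadline=None)
@given(sa=st.sampled_from("+-"), sb=st.sampled_from("+-"),
       ta=st.integers(0, 10**6), tb=st.integers(0, 10**6))
def test_orientation_symmetry(sa, sb, ta, tb):
    ab = classify_orientation(sa, ta, sb, tb)
    ba = classify_orientation(sb, tb, sa, ta)
    if sa == sb:
        pair = {ab, ba}
        if ta != tb:
            assert pair == {"same-strand-upstream", "same-strand-downstream"}
    else:
        assert ab == ba
        assert ab in ("divergent", "convergent")


def test_convergent_when_transcribing_toward_each_other():
    assert classify_orientation("+", 100, "-", 5000) == "convergent"


# ---------------------------------------------------------------------------
# TSS selection
# ---------------------------------------------------------------------------

def _two_tss_gene():
    t1 = Transcript("t1", [(1000, 1200), (2000, 3000)], "+")
    t2 = Transcript("t2", [(1500, 1650), (2000, 3000)], "+")
    return Gene("g", "chr1", "+", [t1, t2])


def test_single_tss_gene_returns_it_unconditionally():
    g = Gene("g", "chr1", "+", [Transcript("t", [(100, 400)], "+")])
    assert select_ecdysone_tss(g, {100}, {}, {}, "induced") == 100


def test_significant_exon_tss_takes_priority():
    g = _two_tss_gene()
    # TSS 1500's first exon is flagged even though TSS 1000 is more expressed
    got = select_ecdysone_tss(g, {1500}, {1000: 9.0, 1500: 1.0},
                              {1000: 9.0, 1500: 1.0}, "induced")
    assert got == 1500


def test_highest_expression_at_relevant_time_point_breaks_ties():
    g = _two_tss_gene()
    e0 = {1000: 8.0, 1500: 3.0}
    e5 = {1000: 3.0, 1500: 8.0}
    assert select_ecdysone_tss(g, set(), e0, e5, "induced") == 1500
    assert select_ecdysone_tss(g, set(), e0, e5, "repressed") == 1000


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _records(n, orientation="divergent", responsive=False, score=0.0,
             dmax=19000):
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "focal_gene": [f"f{i}" for i in range(n)],
        "neighbor_gene": [f"n{i}" for i in range(n)],
        "cell_line": "L1",
        "focal_call": 1,
        "distance": rng.integers(100, dmax, n),
        "orientation": orientation,
        "neighbor_call": int(responsive),
        "neighbor_responsive": responsive,
        "neighbor_score": score,
        "focal_direction": "induced",
    })


def test_all_nonresponsive_neighbors_give_zero_fraction_curve():
    prof = build_profiles(_records(350))
    assert np.allclose(prof["fraction_responsive"], 0.0)
    assert np.allclose(prof["smoothed_fraction_responsive"], 0.0, atol=1e-9)


def test_constant_scores_pass_through_loess():
    prof = build_profiles(_records(500, score=3.5))
    assert np.allclose(prof["smoothed_mean_score"], 3.5, atol=1e-9)


def test_bins_aggregate_exactly_100_records():
    prof = build_profiles(_records(250))
    assert list(prof["n_records"]) == [100, 100, 50]


def test_small_group_yields_single_bin():
    prof = build_profiles(_records(40))
    assert len(prof) == 1 and prof.loc[0, "n_records"] == 40


def test_neighbor_pair_distances_match_annotation(small_dataset):
    ann = small_dataset.annotation
    tss = pd.Series({g.gene_id: g.primary_tss for g in ann})
    pairs = neighbor_pairs(ann, tss)
    assert (pairs["distance"] <= 20000).all()
    sample = pairs.sample(min(200, len(pairs)), random_state=0)
    for _, row in sample.iterrows():
        d = abs(tss[row["focal_gene"]] - tss[row["neighbor_gene"]])
        assert d == row["distance"]


# ---------------------------------------------------------------------------
# proximity enrichment
# ---------------------------------------------------------------------------

def _layout(weak_near=True):
    """30 induced TSSs; weak genes adjacent (or far); background spread out."""
    tss, chrom = {}, {}
    induced, weak, others = [], [], []
    for i in range(30):
        g = f"ind{i}"
        induced.append(g)
        tss[g] = 100_000 * (i + 1)
        chrom[g] = "chr1"
    for i in range(20):
        g = f"weak{i}"
        weak.append(g)
        base = 100_000 * ((i % 30) + 1)
        tss[g] = base + (1200 if weak_near else 30_000)
        chrom[g] = "chr1"
    for i in range(200):
        g = f"bg{i}"
        others.append(g)
        # a small baseline fraction of background genes sits near induced
        # TSSs so the expected rate is positive
        if i < 10:
            tss[g] = 100_000 * (i + 1) + 2000
        else:
            tss[g] = 4_000_000 + 50_000 * i
        chrom[g] = "chr1"
    return pd.Series(tss), chrom, weak, induced


def test_planted_adjacency_is_enriched():
    tss, chrom, weak, induced = _layout(weak_near=True)
    res = proximity_enrichment(weak, induced, tss, chrom, radius=2500)
    assert res["enrichment"] > 0
    assert res["p"] < 0.01


def test_distant_weak_genes_are_not_enriched():
    tss, chrom, weak, induced = _layout(weak_near=False)
    res = proximity_enrichment(weak, induced, tss, chrom, radius=2500)
    assert res["observed"] == 0.0


def test_radius_zero_gives_no_hits_and_minus_one_enrichment():
    tss, chrom, weak, induced = _layout(weak_near=True)
    res = proximity_enrichment(weak, induced, tss, chrom, radius=0)
    assert res["observed"] == 0.0
    # expected is zero too (no distinct genes share a TSS), so undefined
    if res["enrichment"] is not None:
        assert res["enrichment"] == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# motif enrichment
# ---------------------------------------------------------------------------

def test_planted_receptor_sites_enriched(small_dataset, small_analysis):
    from ecdyatlas.prediction import calibrate_motif_threshold
    truth = small_dataset.truth.genes
    pwms = {p.name: p for p in small_dataset.pwms}
    fg = list(truth.index[(truth["gene_class"] == "widespread")
                          & (truth["direction"] > 0)])
    nulls = list(truth.index[truth["gene_class"] == "null"])
    thr = calibrate_motif_threshold(
        pwms["EcR"], [small_dataset.promoters[g] for g in nulls])
    res = motif_enrichment(small_dataset.promoters, fg, nulls + fg,
                           pwms["EcR"], thr.cutoff)
    assert res["enrichment"] > 0
    assert res["p"] < 0.01


def test_uniform_foreground_is_unenriched(small_dataset):
    truth = small_dataset.truth.genes
    nulls = list(truth.index[truth["gene_class"] == "null"])
    pwm = PWM.from_consensus("x", "ACGTACGA")
    res = motif_enrichment(small_dataset.promoters, nulls[:60], nulls,
                           pwm, threshold=pwm.max_score - 4)
    if res["enrichment"] is not None:
        assert abs(res["enrichment"]) < 1.5
        assert res["p"] > 0.01
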