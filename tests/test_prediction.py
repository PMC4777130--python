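"""Motif thresholds, matched sets, masked features, LOCO, learning curve."""

import numpy as np
import pandas as pd
import pytest

from ecdyatlas.motifs import PWM
from ecdyatlas.prediction import (MatchedSet, PredictionError,
                                  build_features, build_matched_sets,
                                  calibrate_motif_threshold, fit_asymptote,
                                  loco_evaluate)


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def test_threshold_order_statistic_on_distinct_scores(monkeypatch):
    pwm = PWM.from_consensus("m", "ACGTACGT")
    fake = np.linspace(0.0, 10.0, 1000)  # 1000 distinct best scores
    monkeypatch.setattr(PWM, "best_scores", lambda self, seqs: fake)
    thr = calibrate_motif_threshold(pwm, ["x"] * 1000)
    assert thr.realized_hit_rate == pytest.approx(0.049)
    # the cutoff is the 49th-highest best score
    assert thr.cutoff == pytest.approx(np.sort(fake)[-49])


def test_degenerate_pwm_with_tied_scores_errors(monkeypatch):
    pwm = PWM.from_consensus("m", "ACGTACGT")
    monkeypatch.setattr(PWM, "best_scores",
                        lambda self, seqs: np.zeros(500))
    with pytest.raises(PredictionError, match="degenerate"):
        calibrate_motif_threshold(pwm, ["x"] * 500)


def test_calibration_needs_enough_promoters():
    pwm = PWM.from_consensus("m", "ACGTACGT")
    with pytest.raises(PredictionError, match="100"):
        calibrate_motif_threshold(pwm, ["ACGT" * 100] * 50)


def test_planting_a_site_can_only_raise_the_best_score():
    pwm = PWM.from_consensus("m", "AACCGGTT")
    rng = np.random.default_rng(0)
    for _ in range(10):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        pos = int(rng.integers(0, 300 - pwm.width))
        planted = seq[:pos] + pwm.consensus + seq[pos + pwm.width:]
        assert pwm.best_score(planted) >= pwm.best_score(seq)


# ---------------------------------------------------------------------------
# matched sets
# ---------------------------------------------------------------------------

def test_negatives_are_bottom_k_fold_changes(small_analysis):
    cat = small_analysis["catalog"]
    tables = small_analysis["de_tables"]
    sets = build_matched_sets(cat, tables, "induction")
    assert sets
    lfc = pd.DataFrame({l: tables[l]["log2FC"] for l in cat.calls.columns})
    for ms in sets[:20]:
        assert len(ms.positive_lines) == len(ms.negative_lines)
        assert not set(ms.positive_lines) & set(ms.negative_lines)
        candidates = [l for l in cat.calls.columns
                      if cat.calls.loc[ms.gene_id, l] != 1]
        vals = lfc.loc[ms.gene_id, candidates].sort_values()
        expect = set(vals.index[:len(ms.positive_lines)])
        assert set(ms.negative_lines) == expect


def test_gene_called_everywhere_is_not_restricted(small_analysis):
    cat = small_analysis["catalog"]
    sets = build_matched_sets(cat, small_analysis["de_tables"], "induction")
    wide = set(cat.genes_in_class("widespread", "induced"))
    assert not wide & {s.gene_id for s in sets}


def test_label_prior_is_exactly_half(small_analysis, small_dataset):
    from ecdyatlas.pipeline import Workspace
    sets = build_matched_sets(small_analysis["catalog"],
                              small_analysis["de_tables"], "induction")
    rows = sum(len(s.positive_lines) + len(s.negative_lines) for s in sets)
    pos = sum(len(s.positive_lines) for s in sets)
    assert pos * 2 == rows


# ---------------------------------------------------------------------------
# masked features
# ---------------------------------------------------------------------------

def _toy_feature_setup():
    lines = [f"L{i}" for i in range(6)]
    genes = ["gA", "gB"]
    pwms = {"TF1": PWM.from_consensus("TF1", "AAAACCCC"),
            "TF2": PWM.from_consensus("TF2", "GGGGAAAA")}
    promoters = {
        "gA": "T" * 100 + "AAAACCCC" + "T" * 100,  # TF1 site only
        "gB": "T" * 208,                            # no sites
    }
    thresholds = {
        t: type("Thr", (), {"cutoff": pwms[t].max_score - 1e-6,
                            "pwm_id": t, "realized_hit_rate": 0.0})()
        for t in pwms}
    rng = np.random.default_rng(0)
    tf_expr = pd.DataFrame(rng.uniform(10, 1000, (2, 6)),
                           index=["TF1", "TF2"], columns=lines)
    basal = pd.DataFrame(rng.uniform(1, 1000, (30, 6)),
                         index=[f"g{i}" for i in range(28)] + genes,
                         columns=lines)
    sets = [MatchedSet("gA", "induction", lines[:2], lines[2:4]),
            MatchedSet("gB", "induction", lines[:2], lines[2:4])]
    return sets, tf_expr, thresholds, promoters, pwms, basal


def test_features_masked_by_promoter_hits():
    sets, tf_expr, thr, promoters, pwms, basal = _toy_feature_setup()
    fm = build_features(sets, tf_expr, thr, promoters, pwms, basal,
                        tfs=["TF1", "TF2"])
    a = fm[fm["gene_id"] == "gA"]
    b = fm[fm["gene_id"] == "gB"]
    assert (a["tf:TF1"] > 0).all()       # hit present -> expression passes
    assert (a["tf:TF2"] == 0).all()      # no hit -> masked
    assert (b["tf:TF1"] == 0).all() and (b["tf:TF2"] == 0).all()
    assert fm["gene_rank"].between(0, 1).all()


def test_masking_soundness_zero_expression_equals_removed_motif():
    sets, tf_expr, thr, promoters, pwms, basal = _toy_feature_setup()
    zeroed = tf_expr.copy()
    zeroed.loc["TF1"] = 0.0
    fm_zero = build_features(sets, zeroed, thr, promoters, pwms, basal,
                             tfs=["TF1", "TF2"])
    no_motif = dict(promoters)
    no_motif["gA"] = "T" * 208  # remove TF1's site everywhere
    fm_removed = build_features(sets, tf_expr, thr, no_motif, pwms, basal,
                                tfs=["TF1", "TF2"])
    pd.testing.assert_frame_equal(fm_zero, fm_removed)


def test_lowest_expressed_gene_has_rank_zero():
    sets, tf_expr, thr, promoters, pwms, basal = _toy_feature_setup()
    basal.loc["gA"] = basal.min(axis=0) / 2  # gA lowest in every line
    fm = build_features(sets, tf_expr, thr, promoters, pwms, basal,
                        tfs=["TF1", "TF2"])
    assert (fm.loc[fm["gene_id"] == "gA", "gene_rank"] == 0).all()


# ---------------------------------------------------------------------------
# LOCO evaluation
# ---------------------------------------------------------------------------

def _separable_matrix(n_lines=6, rows_per_line=30, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lines):
        for j in range(rows_per_line):
            label = int(rng.random() < 0.5)
            rows.append({"gene_id": f"g{j}", "cell_line": f"L{i}",
                         "label": label, "direction": "induction",
                         "tf:TF1": label * 5.0 + rng.normal(0, 0.1),
                         "gene_rank": rng.random()})
    return pd.DataFrame(rows)


def test_single_separating_feature_gives_high_accuracy():
    fm = _separable_matrix()
    res = loco_evaluate(fm, n_trees=100, seed=0)
    assert res["accuracy"] >= 0.95
    assert res["importances"].index[0] == "tf:TF1"


def test_permuted_labels_give_chance_accuracy():
    rng = np.random.default_rng(1)
    fm = _separable_matrix(seed=1)
    accs = []
    for rep in range(5):
        shuffled = fm.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        shuffled["tf:TF1"] = rng.normal(0, 1, len(shuffled))
        accs.append(loco_evaluate(shuffled, n_trees=50, seed=rep)["accuracy"])
    assert abs(np.mean(accs) - 0.5) < 0.07


def test_loco_requires_three_lines():
    fm = _separable_matrix(n_lines=2)
    with pytest.raises(PredictionError):
        loco_evaluate(fm)


# ---------------------------------------------------------------------------
# asymptote fit
# ---------------------------------------------------------------------------

def test_asymptote_exact_recovery():
    n = np.array([4, 8, 12, 20, 40])
    acc = 0.75 - 0.5 / n
    a, b = fit_asymptote(n, acc)
    assert a == pytest.approx(0.75, abs=1e-6)
    assert b == pytest.approx(0.5, abs=1e-6)


def test_constant_series_gives_zero_slope():
    n = np.array([4, 8, 12, 20])
    a, b = fit_asymptote(n, np.full(4, 0.66))
    assert a == pytest.approx(0.66, abs=1e-9)
    assert b == pytest.approx(0.0, abs=1e-9)
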