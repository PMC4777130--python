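"""Size factors, borrowed dispersions, and the per-line Wald test."""

import numpy as np
import pandas as pd
import pytest

from ecdyatlas.config import SimulationConfig
from ecdyatlas.countio import CountMatrix
from ecdyatlas.diffexpr import (DiffExprError, estimate_size_factors,
                                fit_dispersions, run_de_all_lines)
from ecdyatlas.diffexpr import test_exon_de as exon_usage_test
from ecdyatlas.diffexpr import test_gene_de as wald_gene_test
from ecdyatlas.simulate import simulate_dataset


def _sheet(samples):
    return pd.DataFrame(samples, columns=["sample_id", "cell_line",
                                          "time_hr", "replicate"])


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_median_of_ratios_worked_example():
    """Two proportional samples -> factors (1/sqrt(2), sqrt(2))."""
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                          index=["g1", "g2", "g3"])
    sf = estimate_size_factors(counts)
    assert sf["s1"] == pytest.approx(0.7071, abs=1e-4)
    assert sf["s2"] == pytest.approx(1.4142, abs=1e-4)


def test_sample_equal_to_reference_gets_factor_one():
    counts = pd.DataFrame({"s1": [10, 40, 90], "s2": [10, 40, 90],
                           "s3": [10, 40, 90]}, index=["g1", "g2", "g3"])
    sf = estimate_size_factors(counts)
    assert np.allclose(sf, 1.0)


def test_size_factors_invariant_to_gene_order():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(1, 500, (50, 4)),
                          index=[f"g{i}" for i in range(50)],
                          columns=list("abcd"))
    sf = estimate_size_factors(counts)
    shuffled = counts.sample(frac=1.0, random_state=2)
    pd.testing.assert_series_equal(sf, estimate_size_factors(shuffled))


def test_doubling_a_library_doubles_its_factor(small_dataset):
    counts = small_dataset.counts.select(times=(0, 5)).counts
    sf = estimate_size_factors(counts)
    boosted = counts.copy()
    col = counts.columns[0]
    boosted[col] = boosted[col] * 2
    sf2 = estimate_size_factors(boosted)
    # the geometric-mean reference shifts by 2**(1/n_samples), so the clean
    # statement is relative: the boosted sample doubles against every other
    other = counts.columns[5]
    ratio = (sf2[col] / sf2[other]) / (sf[col] / sf[other])
    assert ratio == pytest.approx(2.0, rel=1e-9)


# ---------------------------------------------------------------------------
# dispersions
# ---------------------------------------------------------------------------

def test_identical_replicates_give_zero_raw_and_trend_final():
    sheet = _sheet([("a1", "A", 0, 1), ("a2", "A", 0, 2),
                    ("a5", "A", 5, 1), ("a6", "A", 5, 2)])
    rng = np.random.default_rng(3)
    base = rng.integers(50, 500, 40)
    counts = pd.DataFrame(
        {"a1": base, "a2": base, "a5": base, "a6": base},
        index=[f"g{i}" for i in range(40)])
    cm = CountMatrix(counts, sheet)
    disp = fit_dispersions(cm)
    assert (disp.raw.fillna(0) == 0).all()
    pd.testing.assert_series_equal(
        disp.final("trend"), disp.fitted, check_names=False)


def test_no_replicates_raises_instructive_error(small_dataset):
    cm = small_dataset.counts.select(times=(0, 5))
    keep = cm.samples["replicate"] == 1
    solo = CountMatrix(cm.counts[cm.samples.index[keep]],
                       cm.samples.loc[keep])
    with pytest.raises(DiffExprError, match="replicate"):
        fit_dispersions(solo)


def test_dispersion_trend_recovery_within_20_percent():
    """Known alpha(mu) = 0.05 + 2/mu recovered from replicated lines."""
    cfg = SimulationConfig(
        n_lines=20, n_genes=5000, n_tfs=2, n_widespread=0, n_restricted=0,
        n_weak=0, operon_pair_count=0, divergent_pair_count=0,
        tss_switch_count=0, isoform_coupled_count=0, bidirectional_count=0,
        timecourse_lines=None, frac_replicated_lines=0.2,
        dispersion_trend=(0.05, 2.0), baseline_mean_range=(20.0, 2000.0),
        seed=17)
    ds = simulate_dataset(cfg)
    cm = ds.counts.select(times=(0, 5))
    disp = fit_dispersions(cm)
    a0, a1 = disp.trend
    assert a0 == pytest.approx(0.05, rel=0.2)
    assert a1 == pytest.approx(2.0, rel=0.2)


def test_poisson_replicates_recover_near_zero_dispersion():
    cfg = SimulationConfig(
        n_lines=10, n_genes=2000, n_tfs=2, n_widespread=0, n_restricted=0,
        n_weak=0, operon_pair_count=0, divergent_pair_count=0,
        tss_switch_count=0, isoform_coupled_count=0, bidirectional_count=0,
        timecourse_lines=None, frac_replicated_lines=0.4,
        dispersion_trend=(0.0, 0.0), seed=19)
    ds = simulate_dataset(cfg)
    disp = fit_dispersions(ds.counts.select(times=(0, 5)))
    assert disp.final("trend").median() <= 0.01


def test_maximum_sharing_bounds_trend_from_below(small_analysis):
    disp = small_analysis["dispersions"]
    assert (disp.maximum >= disp.fitted - 1e-12).all()


# ---------------------------------------------------------------------------
# gene-level Wald test
# ---------------------------------------------------------------------------

def test_equal_means_give_zero_lfc_and_p_one():
    sheet = _sheet([("a0", "A", 0, 1), ("a5", "A", 5, 1),
                    ("b0", "B", 0, 1), ("b5", "B", 5, 2)])
    counts = pd.DataFrame({"a0": [100, 7], "a5": [100, 7],
                           "b0": [100, 7], "b5": [100, 7]},
                          index=["g1", "g2"])
    cm = CountMatrix(counts, sheet)
    sf = pd.Series(1.0, index=counts.columns)
    from ecdyatlas.diffexpr import DispersionModel
    dm = DispersionModel(raw=pd.Series(np.nan, index=counts.index),
                         trend=(0.01, 1.0),
                         base_mean=counts.mean(axis=1))
    res = wald_gene_test(cm, sf, dm, "A")
    assert np.allclose(res["log2FC"], 0.0)
    assert np.allclose(res["p_raw"], 1.0)


def test_scaling_a_sample_leaves_p_values_invariant(small_dataset):
    cm = small_dataset.counts.select(times=(0, 5))
    sf = estimate_size_factors(cm.counts)
    disp = fit_dispersions(cm, sf)
    line = cm.lines[2]
    base = wald_gene_test(cm, sf, disp, line)

    scaled_counts = cm.counts.copy()
    col = cm.sample_ids(line, 5)[0]
    scaled_counts[col] = scaled_counts[col] * 3
    cm2 = CountMatrix(scaled_counts, cm.samples)
    sf2 = sf.copy()
    sf2[col] = sf2[col] * 3
    res = wald_gene_test(cm2, sf2, disp, line)
    # normalized means and fold changes are exactly invariant; p-values keep
    # a per-read (shot-noise) variance term, so they are invariant only up
    # to its share of the total variance
    np.testing.assert_allclose(res["log2FC"], base["log2FC"], atol=1e-9)
    np.testing.assert_allclose(res["p_raw"], base["p_raw"], atol=0.05)


def test_swapping_time_labels_negates_lfc_and_preserves_p(small_dataset):
    cm = small_dataset.counts.select(times=(0, 5))
    sf = estimate_size_factors(cm.counts)
    disp = fit_dispersions(cm, sf)
    line = cm.lines[0]
    fwd = wald_gene_test(cm, sf, disp, line)
    swapped = cm.samples.copy()
    mask = swapped["cell_line"] == line
    swapped.loc[mask, "time_hr"] = 5 - swapped.loc[mask, "time_hr"]
    cm2 = CountMatrix(cm.counts, swapped.reset_index(drop=True))
    rev = wald_gene_test(cm2, sf, disp, line)
    np.testing.assert_allclose(rev["log2FC"], -fwd["log2FC"], atol=1e-9)
    np.testing.assert_allclose(rev["p_raw"], fwd["p_raw"], atol=1e-9)


def test_bh_adjustment_is_monotone_and_bounded(small_analysis):
    for tab in small_analysis["de_tables"].values():
        srt = tab.sort_values("p_raw")
        assert (srt["p_adj"] >= srt["p_raw"] - 1e-12).all()
        assert (srt["p_adj"] <= 1.0).all()
        # monotone in p_raw
        assert (np.diff(srt["p_adj"].to_numpy()) >= -1e-12).all()


def test_planted_strong_effect_recovered():
    """A +3 log2FC planted in every line is estimated within +-0.3 and
    significant in >=95% of (gene, line) instances."""
    cfg = SimulationConfig(
        n_lines=10, n_genes=800, n_tfs=2, n_widespread=60, n_restricted=0,
        n_weak=0, operon_pair_count=0, divergent_pair_count=0,
        tss_switch_count=0, isoform_coupled_count=0, bidirectional_count=0,
        timecourse_lines=None, effect_log2fc=3.0, seed=23)
    ds = simulate_dataset(cfg)
    cm = ds.counts.select(times=(0, 5))
    sf = estimate_size_factors(cm.counts)
    disp = fit_dispersions(cm, sf)
    tables = run_de_all_lines(cm, sf, disp)
    truth = ds.truth
    induced = truth.genes.index[(truth.genes["gene_class"] == "widespread")
                                & (truth.genes["direction"] > 0)]
    ok = []
    for line, tab in tables.items():
        sub = tab.loc[induced]
        ok.extend(((sub["p_adj"] < 0.01)
                   & (sub["log2FC"].sub(3.0).abs() < 0.3)).tolist())
    assert np.mean(ok) >= 0.95


# ---------------------------------------------------------------------------
# exon-level usage
# ---------------------------------------------------------------------------

def test_exon_matching_gene_fold_change_is_null(small_dataset, small_analysis):
    ecm = small_dataset.exon_counts.select(times=(0, 5))
    res = exon_usage_test(ecm, small_analysis["cm"], small_analysis["sf"],
                       small_analysis["dispersions"],
                       small_dataset.annotation.exon_table())
    # exons of flat (null) single-TSS genes shadow their gene exactly
    truth = small_dataset.truth.genes
    null_genes = set(truth.index[(truth["gene_class"] == "null")
                                 & ~truth["tss_switch"]])
    sub = res[res["gene_id"].isin(null_genes)]
    assert not sub["significant"].any()


def test_planted_promoter_switch_flagged(small_dataset, small_analysis):
    ecm = small_dataset.exon_counts.select(times=(0, 5))
    res = exon_usage_test(ecm, small_analysis["cm"], small_analysis["sf"],
                       small_analysis["dispersions"],
                       small_dataset.annotation.exon_table())
    switch_genes = set(small_dataset.truth.genes.index[
        small_dataset.truth.genes["tss_switch"]])
    assert switch_genes
    flagged = set(res.loc[res["promoter_switch_gene"], "gene_id"])
    assert switch_genes <= flagged
    # single-TSS genes can never be flagged
    single = {g.gene_id for g in small_dataset.annotation
              if len(g.tsss) == 1}
    assert not (flagged & single)


def test_unmapped_exon_raises(small_dataset, small_analysis):
    ecm = small_dataset.exon_counts.select(times=(0, 5))
    table = small_dataset.annotation.exon_table().iloc[:-1]
    with pytest.raises(DiffExprError, match="not mapped"):
        exon_usage_test(ecm, small_analysis["cm"], small_analysis["sf"],
                     small_analysis["dispersions"], table)
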