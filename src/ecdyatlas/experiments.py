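"""Planted-truth verification experiments.

Each function simulates a dataset whose ground truth isolates one claim the
pipeline makes -- null calibration, widespread/weak recovery, the receptor's
rate-limiting role, positional coupling, motif-masked predictability, or
time-course shapes -- runs the relevant stages, and returns the measured
quantities.  They are the backbone of the acceptance test suite and of
``scripts/acceptance.py``.

Problem sizes are chosen so each experiment runs in seconds to a few
minutes on one CPU while leaving the measured quantities well away from
their decision boundaries; the residualization experiment uses many more
lines than the emulated study because a genome-wide maximum-|r| check needs
the null maximum correlation (~3.3/sqrt(n_lines)) well below the reporting
threshold.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import rgc_correlation_scan, residualize_and_rescan
from .catalog import (call_responsive, fisher_combine, summarize_catalog,
                      ResponseCatalog)
from .config import SimulationConfig, derive_seed
from .diffexpr import estimate_size_factors, fit_dispersions, run_de_all_lines
from .positional import (build_neighbor_records, build_profiles,
                         select_tss_map)
from .prediction import (build_features, build_matched_sets,
                         calibrate_motif_threshold, loco_evaluate,
                         subsample_learning_curve)
from .simulate import SimulatedDataset, simulate_dataset
from .timecourse import normalize_timecourse

__all__ = ["analyze", "type_i_calibration", "widespread_recovery",
           "weak_sensitivity", "ecr_rate_limiting", "positional_contrast",
           "prediction_experiment", "timecourse_recovery"]


def analyze(ds: SimulatedDataset):
    """DE + Fisher + calls + catalog for a simulated dataset."""
    cm = ds.counts.select(times=(0, 5))
    sf = estimate_size_factors(cm.counts)
    disp = fit_dispersions(cm, sf)
    tables = run_de_all_lines(cm, sf, disp)
    fi = fisher_combine(tables, "induction")
    fr = fisher_combine(tables, "repression")
    catalog = summarize_catalog(call_responsive(tables, fi, fr), fi, fr)
    return tables, catalog


# ---------------------------------------------------------------------------
# 1. null calibration
# ---------------------------------------------------------------------------

def type_i_calibration(seed: int = 0, n_genes: int = 5000,
                       n_lines: int = 10) -> dict:
    """Zero-effect simulation: per-line raw-p rate and Fisher uniformity."""
    cfg = SimulationConfig(
        n_lines=n_lines, n_genes=n_genes, n_widespread=0, n_restricted=0,
        n_weak=0, operon_pair_count=0, divergent_pair_count=0,
        tss_switch_count=0, isoform_coupled_count=0, bidirectional_count=0,
        timecourse_lines=None, seed=derive_seed(seed, "type1"))
    ds = simulate_dataset(cfg)
    cm = ds.counts.select(times=(0, 5))
    sf = estimate_size_factors(cm.counts)
    disp = fit_dispersions(cm, sf)
    tables = run_de_all_lines(cm, sf, disp)
    fractions = {line: float((t["p_raw"] < 0.05).mean())
                 for line, t in tables.items()}
    fi = fisher_combine(tables, "induction")
    fr = fisher_combine(tables, "repression")
    return {
        "per_line_fraction_p05": fractions,
        "fraction_band_halfwidth": 3 * float(np.sqrt(0.05 * 0.95 / n_genes)),
        "ks_p_induction": float(stats.kstest(fi["p_fisher"], "uniform").pvalue),
        "ks_p_repression": float(stats.kstest(fr["p_fisher"], "uniform").pvalue),
        "n_genes": n_genes, "n_lines": n_lines,
    }


# ---------------------------------------------------------------------------
# 2. widespread recovery / null specificity
# ---------------------------------------------------------------------------

def widespread_recovery(seed: int = 0) -> dict:
    """50 widespread + 500 restricted + 4450 null genes across 20 lines."""
    cfg = SimulationConfig(
        n_lines=20, n_genes=5000, n_widespread=50, n_restricted=500,
        n_weak=0, operon_pair_count=5, divergent_pair_count=5,
        tss_switch_count=0, isoform_coupled_count=0, bidirectional_count=0,
        effect_log2fc=2.0, timecourse_lines=None,
        seed=derive_seed(seed, "widespread"))
    ds = simulate_dataset(cfg)
    _, catalog = analyze(ds)
    truth = ds.truth.genes
    wide = truth.index[truth["gene_class"] == "widespread"]
    hits = []
    for g in wide:
        d = "induced" if truth.loc[g, "direction"] > 0 else "repressed"
        hits.append(catalog.gene_summary.loc[g, f"breadth_{d}"] == "widespread")
    null = truth.index[truth["gene_class"] == "null"]
    null_called = (catalog.calls.loc[null] != 0).any(axis=1)
    return {
        "widespread_recovery": float(np.mean(hits)),
        "null_called_rate": float(null_called.mean()),
        "n_widespread": int(len(wide)), "n_null": int(len(null)),
    }


# ---------------------------------------------------------------------------
# 3. weak-responder power
# ---------------------------------------------------------------------------

def weak_sensitivity(seed: int = 0, n_sims: int = 20,
                     weak_per_sim: int = 5) -> dict:
    """1.5-fold responders in 80% of 20 lines, replicated across simulations."""
    detected = total = 0
    for rep in range(n_sims):
        cfg = SimulationConfig(
            n_lines=20, n_genes=1000, n_widespread=0, n_restricted=0,
            n_weak=weak_per_sim, operon_pair_count=0, divergent_pair_count=0,
            tss_switch_count=0, isoform_coupled_count=0,
            bidirectional_count=0, timecourse_lines=None,
            seed=derive_seed(seed, f"weak:{rep}"))
        ds = simulate_dataset(cfg)
        _, catalog = analyze(ds)
        truth = ds.truth.genes
        for g in truth.index[truth["gene_class"] == "weak"]:
            d = "induced" if truth.loc[g, "direction"] > 0 else "repressed"
            total += 1
            detected += bool(catalog.gene_summary.loc[g, f"weak_{d}"])
    return {"sensitivity": detected / total, "n_planted": total}


# ---------------------------------------------------------------------------
# 4. receptor titer is rate-limiting
# ---------------------------------------------------------------------------

def ecr_rate_limiting(seed: int = 0, n_reps: int = 100) -> dict:
    """Does the receptor top the RGC scan, and does residualization clear it?

    Each replicate simulates 350 genes x 200 lines with titer-gated
    restricted firing, runs the correlation scan on basal expression, and
    re-scans the residuals after regressing RGC on receptor expression.
    """
    rank1 = r_ok = resid_ok = 0
    r_values, resid_tops = [], []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_lines=200, n_genes=350, n_tfs=30, n_widespread=20,
            n_restricted=200, n_weak=0, operon_pair_count=3,
            divergent_pair_count=3, tss_switch_count=0,
            isoform_coupled_count=0, bidirectional_count=0,
            timecourse_lines=None, seed=derive_seed(seed, f"rgc:{rep}"))
        ds = simulate_dataset(cfg)
        tables, catalog = analyze(ds)
        basal = pd.DataFrame({l: tables[l]["mean_0h"] for l in tables})
        scan = rgc_correlation_scan(basal, catalog.line_summary["rgc"])
        resid = residualize_and_rescan(basal, catalog.line_summary["rgc"],
                                       "EcR")
        r = float(scan.loc["EcR", "r"])
        top = float(resid["r"].abs().max())
        r_values.append(r)
        resid_tops.append(top)
        rank1 += scan.index[0] == "EcR"
        r_ok += r >= 0.7
        resid_ok += top < 0.4
    return {
        "n_reps": n_reps,
        "rank1_fraction": rank1 / n_reps,
        "r_at_least_0.7_fraction": r_ok / n_reps,
        "residual_below_0.4_fraction": resid_ok / n_reps,
        "mean_r_ecr": float(np.mean(r_values)),
        "mean_residual_top_abs_r": float(np.mean(resid_tops)),
    }


# ---------------------------------------------------------------------------
# 5. positional coupling contrast
# ---------------------------------------------------------------------------

def positional_contrast(seed: int = 0) -> dict:
    """Tandem (operon-type) coupling on, divergent coupling off.

    Compares the smoothed mean directional score of same-strand neighbors
    of induced genes against divergent neighbors at TSS distances below
    2 kb, via a sign test on the smoothed curves evaluated at the divergent
    group's bin centers.
    """
    cfg = SimulationConfig(
        n_lines=20, n_genes=2000, n_widespread=120, n_restricted=200,
        n_weak=0, operon_pair_count=40, divergent_pair_count=40,
        tss_switch_count=0, isoform_coupled_count=0, bidirectional_count=0,
        timecourse_lines=None, seed=derive_seed(seed, "positional"))
    ds = simulate_dataset(cfg)
    tables, catalog = analyze(ds)
    tss = select_tss_map(ds.annotation, catalog)
    records = build_neighbor_records(ds.annotation, catalog, tables, tss)
    profiles = build_profiles(records)
    ind = profiles[profiles["focal_direction"] == "induced"]
    same = ind[ind["orientation"].str.startswith("same-strand")]
    div = ind[ind["orientation"] == "divergent"]
    grid = div.loc[div["bin_center"] < 2000, "bin_center"].to_numpy()

    def curve(df, xs):
        df = df.sort_values("bin_center")
        return np.interp(xs, df["bin_center"], df["smoothed_mean_score"])

    diff = curve(same, grid) - curve(div, grid)
    n_pos = int((diff > 0).sum())
    p = float(stats.binomtest(n_pos, len(grid), 0.5,
                              alternative="greater").pvalue)
    return {
        "n_grid_points": int(len(grid)),
        "n_same_strand_higher": n_pos,
        "sign_test_p": p,
        "mean_gap": float(diff.mean()),
        "background_fraction": float(profiles.attrs["background"]),
    }


# ---------------------------------------------------------------------------
# 6. motif-masked prediction
# ---------------------------------------------------------------------------

def _prediction_setup(ds: SimulatedDataset, tables, catalog):
    basal = pd.DataFrame({l: tables[l]["mean_0h"] for l in tables})
    pwms = {p.name: p for p in ds.pwms}
    tf_names = [t for t in pwms if t in basal.index]
    tf_expression = basal.loc[tf_names]
    truth = ds.truth.genes
    nonresponsive = [g for g in catalog.calls.index
                     if (catalog.calls.loc[g] == 0).all()]
    nr_prom = [ds.promoters[g] for g in nonresponsive]
    thresholds = {tf: calibrate_motif_threshold(pwms[tf], nr_prom)
                  for tf in tf_names}
    return basal, tf_expression, pwms, thresholds


def prediction_experiment(seed: int = 0, direction: str = "induction",
                          n_trees: int = 500, n_permutations: int = 10,
                          learning_curve: bool = True,
                          curve_reps: int = 10) -> dict:
    """5 responsible TFs among 20, 200 restricted genes, 20 lines."""
    cfg = SimulationConfig(
        n_lines=20, n_genes=2000, n_tfs=20, n_responsible_tfs=5,
        n_widespread=40, n_restricted=200, n_weak=0, operon_pair_count=5,
        divergent_pair_count=5, tss_switch_count=0, isoform_coupled_count=0,
        bidirectional_count=0, timecourse_lines=None,
        seed=derive_seed(seed, "predict"))
    ds = simulate_dataset(cfg)
    tables, catalog = analyze(ds)
    basal, tf_expression, pwms, thresholds = _prediction_setup(
        ds, tables, catalog)

    sets = build_matched_sets(catalog, tables, direction)
    fm = build_features(sets, tf_expression, thresholds, ds.promoters,
                        pwms, basal)
    res = loco_evaluate(fm, n_trees=n_trees, seed=derive_seed(seed, "loco"))

    responsible = [f"tf:{t}" for t in ds.states.tf_names[1:6]]
    top10 = list(res["importances"].head(10).index)
    n_top = sum(t in top10 for t in responsible)

    rng = np.random.default_rng(derive_seed(seed, "perm"))
    perm_accs = []
    for rep in range(n_permutations):
        fm2 = fm.copy()
        fm2["label"] = rng.permutation(fm2["label"].to_numpy())
        perm_accs.append(loco_evaluate(fm2, n_trees=100,
                                       seed=int(rng.integers(2**31)))
                         ["accuracy"])
    out = {
        "direction": direction,
        "loco_accuracy": res["accuracy"],
        "n_rows": int(len(fm)),
        "n_matched_genes": int(len(sets)),
        "permuted_accuracy": float(np.mean(perm_accs)),
        "responsible_tfs_in_top10": int(n_top),
        "importances_top10": top10,
    }
    if learning_curve:
        def builder(msets):
            return build_features(msets, tf_expression, thresholds,
                                  ds.promoters, pwms, basal)
        lc = subsample_learning_curve(
            catalog, tables, direction, builder,
            n_values=[5, 7, 9, 11, 14, 18], reps=curve_reps, n_trees=100,
            seed=derive_seed(seed, "curve"))
        means = lc["mean_accuracy"]
        rho = stats.spearmanr(means.index, means.values)
        out.update({
            "curve_mean_accuracy": {int(k): float(v)
                                    for k, v in means.items()},
            "curve_spearman_rho": float(rho.statistic),
            "curve_spearman_p": float(rho.pvalue),
            "asymptote": float(lc["asymptote"]),
            "asymptote_ci": [float(x) for x in lc["asymptote_ci"]],
            "max_observed_accuracy": float(means.max()),
        })
    return out


# ---------------------------------------------------------------------------
# 7/8. time-course shape recovery
# ---------------------------------------------------------------------------

def timecourse_recovery(seed: int = 0) -> dict:
    """Centering exactness and planted fast-peak recovery."""
    cfg = SimulationConfig(
        n_lines=6, n_genes=900, n_widespread=140, n_restricted=80, n_weak=0,
        operon_pair_count=5, divergent_pair_count=5, tss_switch_count=0,
        isoform_coupled_count=0, bidirectional_count=0,
        timecourse_lines=("CL01", "CL02"),
        seed=derive_seed(seed, "timecourse"))
    ds = simulate_dataset(cfg)
    prof = normalize_timecourse(ds.counts)
    tcols = ["t0", "t1", "t3", "t5", "t7"]
    max_center = float(np.abs(prof[tcols].mean(axis=1)).max())
    fast = ds.truth.shapes[ds.truth.shapes["shape"] == "fast"]
    merged = prof.merge(fast, on=["gene_id", "cell_line"])
    dirs = merged["gene_id"].map(ds.truth.genes["direction"]).to_numpy()
    oriented = merged[tcols].to_numpy() * dirs[:, None]
    recovery = float((oriented.argmax(axis=1) == 1).mean())
    return {
        "max_centering_error": max_center,
        "fast_peak_recovery": recovery,
        "n_fast_planted": int(len(merged)),
        "n_profiles": int(len(prof)),
    }
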