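"""Motif-masked prediction of restricted responses.

For each restricted gene, the cell lines carrying its significant call are
positives and an equal number of the most oppositely-responding lines (by
log2 fold change) are matched negatives, so chance accuracy is exactly 0.5.
Features are per-TF normalized expression masked to zero unless the gene's
promoter contains a hit for that TF's motif (threshold calibrated so just
under 5% of nonresponsive promoters score a hit), plus the gene's basal
expression rank within the line.  A bagged decision-tree ensemble (random
forest) is evaluated by leaving out whole cell lines, and learning curves
over subsampled line sets are extrapolated with a hyperbolic saturation
a - b/n to a theoretical maximal accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .catalog import ResponseCatalog
from .motifs import PWM

__all__ = ["MotifThreshold", "calibrate_motif_threshold", "MatchedSet",
           "build_matched_sets", "eligible_tfs", "build_features",
           "loco_evaluate", "subsample_learning_curve", "fit_asymptote",
           "PredictionError"]

TARGET_HIT_RATE = 0.05
DEFAULT_N_TREES = 500


class PredictionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# motif threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class MotifThreshold:
    pwm_id: str
    cutoff: float
    realized_hit_rate: float


def calibrate_motif_threshold(pwm: PWM,
                              nonresponsive_promoters: Sequence[str],
                              target_rate: float = TARGET_HIT_RATE
                              ) -> MotifThreshold:
    """Smallest best-window score cutoff with hit rate just below 5%.

    Candidate cutoffs are the distinct per-promoter best scores (both
    strands scanned); the chosen cutoff is the smallest candidate whose
    hit rate (fraction of promoters scoring >= cutoff) is below the target.
    """
    if len(nonresponsive_promoters) < 100:
        raise PredictionError(
            "threshold calibration needs >= 100 nonresponsive promoters")
    best = pwm.best_scores(nonresponsive_promoters)
    n = len(best)
    candidates = np.unique(best)  # ascending
    for cutoff in candidates:
        rate = float(np.mean(best >= cutoff))
        if rate < target_rate:
            return MotifThreshold(pwm.name, float(cutoff), rate)
    raise PredictionError(
        f"PWM {pwm.name}: no cutoff achieves a hit rate below "
        f"{target_rate} (degenerate score distribution)")


# ---------------------------------------------------------------------------
# matched sets
# ---------------------------------------------------------------------------

@dataclass
class MatchedSet:
    gene_id: str
    direction: str                      # "induction" | "repression"
    positive_lines: List[str]
    negative_lines: List[str]


def build_matched_sets(catalog: ResponseCatalog,
                       de_tables: Dict[str, pd.DataFrame],
                       direction: str,
                       lines: Optional[Sequence[str]] = None
                       ) -> List[MatchedSet]:
    """Positives = restricted calls; negatives = most-opposite fold changes.

    For induction, each restricted induced gene's negatives are the lines
    without the call showing the smallest log2FC (most repressive); for
    repression, the largest.  Genes with fewer candidate negatives than
    positives are skipped.
    """
    if direction not in ("induction", "repression"):
        raise PredictionError(f"unknown direction {direction!r}")
    sign = 1 if direction == "induction" else -1
    dname = "induced" if sign == 1 else "repressed"
    all_lines = list(catalog.calls.columns) if lines is None else list(lines)
    calls = catalog.calls[all_lines]

    # restricted status within the given line subset: called somewhere but
    # in no more than half of the subset
    n_called = (calls == sign).sum(axis=1)
    restricted = calls.index[(n_called > 0) & (n_called <= len(all_lines) / 2)]

    lfc = pd.DataFrame({l: de_tables[l]["log2FC"] for l in all_lines})
    sets: List[MatchedSet] = []
    for gid in restricted:
        pos = [l for l in all_lines if calls.loc[gid, l] == sign]
        candidates = [l for l in all_lines if calls.loc[gid, l] != sign]
        if len(candidates) < len(pos):
            continue
        vals = lfc.loc[gid, candidates]
        order = vals.sort_values(ascending=(sign == 1))
        neg = list(order.index[:len(pos)])
        sets.append(MatchedSet(gid, direction, pos, neg))
    return sets


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def eligible_tfs(tf_expression: pd.DataFrame,
                 basal_expression: pd.DataFrame,
                 thresholds: Dict[str, MotifThreshold]) -> List[str]:
    """TFs with a motif threshold and valid expression.

    A TF is eligible if at least one line expresses it above the 20th
    percentile of genes with at least one read in that line.
    """
    out = []
    for tf in tf_expression.index:
        if tf not in thresholds:
            continue
        ok = False
        for line in tf_expression.columns:
            col = basal_expression[line]
            detected = col[col > 0]
            if detected.empty:
                continue
            if tf_expression.loc[tf, line] > np.percentile(detected, 20):
                ok = True
                break
        if ok:
            out.append(tf)
    return out


def build_features(matched_sets: Sequence[MatchedSet],
                   tf_expression: pd.DataFrame,
                   thresholds: Dict[str, MotifThreshold],
                   promoters: Dict[str, str],
                   pwms: Dict[str, PWM],
                   basal_expression: pd.DataFrame,
                   tfs: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """(gene, line) rows with masked TF features, gene rank, and labels.

    The TF column of a row is the TF's log2 normalized expression in that
    line if the row's gene has a promoter hit for the TF's motif, else 0.
    The gene-rank feature is the gene's basal expression rank within the
    line scaled to [0, 1].
    """
    if tfs is None:
        tfs = eligible_tfs(tf_expression, basal_expression, thresholds)
    tfs = [t for t in tfs if t in thresholds]
    if not tfs:
        raise PredictionError("no eligible TFs with motif thresholds")

    genes = sorted({s.gene_id for s in matched_sets})
    hit = {g: {} for g in genes}
    for tf in tfs:
        pwm = pwms[tf]
        thr = thresholds[tf].cutoff
        for g in genes:
            hit[g][tf] = pwm.has_hit(promoters[g], thr)

    rank01 = basal_expression.rank(axis=0, method="average")
    rank01 = (rank01 - 1) / (len(basal_expression) - 1)

    tf_log = np.log2(tf_expression + 1.0)
    rows = []
    for ms in matched_sets:
        for label, lines in ((1, ms.positive_lines), (0, ms.negative_lines)):
            for line in lines:
                row = {"gene_id": ms.gene_id, "cell_line": line,
                       "label": label, "direction": ms.direction}
                for tf in tfs:
                    row[f"tf:{tf}"] = (float(tf_log.loc[tf, line])
                                       if hit[ms.gene_id][tf] else 0.0)
                row["gene_rank"] = float(rank01.loc[ms.gene_id, line])
                rows.append(row)
    if not rows:
        raise PredictionError("no matched-set rows")
    return pd.DataFrame(rows)


def _feature_columns(fm: pd.DataFrame) -> List[str]:
    return [c for c in fm.columns if c.startswith("tf:")] + ["gene_rank"]


# ---------------------------------------------------------------------------
# leave-one-cell-line-out evaluation
# ---------------------------------------------------------------------------

def loco_evaluate(feature_matrix: pd.DataFrame,
                  n_trees: int = DEFAULT_N_TREES,
                  seed: int = 0) -> dict:
    """Mean held-out accuracy over leave-one-line-out folds.

    Also fits the ensemble on all rows to report feature importances
    (mean impurity decrease).
    """
    lines = sorted(feature_matrix["cell_line"].unique())
    if len(lines) < 3:
        raise PredictionError("LOCO evaluation requires >= 3 cell lines")
    cols = _feature_columns(feature_matrix)
    x = feature_matrix[cols].to_numpy()
    y = feature_matrix["label"].to_numpy()
    line_of = feature_matrix["cell_line"].to_numpy()

    per_line = {}
    skipped = []
    for i, line in enumerate(lines):
        test = line_of == line
        if not test.any():
            skipped.append(line)
            continue
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed + i,
            n_jobs=1)
        clf.fit(x[~test], y[~test])
        per_line[line] = float((clf.predict(x[test]) == y[test]).mean())

    full = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1)
    full.fit(x, y)
    importances = pd.Series(full.feature_importances_, index=cols,
                            name="importance").sort_values(ascending=False)
    return {
        "accuracy": float(np.mean(list(per_line.values()))),
        "per_line": per_line,
        "skipped_lines": skipped,
        "importances": importances,
    }


# ---------------------------------------------------------------------------
# learning curve over subsampled line sets
# ---------------------------------------------------------------------------

def fit_asymptote(n_values: Sequence[float],
                  accuracies: Sequence[float]) -> Tuple[float, float]:
    """Least-squares fit of acc(n) = a - b/n; returns (a, b)."""
    n = np.asarray(n_values, dtype=float)
    acc = np.asarray(accuracies, dtype=float)
    design = np.column_stack([np.ones_like(n), -1.0 / n])
    coef, *_ = np.linalg.lstsq(design, acc, rcond=None)
    return float(coef[0]), float(coef[1])


def subsample_learning_curve(catalog: ResponseCatalog,
                             de_tables: Dict[str, pd.DataFrame],
                             direction: str,
                             feature_builder,
                             n_values: Sequence[int],
                             reps: int = 20,
                             n_trees: int = 100,
                             seed: int = 0,
                             n_boot: int = 200) -> dict:
    """Accuracy vs number of cell lines, with a fitted asymptote.

    For each n, `reps` random subsets of n lines are drawn; restricted sets,
    matched sets, and features are rebuilt from the subset alone (via
    `feature_builder(matched_sets)`), and LOCO accuracy within the subset is
    averaged.  The asymptote `a` of the fit a - b/n is reported with a
    bootstrap percentile interval over replicate means.
    """
    import warnings
    if reps < 10:
        warnings.warn("fewer than 10 subsample repetitions: the asymptote "
                      "interval is unreliable", stacklevel=2)
    all_lines = list(catalog.calls.columns)
    for n in n_values:
        if not (4 <= n <= len(all_lines) - 1):
            raise PredictionError(
                f"subset size {n} outside [4, n_lines - 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        for rep in range(reps):
            subset = list(rng.choice(all_lines, size=n, replace=False))
            sets = build_matched_sets(catalog, de_tables, direction,
                                      lines=subset)
            if not sets:
                continue
            fm = feature_builder(sets)
            if fm["cell_line"].nunique() < 3 or fm["label"].nunique() < 2:
                continue
            res = loco_evaluate(fm, n_trees=n_trees,
                                seed=int(rng.integers(2**31)))
            rows.append({"n_lines": n, "rep": rep,
                         "accuracy": res["accuracy"]})
    curve = pd.DataFrame(rows)
    if curve.empty:
        raise PredictionError("no usable subsets in the learning curve")
    means = curve.groupby("n_lines")["accuracy"].mean()
    a, b = fit_asymptote(means.index.to_numpy(), means.to_numpy())

    boots = []
    for _ in range(n_boot):
        sampled = (curve.groupby("n_lines")["accuracy"]
                   .apply(lambda s: s.sample(len(s), replace=True,
                                             random_state=int(
                                                 rng.integers(2**31))).mean()))
        ab, _bb = fit_asymptote(sampled.index.to_numpy(), sampled.to_numpy())
        boots.append(ab)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots
              else (np.nan, np.nan))
    return {"curve": curve, "mean_accuracy": means,
            "asymptote": a, "slope": b,
            "asymptote_ci": (float(lo), float(hi))}
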