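"""Extended time-course shape normalization.

Expression over the 0/1/3/5/7 hr course is converted into a comparable
"response shape" per (gene, line): counts are size-factor normalized
(median of ratios across all time-course samples), mean-centered across the
five time points, and divided by a fitted standard deviation -- a LOESS fit
of the per-combination SD on the per-combination mean over all gene-line
combinations -- so genes at very different steady-state levels become
comparable.  Units are standard deviations from the mean across time.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .countio import CountMatrix
from .diffexpr import estimate_size_factors

__all__ = ["normalize_timecourse", "summarize_shapes", "classify_shape",
           "TimecourseError", "TIMEPOINTS"]

TIMEPOINTS = (0, 1, 3, 5, 7)
SD_FLOOR = 1e-6
SD_LOESS_SPAN = 0.75


class TimecourseError(ValueError):
    pass


def normalize_timecourse(cm: CountMatrix,
                         lines: Optional[Sequence[str]] = None,
                         size_factors: Optional[pd.Series] = None
                         ) -> pd.DataFrame:
    """Shape profiles for every (gene, line) with a full 5-point course.

    Returns a frame with columns ``gene_id, cell_line, t0, t1, t3, t5, t7,
    mean_expr, fitted_sd`` where the five t-columns are in fitted-SD units
    and sum to zero.  Combinations whose fitted SD falls at or below the
    floor are excluded; their count is in ``.attrs['n_excluded']``.
    """
    if lines is None:
        have = cm.samples.groupby("cell_line")["time_hr"].agg(set)
        lines = [l for l, ts in have.items() if set(TIMEPOINTS) <= ts]
    if not lines:
        raise TimecourseError("no cell line has the full 5-point time course")
    ids: List[str] = []
    meta = []
    for line in lines:
        for t in TIMEPOINTS:
            sids = cm.sample_ids(line, t)
            if not sids:
                raise TimecourseError(
                    f"line {line} is missing the {t} hr time point")
            ids.extend(sids)
            meta.extend((line, t, s) for s in sids)
    counts = cm.counts[ids]
    sf = (estimate_size_factors(counts) if size_factors is None
          else size_factors.reindex(counts.columns))
    q = counts / sf

    # average replicates within (line, time)
    per_lt = {}
    for line in lines:
        cols = []
        for t in TIMEPOINTS:
            sids = cm.sample_ids(line, t)
            cols.append(q[sids].mean(axis=1))
        per_lt[line] = np.column_stack(cols)  # genes x 5

    rows_gene, rows_line, mats = [], [], []
    for line in lines:
        mats.append(per_lt[line])
        rows_gene.extend(counts.index)
        rows_line.extend([line] * len(counts.index))
    values = np.vstack(mats)  # (genes*lines) x 5
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=0)

    order = np.argsort(means, kind="mergesort")
    fitted_sorted = lowess(sds[order], means[order], frac=SD_LOESS_SPAN,
                           it=0, return_sorted=False)
    fitted = np.empty_like(fitted_sorted)
    fitted[order] = fitted_sorted

    centered = values - means[:, None]
    keep = fitted > SD_FLOOR
    profiles = centered[keep] / fitted[keep, None]
    out = pd.DataFrame(profiles, columns=[f"t{t}" for t in TIMEPOINTS])
    out.insert(0, "gene_id", np.asarray(rows_gene, dtype=object)[keep])
    out.insert(1, "cell_line", np.asarray(rows_line, dtype=object)[keep])
    out["mean_expr"] = means[keep]
    out["fitted_sd"] = fitted[keep]
    out.attrs["n_excluded"] = int((~keep).sum())
    return out.reset_index(drop=True)


def classify_shape(values: Sequence[float]) -> str:
    """early-peak: max at 1 hr, strictly decreasing after; late-rise: max at 7 hr."""
    v = np.asarray(values, dtype=float)
    if v[1] == v.max() and np.all(np.diff(v[1:]) < 0):
        return "early-peak"
    if v[-1] == v.max():
        return "late-rise"
    return "other"


def summarize_shapes(profiles: pd.DataFrame,
                     gene_sets: Dict[str, Iterable[str]]) -> dict:
    """Median trajectories and shape-class counts per gene set and line."""
    tcols = [f"t{t}" for t in TIMEPOINTS]
    profiles = profiles.copy()
    profiles["shape_class"] = [classify_shape(row)
                               for row in profiles[tcols].to_numpy()]
    medians = []
    classes = []
    for name, members in gene_sets.items():
        members = set(members)
        sub = profiles[profiles["gene_id"].isin(members)]
        if sub.empty:
            continue
        med = sub.groupby("cell_line")[tcols].median()
        med.insert(0, "gene_set", name)
        medians.append(med.reset_index())
        cls = (sub.groupby(["cell_line", "shape_class"]).size()
               .rename("count").reset_index())
        cls.insert(0, "gene_set", name)
        classes.append(cls)
    return {
        "profiles": profiles,
        "median_trajectories": (pd.concat(medians, ignore_index=True)
                                if medians else pd.DataFrame()),
        "class_counts": (pd.concat(classes, ignore_index=True)
                         if classes else pd.DataFrame()),
    }
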