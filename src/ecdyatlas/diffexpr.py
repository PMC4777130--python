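"""Simplified DESeq-style differential expression with borrowed dispersions.

Only a subset of cell lines carries biological duplicates, so gene-wise
dispersions are estimated from the replicated samples alone (method of
moments pooled over replicate groups), a parametric trend
``alpha(mu) = a0 + a1/mu`` is fitted across genes, and the trend is applied
to every line under the assumption that biological dispersion is consistent
across lines.  Per line, a Wald test on the difference of normalized 5 hr
and 0 hr means under the NB variance with fixed alpha gives the raw p-value;
BH adjustment is applied across genes within each line.

The pseudocounted log2 fold change (pseudocount 0.5 on the normalized scale)
is reported for effect size only; it does not enter the test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .countio import CountMatrix

__all__ = ["estimate_size_factors", "DispersionModel", "fit_dispersions",
           "test_gene_de", "run_de_all_lines", "test_exon_de",
           "normalized_counts", "DiffExprError"]

LOG2FC_PSEUDOCOUNT = 0.5
USAGE_FOLD_THRESHOLD = 50.0


class DiffExprError(ValueError):
    pass


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (robust median library normalization).

    The per-gene reference is the geometric mean across samples, computed
    over genes with no zero count; each sample's factor is the median ratio
    of its counts to the reference.  Factors are not renormalized afterward.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise DiffExprError(
            "all-zero reference: no gene has nonzero counts in every sample")
    log_ref = logs[finite].mean(axis=1)
    factors = np.exp(np.median(logs[finite] - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix,
                      sf: Optional[pd.Series] = None) -> pd.DataFrame:
    if sf is None:
        sf = estimate_size_factors(cm.counts)
    return cm.counts / sf.reindex(cm.counts.columns)


# ---------------------------------------------------------------------------
# dispersions
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    """Gene dispersions from replicated lines plus a fitted 1/mu trend.

    ``raw`` holds the pooled method-of-moments estimate where replicate
    groups allow one (NaN otherwise); ``trend`` is (a0, a1) of
    alpha(mu) = a0 + a1/mu; ``base_mean`` is the normalized mean used to
    evaluate the trend.  ``alpha(...)`` evaluates the trend at arbitrary
    means; per-gene final dispersions come in two flavours:

    - ``fitted``: the trend value (default used for testing; calibrated)
    - ``maximum``: max(raw, trend) where a raw estimate exists (conservative)
    """

    raw: pd.Series
    trend: Tuple[float, float]
    base_mean: pd.Series
    _FLOOR = 1e-8

    def alpha(self, mean) -> np.ndarray:
        a0, a1 = self.trend
        mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
        return np.maximum(a0 + a1 / mean, self._FLOOR)

    @property
    def fitted(self) -> pd.Series:
        return pd.Series(self.alpha(self.base_mean), index=self.raw.index,
                         name="alpha_fitted")

    @property
    def maximum(self) -> pd.Series:
        fit = self.fitted
        return pd.Series(np.fmax(self.raw, fit), index=self.raw.index,
                         name="alpha_max").fillna(fit)

    def final(self, sharing: str = "trend") -> pd.Series:
        if sharing == "trend":
            return self.fitted
        if sharing == "maximum":
            return self.maximum
        raise ValueError(f"unknown sharing mode {sharing!r}")


def replicate_groups(cm: CountMatrix) -> List[List[str]]:
    groups = []
    for (_, _), grp in cm.samples.groupby(["cell_line", "time_hr"]):
        if len(grp) >= 2:
            groups.append(list(grp.index))
    return groups


def fit_dispersions(cm: CountMatrix,
                    sf: Optional[pd.Series] = None) -> DispersionModel:
    """Estimate the dispersion trend from the replicated samples only."""
    if sf is None:
        sf = estimate_size_factors(cm.counts)
    groups = replicate_groups(cm)
    if not groups:
        raise DiffExprError(
            "no replicated samples: dispersion estimation requires at least "
            "one cell line with duplicate samples at the same time point")
    q = normalized_counts(cm, sf)
    num = np.zeros(len(q))
    den = np.zeros(len(q))
    for g in groups:
        sub = q[g].to_numpy()
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        inv_sf = float((1.0 / sf[g]).mean())
        w = len(g) - 1
        num += w * (var - mu * inv_sf)
        den += w * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        signed = np.where(den > 0, num / den, np.nan)
    raw = pd.Series(np.maximum(signed, 0.0), index=q.index, name="alpha_raw")
    base_mean = q.mean(axis=1).rename("base_mean")

    # The trend is regressed on the *untruncated* moment estimates: the
    # signed values are mean-unbiased for alpha, whereas conditioning on
    # positive estimates truncation-biases the trend upward when replicate
    # groups are few (sampling noise is of the order of alpha itself).
    ok = pd.Series(np.isfinite(signed), index=q.index) & (base_mean > 0)
    if ok.sum() < 10:
        raise DiffExprError("too few genes with usable dispersion estimates")
    x = 1.0 / base_mean[ok].to_numpy()
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, signed[ok.to_numpy()], rcond=None)
    a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    return DispersionModel(raw=raw, trend=(a0, a1), base_mean=base_mean)


# ---------------------------------------------------------------------------
# gene-level Wald test
# ---------------------------------------------------------------------------

def _group_mean_var(counts: np.ndarray, sf: np.ndarray, mu: np.ndarray,
                    alpha: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Mean of normalized counts and its NB variance at common mean mu."""
    n = counts.shape[1]
    mean = (counts / sf).mean(axis=1)
    var = mu * float(np.sum(1.0 / sf)) / n**2 + alpha * mu**2 / n
    return mean, var


def test_gene_de(cm: CountMatrix, sf: pd.Series, dispersions: DispersionModel,
                 line: str, sharing: str = "trend") -> pd.DataFrame:
    """Per-gene 5 hr vs 0 hr Wald test within one cell line."""
    ids0 = cm.sample_ids(line, 0)
    ids5 = cm.sample_ids(line, 5)
    if not ids0 or not ids5:
        raise DiffExprError(f"line {line} lacks a 0 hr or 5 hr sample")
    c0 = cm.counts[ids0].to_numpy(dtype=float)
    c5 = cm.counts[ids5].to_numpy(dtype=float)
    s0 = sf[ids0].to_numpy()
    s5 = sf[ids5].to_numpy()
    m0 = (c0 / s0).mean(axis=1)
    m5 = (c5 / s5).mean(axis=1)
    mu = 0.5 * (m0 + m5)
    if sharing == "trend":
        alpha = dispersions.alpha(mu)
    else:
        alpha = dispersions.final(sharing).reindex(cm.counts.index).to_numpy()
    _, v0 = _group_mean_var(c0, s0, mu, alpha)
    _, v5 = _group_mean_var(c5, s5, mu, alpha)
    denom = np.sqrt(v0 + v5)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, (m5 - m0) / denom, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    log2fc = np.log2((m5 + LOG2FC_PSEUDOCOUNT) / (m0 + LOG2FC_PSEUDOCOUNT))
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene_id": cm.counts.index,
        "cell_line": line,
        "baseMean": mu,
        "mean_0h": m0,
        "mean_5h": m5,
        "log2FC": log2fc,
        "p_raw": p,
        "p_adj": p_adj,
        "direction": np.sign(log2fc).astype(int),
    }).set_index("gene_id")


def run_de_all_lines(cm: CountMatrix, sf: Optional[pd.Series] = None,
                     dispersions: Optional[DispersionModel] = None,
                     sharing: str = "trend") -> Dict[str, pd.DataFrame]:
    """DE tables for every cell line (0 hr / 5 hr samples only)."""
    cm05 = cm.select(times=(0, 5))
    if sf is None:
        sf = estimate_size_factors(cm05.counts)
    if dispersions is None:
        dispersions = fit_dispersions(cm05, sf)
    return {line: test_gene_de(cm05, sf, dispersions, line, sharing=sharing)
            for line in cm05.lines}


# ---------------------------------------------------------------------------
# exon-level differential usage (fit jointly across lines)
# ---------------------------------------------------------------------------

def test_exon_de(exon_cm: CountMatrix, gene_cm: CountMatrix,
                 sf: pd.Series, dispersions: DispersionModel,
                 exon_table: pd.DataFrame) -> pd.DataFrame:
    """Differential exon usage pooled over all cell lines.

    For each exon, Delta = mean over lines of (exon log2FC - gene log2FC);
    the NB-propagated delta-method SE gives a Wald p, BH-adjusted across
    exons.  An exon is a significant event iff p_adj < 0.01 and the usage
    fold change ``2**|Delta|`` is at least 50.  Genes with both a significant
    induced and a significant repressed exon, each the first exon of a
    distinct TSS, are flagged as promoter-switching candidates.

    This is a reduced surrogate for a full exon-level GLM: it tests a single
    pooled usage shift rather than per-line interaction terms.
    """
    unmapped = set(exon_cm.counts.index) - set(exon_table.index)
    if unmapped:
        raise DiffExprError(
            f"exons not mapped to genes: {sorted(unmapped)[:5]}")
    gene_of = exon_table["gene_id"].reindex(exon_cm.counts.index)
    missing_gene = set(gene_of) - set(gene_cm.counts.index)
    if missing_gene:
        raise DiffExprError(
            f"exon parents missing from gene counts: {sorted(missing_gene)[:5]}")

    lines = exon_cm.lines
    c = LOG2FC_PSEUDOCOUNT
    delta_sum = np.zeros(len(gene_of))
    var_sum = np.zeros(len(gene_of))
    for line in lines:
        ids0 = exon_cm.sample_ids(line, 0)
        ids5 = exon_cm.sample_ids(line, 5)
        e0 = (exon_cm.counts[ids0].to_numpy(dtype=float)
              / sf[ids0].to_numpy()).mean(axis=1)
        e5 = (exon_cm.counts[ids5].to_numpy(dtype=float)
              / sf[ids5].to_numpy()).mean(axis=1)
        g0 = (gene_cm.counts[ids0].to_numpy(dtype=float)
              / sf[ids0].to_numpy()).mean(axis=1)
        g5 = (gene_cm.counts[ids5].to_numpy(dtype=float)
              / sf[ids5].to_numpy()).mean(axis=1)
        g0 = pd.Series(g0, index=gene_cm.counts.index)[gene_of].to_numpy()
        g5 = pd.Series(g5, index=gene_cm.counts.index)[gene_of].to_numpy()
        lfc_e = np.log2((e5 + c) / (e0 + c))
        lfc_g = np.log2((g5 + c) / (g0 + c))
        delta_sum += lfc_e - lfc_g

        inv0 = float(np.mean(1.0 / sf[ids0].to_numpy())) / len(ids0)
        inv5 = float(np.mean(1.0 / sf[ids5].to_numpy())) / len(ids5)
        # delta-method variance of log2 of the group mean, Var(mean) under NB
        for m, inv, n_s in ((e0, inv0, len(ids0)), (e5, inv5, len(ids5)),
                            (g0, inv0, len(ids0)), (g5, inv5, len(ids5))):
            mm = np.maximum(m, c)
            alpha = dispersions.alpha(mm)
            v_mean = mm * inv + alpha * mm**2 / n_s
            var_sum += v_mean / (mm**2 * np.log(2)**2)

    k = len(lines)
    delta = delta_sum / k
    se = np.sqrt(var_sum) / k
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / se, 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    sig = (p_adj < 0.01) & (np.abs(delta) >= np.log2(USAGE_FOLD_THRESHOLD))

    res = pd.DataFrame({
        "gene_id": gene_of.values,
        "delta_log2": delta,
        "usage_fold": np.exp2(np.abs(delta)),
        "p_raw": p,
        "p_adj": p_adj,
        "significant": sig,
    }, index=exon_cm.counts.index.rename("exon_id"))
    res = res.join(exon_table[["is_first", "tss"]])

    # promoter-switching candidates
    res["promoter_switch_gene"] = False
    sig_first = res[res["significant"] & res["is_first"]]
    for gid, grp in sig_first.groupby("gene_id"):
        up = grp[grp["delta_log2"] > 0]
        down = grp[grp["delta_log2"] < 0]
        if len(up) and len(down):
            if set(up["tss"]) - set(down["tss"]) and \
                    set(down["tss"]) - set(up["tss"]):
                res.loc[res["gene_id"] == gid, "promoter_switch_gene"] = True
    return res
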