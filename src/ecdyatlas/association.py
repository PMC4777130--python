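"""Rate-limiting-factor and isoform-fraction correlation scans.

The Responsive Gene Count (RGC) of a line is the number of genes it
significantly induces or represses at 5 hr.  Scanning the correlation of
each gene's basal expression with the RGC across lines identifies candidate
rate-limiting factors; in the emulated system the receptor titer drives
restricted-response firing, so the receptor gene should top the ranking.
Residualizing the RGC on a conditioning gene's expression and re-scanning
tests whether that gene explains the association.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rgc_correlation_scan", "residualize_and_rescan",
           "isoform_fraction", "isoform_response_scan", "AssociationError"]

EXPRESSED_MIN = 1.0      # normalized count defining "basally expressed"
MIN_EXPRESSED_LINES = 3


class AssociationError(ValueError):
    pass


def _pearson_scan(x: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Vectorized per-row Pearson r of x (genes x lines) against y."""
    n = x.shape[1]
    xv = x.to_numpy(dtype=float)
    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    out = pd.DataFrame({"r": r, "p": p}, index=x.index)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.reindex(out["r"].abs().sort_values(ascending=False).index)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def rgc_correlation_scan(basal_expr: pd.DataFrame,
                         target_counts: pd.Series) -> pd.DataFrame:
    """Correlate log basal expression of every gene with per-line counts.

    `basal_expr` is normalized 0 hr expression (genes x lines);
    `target_counts` is the per-line RGC (or the induced or repressed count
    alone).  Genes basally expressed in fewer than three lines, and genes
    with zero variance across lines, are excluded.
    """
    lines = [l for l in basal_expr.columns if l in target_counts.index]
    if len(lines) < 4:
        raise AssociationError("correlation scan requires >= 4 lines")
    expr = basal_expr[lines]
    y = target_counts[lines].to_numpy(dtype=float)
    if np.allclose(y.var(), 0.0):
        raise AssociationError("target counts have zero variance across lines")
    keep = (expr >= EXPRESSED_MIN).sum(axis=1) >= MIN_EXPRESSED_LINES
    x = np.log2(expr.loc[keep] + 1.0)
    nonconst = x.var(axis=1) > 0
    x = x.loc[nonconst]
    if x.empty:
        raise AssociationError("no gene passes the expression filter")
    res = _pearson_scan(x, y)
    res.attrs["n_excluded_constant"] = int((~nonconst).sum())
    res.attrs["n_excluded_unexpressed"] = int((~keep).sum())
    return res


def residualize_and_rescan(basal_expr: pd.DataFrame,
                           target_counts: pd.Series,
                           conditioning_gene: str) -> pd.DataFrame:
    """OLS-residualize the target on one gene's expression, then re-scan."""
    lines = [l for l in basal_expr.columns if l in target_counts.index]
    g = np.log2(basal_expr.loc[conditioning_gene, lines].to_numpy(dtype=float)
                + 1.0)
    if np.allclose(g.var(), 0.0):
        raise AssociationError(
            f"conditioning gene {conditioning_gene} has zero variance")
    y = target_counts[lines].to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(g), g])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return rgc_correlation_scan(basal_expr[lines],
                                pd.Series(resid, index=lines))


def isoform_fraction(isoform_counts: pd.DataFrame,
                     isoform_lengths: pd.Series,
                     b_group: str = "EcR-B1/2",
                     a_group: str = "EcR-A") -> pd.Series:
    """Length-normalized B1/2 fraction per line.

    f_B = (c_B / L_B) / (c_A / L_A + c_B / L_B); lines where both isoform
    groups have zero counts are excluded.
    """
    cb = isoform_counts.loc[b_group] / isoform_lengths[b_group]
    ca = isoform_counts.loc[a_group] / isoform_lengths[a_group]
    total = ca + cb
    keep = total > 0
    dropped = list(total.index[~keep])
    f = (cb[keep] / total[keep]).rename("b12_fraction")
    f.attrs["excluded_lines"] = dropped
    return f


def isoform_response_scan(f_b: pd.Series,
                          de_tables: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Rank genes by correlation of their 5 hr log2FC with the B1/2 fraction."""
    lines = [l for l in f_b.index if l in de_tables]
    if len(lines) < 4:
        raise AssociationError("isoform scan requires >= 4 lines")
    y = f_b[lines].to_numpy(dtype=float)
    if np.allclose(y.var(), 0.0):
        raise AssociationError("isoform fraction has zero variance")
    lfc = pd.DataFrame({l: de_tables[l]["log2FC"] for l in lines})
    nonconst = lfc.var(axis=1) > 0
    return _pearson_scan(lfc.loc[nonconst], y)
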