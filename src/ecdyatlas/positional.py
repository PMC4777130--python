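"""Genomic neighborhood co-response analysis.

All distances are TSS-to-TSS.  For every responsive (gene, line), each gene
whose selected TSS lies within 20 kb contributes a record carrying whether
it responded and its trimmed directional score (signed -log10 p, clamped to
+/-10).  Records are grouped by promoter architecture (same-strand
upstream/downstream, divergent, convergent) and the focal response
direction, sorted by distance, aggregated in consecutive bins of 100
gene-line combinations, and LOESS-smoothed (local linear, tricube).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .catalog import ResponseCatalog
from .genome import Gene, GeneAnnotation
from .motifs import PWM

__all__ = ["directional_score", "classify_orientation", "select_ecdysone_tss",
           "select_tss_map", "neighbor_pairs", "build_neighbor_records",
           "build_profiles", "proximity_enrichment", "motif_enrichment",
           "NEIGHBOR_RADIUS", "PositionalError"]

NEIGHBOR_RADIUS = 20_000
BIN_SIZE = 100
SCORE_CLAMP = 10.0
LOESS_SPAN = 0.5


class PositionalError(ValueError):
    pass


def directional_score(p_raw, log2fc):
    """Signed -log10 p, clamped to [-10, 10]; zero fold change scores 0."""
    p = np.asarray(p_raw, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    with np.errstate(divide="ignore"):
        mag = -np.log10(p)
    score = np.sign(lfc) * mag
    score = np.clip(np.nan_to_num(score, nan=0.0,
                                  posinf=SCORE_CLAMP, neginf=-SCORE_CLAMP),
                    -SCORE_CLAMP, SCORE_CLAMP)
    if np.isscalar(p_raw) and np.isscalar(log2fc):
        return float(score)
    return score


def classify_orientation(focal_strand: str, focal_tss: int,
                         neighbor_strand: str, neighbor_tss: int) -> str:
    """Promoter architecture of a neighbor relative to the focal gene.

    Same-strand neighbors are upstream/downstream along the focal gene's
    direction of transcription.  Opposite-strand pairs are divergent when
    the two genes transcribe away from each other (5' ends facing away,
    i.e. back-to-back promoters) and convergent when they transcribe toward
    each other.
    """
    if focal_strand == neighbor_strand:
        if focal_strand == "+":
            return ("same-strand-downstream" if neighbor_tss > focal_tss
                    else "same-strand-upstream")
        return ("same-strand-downstream" if neighbor_tss < focal_tss
                else "same-strand-upstream")
    # opposite strands: find the gene transcribing rightward ('+')
    plus_tss = focal_tss if focal_strand == "+" else neighbor_tss
    minus_tss = neighbor_tss if focal_strand == "+" else focal_tss
    return "divergent" if minus_tss <= plus_tss else "convergent"


# ---------------------------------------------------------------------------
# ecdysone-relevant TSS selection
# ---------------------------------------------------------------------------

def select_ecdysone_tss(gene: Gene, sig_first_exon_tss: Set[int],
                        first_exon_expr_0h: Dict[int, float],
                        first_exon_expr_5h: Dict[int, float],
                        context: str) -> int:
    """Pick the TSS used for distance and promoter analyses.

    A TSS whose first exon shows a significant exon-level event wins; else
    the TSS whose first exon has the highest length-normalized expression at
    the relevant time point (5 hr for induced genes, 0 hr for repressed,
    the average for nonresponsive).  Single-TSS genes return their TSS.
    """
    tsss = gene.tsss
    if len(tsss) == 1:
        return tsss[0]
    sig = [t for t in tsss if t in sig_first_exon_tss]
    if sig:
        return sig[0]

    def relevance(t: int) -> float:
        e0 = first_exon_expr_0h.get(t, 0.0)
        e5 = first_exon_expr_5h.get(t, 0.0)
        if context == "induced":
            return e5
        if context == "repressed":
            return e0
        return 0.5 * (e0 + e5)

    return max(tsss, key=relevance)


def select_tss_map(annotation: GeneAnnotation,
                   catalog: Optional[ResponseCatalog] = None,
                   exon_results: Optional[pd.DataFrame] = None,
                   exon_expr: Optional[pd.DataFrame] = None,
                   exon_table: Optional[pd.DataFrame] = None) -> pd.Series:
    """Selected TSS per gene.

    `exon_expr` holds per-exon length-normalized expression with columns
    ``expr_0h`` and ``expr_5h``; `exon_results` is the exon-level DE table.
    Without exon information, the primary TSS is used.
    """
    sig_by_gene: Dict[str, Set[int]] = {}
    if exon_results is not None:
        sig = exon_results[exon_results["significant"]
                           & exon_results["is_first"]]
        for gid, grp in sig.groupby("gene_id"):
            sig_by_gene[gid] = set(grp["tss"])
    e0_by_gene: Dict[str, Dict[int, float]] = {}
    e5_by_gene: Dict[str, Dict[int, float]] = {}
    if exon_expr is not None and exon_table is not None:
        first = exon_table[exon_table["is_first"]]
        joined = first.join(exon_expr, how="inner")
        for gid, grp in joined.groupby("gene_id"):
            e0_by_gene[gid] = dict(zip(grp["tss"], grp["expr_0h"]))
            e5_by_gene[gid] = dict(zip(grp["tss"], grp["expr_5h"]))

    out = {}
    for gene in annotation:
        context = "nonresponsive"
        if catalog is not None and gene.gene_id in catalog.gene_summary.index:
            row = catalog.gene_summary.loc[gene.gene_id]
            if row["n_induced_lines"] >= max(1, row["n_repressed_lines"]):
                context = "induced" if row["n_induced_lines"] > 0 \
                    else "nonresponsive"
            elif row["n_repressed_lines"] > 0:
                context = "repressed"
        out[gene.gene_id] = select_ecdysone_tss(
            gene, sig_by_gene.get(gene.gene_id, set()),
            e0_by_gene.get(gene.gene_id, {}),
            e5_by_gene.get(gene.gene_id, {}), context)
    return pd.Series(out, name="tss")


# ---------------------------------------------------------------------------
# neighbor records and profiles
# ---------------------------------------------------------------------------

def neighbor_pairs(annotation: GeneAnnotation,
                   tss_map: pd.Series,
                   radius: int = NEIGHBOR_RADIUS) -> pd.DataFrame:
    """All ordered (focal, neighbor) gene pairs with TSS distance <= radius."""
    rows = []
    by_chrom: Dict[str, List[Gene]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: tss_map[g.gene_id])
        tss = [tss_map[g.gene_id] for g in genes]
        for i, ga in enumerate(genes):
            for j in range(i + 1, len(genes)):
                gb = genes[j]
                d = abs(tss[j] - tss[i])
                if d > radius:
                    break
                for focal, nb in ((ga, gb), (gb, ga)):
                    rows.append({
                        "focal_gene": focal.gene_id,
                        "neighbor_gene": nb.gene_id,
                        "distance": d,
                        "orientation": classify_orientation(
                            focal.strand, tss_map[focal.gene_id],
                            nb.strand, tss_map[nb.gene_id]),
                    })
    return pd.DataFrame(rows, columns=["focal_gene", "neighbor_gene",
                                       "distance", "orientation"])


def build_neighbor_records(annotation: GeneAnnotation,
                           catalog: ResponseCatalog,
                           de_tables: Dict[str, pd.DataFrame],
                           tss_map: pd.Series,
                           radius: int = NEIGHBOR_RADIUS) -> pd.DataFrame:
    """One record per (responsive focal gene, line, neighbor within radius)."""
    pairs = neighbor_pairs(annotation, tss_map, radius)
    if pairs.empty:
        return pairs
    calls_long = (catalog.calls.stack().rename("focal_call")
                  .rename_axis(["focal_gene", "cell_line"]).reset_index())
    calls_long = calls_long[calls_long["focal_call"] != 0]
    rec = calls_long.merge(pairs, on="focal_gene", how="inner")

    nb_call = (catalog.calls.stack().rename("neighbor_call")
               .rename_axis(["neighbor_gene", "cell_line"]).reset_index())
    rec = rec.merge(nb_call, on=["neighbor_gene", "cell_line"], how="left")
    rec["neighbor_call"] = rec["neighbor_call"].fillna(0).astype(int)
    rec["neighbor_responsive"] = rec["neighbor_call"] != 0

    score_parts = []
    for line, tab in de_tables.items():
        s = pd.DataFrame({
            "neighbor_gene": tab.index,
            "cell_line": line,
            "neighbor_score": directional_score(tab["p_raw"].to_numpy(),
                                                tab["log2FC"].to_numpy()),
        })
        score_parts.append(s)
    scores = pd.concat(score_parts, ignore_index=True)
    rec = rec.merge(scores, on=["neighbor_gene", "cell_line"], how="left")
    rec["focal_direction"] = np.where(rec["focal_call"] > 0,
                                      "induced", "repressed")
    return rec


def build_profiles(records: pd.DataFrame, bin_size: int = BIN_SIZE,
                   span: float = LOESS_SPAN) -> pd.DataFrame:
    """Binned and LOESS-smoothed fraction-responsive / mean-score profiles.

    Within each (orientation x focal-direction) group, records sorted by
    distance are aggregated in consecutive bins of `bin_size` combinations
    (the last bin may be smaller; groups smaller than one bin yield a single
    bin).  Returns one row per bin with smoothed columns, and attaches the
    10-20 kb background responsive fraction as ``.attrs['background']``.
    """
    if records.empty:
        raise PositionalError("no neighbor records")
    out = []
    for (orient, fdir), grp in records.groupby(
            ["orientation", "focal_direction"]):
        grp = grp.sort_values("distance", kind="mergesort")
        n = len(grp)
        bins = np.arange(n) // bin_size
        agg = grp.assign(_bin=bins).groupby("_bin").agg(
            bin_center=("distance", "mean"),
            n_records=("distance", "size"),
            fraction_responsive=("neighbor_responsive", "mean"),
            mean_score=("neighbor_score", "mean"),
        ).reset_index(drop=True)
        agg["orientation"] = orient
        agg["focal_direction"] = fdir
        x = agg["bin_center"].to_numpy(dtype=float)
        for col in ("fraction_responsive", "mean_score"):
            y = agg[col].to_numpy(dtype=float)
            if len(agg) >= 3:
                sm = lowess(y, x, frac=span, it=0, return_sorted=False)
            else:
                sm = y.copy()
            agg[f"smoothed_{col}"] = sm
        out.append(agg)
    prof = pd.concat(out, ignore_index=True)
    far = records[(records["distance"] >= 10_000)
                  & (records["distance"] <= 20_000)]
    prof.attrs["background"] = (float(far["neighbor_responsive"].mean())
                                if len(far) else np.nan)
    return prof


# ---------------------------------------------------------------------------
# enrichment analyses
# ---------------------------------------------------------------------------

def proximity_enrichment(weak_set: Iterable[str], induced_set: Iterable[str],
                         tss_map: pd.Series,
                         chrom_of: Dict[str, str],
                         radius: int = 2500) -> dict:
    """Are weak genes closer to significantly induced genes than expected?

    observed: fraction of weak genes with an induced gene's TSS within
    `radius`; expected: the same fraction over all non-weak genes; the
    enrichment is observed/expected - 1 with an upper-tail binomial p.
    """
    weak = [g for g in weak_set if g in tss_map.index]
    induced = [g for g in induced_set if g in tss_map.index]
    if not weak or not induced:
        raise PositionalError("empty weak or induced set")

    ind_by_chrom: Dict[str, np.ndarray] = {}
    for g in induced:
        ind_by_chrom.setdefault(chrom_of[g], []).append(tss_map[g])
    ind_by_chrom = {c: np.sort(np.array(v)) for c, v in ind_by_chrom.items()}

    induced_s = set(induced)

    def near(g: str) -> bool:
        pos = tss_map[g]
        arr = ind_by_chrom.get(chrom_of[g])
        if arr is None:
            return False
        lo = np.searchsorted(arr, pos - radius, side="left")
        hi = np.searchsorted(arr, pos + radius, side="right")
        count = hi - lo
        if g in induced_s:
            count -= 1  # a gene is never its own neighbor
        return count > 0

    weak_sset = set(weak)
    background = [g for g in tss_map.index if g not in weak_sset]
    obs_hits = sum(near(g) for g in weak)
    observed = obs_hits / len(weak)
    expected = (sum(near(g) for g in background) / len(background)
                if background else np.nan)
    if not expected or np.isnan(expected):
        return {"observed": observed, "expected": expected,
                "enrichment": None, "p": None,
                "note": "expected rate is zero; enrichment undefined"}
    enrich = observed / expected - 1.0
    p = float(stats.binom.sf(obs_hits - 1, len(weak), expected))
    return {"observed": observed, "expected": expected,
            "enrichment": enrich, "p": p, "n_weak": len(weak)}


def motif_enrichment(promoters: Dict[str, str],
                     foreground_genes: Iterable[str],
                     background_genes: Iterable[str],
                     pwm: PWM, threshold: float) -> dict:
    """Fold enrichment of PWM hits in foreground vs background promoters.

    A gene has the motif iff any window on either strand scores at or above
    `threshold`.  The hypergeometric p treats the background as the
    population and the foreground as the draw.
    """
    fg = [g for g in foreground_genes if g in promoters]
    bg = [g for g in background_genes if g in promoters]
    if not fg or not bg:
        raise PositionalError("empty foreground or background")
    fg_hits = sum(pwm.has_hit(promoters[g], threshold) for g in fg)
    bg_hits = sum(pwm.has_hit(promoters[g], threshold) for g in bg)
    fg_rate = fg_hits / len(fg)
    bg_rate = bg_hits / len(bg)
    if bg_rate == 0:
        return {"foreground_rate": fg_rate, "background_rate": 0.0,
                "enrichment": None, "p": None,
                "note": "background hit rate is zero; enrichment undefined"}
    universe = len(bg)
    p = float(stats.hypergeom.sf(fg_hits - 1, universe, bg_hits, len(fg))) \
        if set(fg) <= set(bg) else float(
            stats.binom.sf(fg_hits - 1, len(fg), bg_rate))
    return {"foreground_rate": fg_rate, "background_rate": bg_rate,
            "enrichment": fg_rate / bg_rate - 1.0, "p": p,
            "n_foreground": len(fg), "n_background": len(bg)}
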