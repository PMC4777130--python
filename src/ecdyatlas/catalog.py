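"""Cross-line response catalog.

Fisher's method is applied to within-line *ranks* rather than raw p-values:
for a given direction, wrong-direction genes are assigned p = 1 (tying them
at the bottom of the list), genes are ranked ascending with mid-ranks for
ties, and u_i = rank/(N+1) is the uniform score combined as
X = -2 sum ln(u_i) ~ chi2 with 2k degrees of freedom.  Rank-based scores
have uniform marginals by construction, so the combination is calibrated
regardless of the per-line test's finite-sample behavior.

Per-line calls use a biological relevance gate (|log2FC| >= 1, i.e. two-fold)
plus a two-tier significance rule: adjusted p < 0.01 on its own, or raw
p < 0.01 rescued by a same-direction Fisher p below 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_combine", "call_responsive", "summarize_catalog",
           "ResponseCatalog", "jaccard_matrix", "jaccard_cluster",
           "go_enrichment", "CatalogError",
           "FOLD_GATE_LOG2", "ADJ_P_THRESHOLD", "RAW_P_THRESHOLD",
           "FISHER_THRESHOLD"]

FOLD_GATE_LOG2 = 1.0
ADJ_P_THRESHOLD = 0.01
RAW_P_THRESHOLD = 0.01
FISHER_THRESHOLD = 1e-8


class CatalogError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fisher's method on within-line ranks
# ---------------------------------------------------------------------------

def fisher_combine(de_tables: Dict[str, pd.DataFrame],
                   direction: str, tie_method: str = "random",
                   tie_seed: int = 0) -> pd.DataFrame:
    """Combine within-line ranked evidence for induction or repression.

    Tied genes (notably the wrong-direction block assigned p = 1) are placed
    at random ranks within their tied block by default, which makes each
    line's u scores an exact permutation of {1..N}/(N+1) and hence exactly
    uniform marginally -- the property the combination requires.  Mid-ranks
    (``tie_method="average"``) are available but concentrate the tied block
    at a single point, slightly deflating the combined statistic.  The
    random placement is deterministic given ``tie_seed``.

    Returns a frame indexed by gene with columns ``statistic`` (X), ``df``
    (2k) and ``p_fisher``.
    """
    if direction not in ("induction", "repression"):
        raise CatalogError(f"unknown direction {direction!r}")
    if tie_method not in ("random", "average"):
        raise CatalogError(f"unknown tie_method {tie_method!r}")
    if not de_tables:
        raise CatalogError("no cell lines to combine")
    lines = list(de_tables)
    genes = de_tables[lines[0]].index
    n = len(genes)
    if n == 0:
        raise CatalogError("empty gene universe")
    rng = np.random.default_rng(
        np.random.SeedSequence([tie_seed, {"induction": 0,
                                           "repression": 1}[direction]]))
    x = np.zeros(n)
    for line in lines:
        tab = de_tables[line]
        if not tab.index.equals(genes):
            tab = tab.reindex(genes)
            if tab["p_raw"].isna().any():
                raise CatalogError(
                    f"line {line} does not cover the shared gene universe")
        lfc = tab["log2FC"].to_numpy()
        p = tab["p_raw"].to_numpy()
        right_dir = lfc > 0 if direction == "induction" else lfc < 0
        p_dir = np.where(right_dir, p, 1.0)
        if tie_method == "average":
            ranks = stats.rankdata(p_dir, method="average")
        else:
            order = np.lexsort((rng.random(n), p_dir))
            ranks = np.empty(n)
            ranks[order] = np.arange(1, n + 1)
        u = ranks / (n + 1)
        x += -2.0 * np.log(u)
    k = len(lines)
    p_fisher = stats.chi2.sf(x, 2 * k)
    return pd.DataFrame({"statistic": x, "df": 2 * k, "p_fisher": p_fisher},
                        index=genes.rename("gene_id"))


def fisher_survival_series(x: float, df: int) -> float:
    """Closed-form chi-square upper tail for even df (independent oracle).

    P(X > x) = exp(-x/2) * sum_{j<df/2} (x/2)^j / j!
    """
    if df % 2:
        raise ValueError("closed form requires even df")
    half = x / 2.0
    term, total = 1.0, 1.0
    for j in range(1, df // 2):
        term *= half / j
        total += term
    return float(np.exp(-half) * total)


# ---------------------------------------------------------------------------
# per-line calls and catalog summary
# ---------------------------------------------------------------------------

def call_responsive(de_tables: Dict[str, pd.DataFrame],
                    fisher_induction: pd.DataFrame,
                    fisher_repression: pd.DataFrame) -> pd.DataFrame:
    """Gene x line call matrix: +1 induced, -1 repressed, 0 not significant."""
    lines = list(de_tables)
    genes = de_tables[lines[0]].index
    calls = pd.DataFrame(0, index=genes.rename("gene_id"),
                         columns=pd.Index(lines, name="cell_line"),
                         dtype=np.int8)
    p_fi = fisher_induction["p_fisher"].reindex(genes).to_numpy()
    p_fr = fisher_repression["p_fisher"].reindex(genes).to_numpy()
    for line in lines:
        tab = de_tables[line].reindex(genes)
        lfc = tab["log2FC"].to_numpy()
        p_raw = tab["p_raw"].to_numpy()
        p_adj = tab["p_adj"].to_numpy()
        fold_ok = np.abs(lfc) >= FOLD_GATE_LOG2
        p_fisher_same = np.where(lfc > 0, p_fi, p_fr)
        strict = p_adj < ADJ_P_THRESHOLD
        relaxed = (p_raw < RAW_P_THRESHOLD) & (p_fisher_same < FISHER_THRESHOLD)
        called = fold_ok & (strict | relaxed)
        calls[line] = np.where(called, np.sign(lfc), 0).astype(np.int8)
    return calls


@dataclass
class ResponseCatalog:
    """Per-gene breadth classes, weak/bidirectional flags, and per-line RGC."""

    calls: pd.DataFrame          # genes x lines in {-1, 0, +1}
    gene_summary: pd.DataFrame
    line_summary: pd.DataFrame
    fisher_induction: pd.DataFrame
    fisher_repression: pd.DataFrame

    @property
    def n_lines(self) -> int:
        return self.calls.shape[1]

    def genes_in_class(self, breadth: str, direction: str) -> List[str]:
        col = f"breadth_{direction}"
        return list(self.gene_summary.index[self.gene_summary[col] == breadth])

    def restricted_sets(self, direction: Optional[str] = None) -> Dict[str, Set[str]]:
        """Per-line responsive gene sets limited to restricted genes."""
        sign = {"induced": 1, "repressed": -1}.get(direction)
        out: Dict[str, Set[str]] = {}
        for line in self.calls.columns:
            members: Set[str] = set()
            for d, s in (("induced", 1), ("repressed", -1)):
                if sign is not None and s != sign:
                    continue
                restricted = set(self.genes_in_class("restricted", d))
                hit = set(self.calls.index[self.calls[line] == s])
                members |= hit & restricted
            out[line] = members
        return out


def summarize_catalog(calls: pd.DataFrame,
                      fisher_induction: pd.DataFrame,
                      fisher_repression: pd.DataFrame) -> ResponseCatalog:
    n_lines = calls.shape[1]
    half = n_lines / 2.0
    n_ind = (calls == 1).sum(axis=1)
    n_rep = (calls == -1).sum(axis=1)
    p_fi = fisher_induction["p_fisher"].reindex(calls.index)
    p_fr = fisher_repression["p_fisher"].reindex(calls.index)

    def breadth(n_called: pd.Series) -> pd.Series:
        out = pd.Series("none", index=calls.index)
        out[n_called > 0] = "restricted"
        out[n_called > half] = "widespread"
        return out

    gene_summary = pd.DataFrame({
        "n_induced_lines": n_ind,
        "n_repressed_lines": n_rep,
        "breadth_induced": breadth(n_ind),
        "breadth_repressed": breadth(n_rep),
        "p_fisher_induction": p_fi,
        "p_fisher_repression": p_fr,
        "weak_induced": (p_fi < FISHER_THRESHOLD) & (n_ind == 0),
        "weak_repressed": (p_fr < FISHER_THRESHOLD) & (n_rep == 0),
        "bidirectional": (n_ind > 0) & (n_rep > 0),
    })
    line_summary = pd.DataFrame({
        "n_induced": (calls == 1).sum(axis=0),
        "n_repressed": (calls == -1).sum(axis=0),
    })
    line_summary["rgc"] = line_summary["n_induced"] + line_summary["n_repressed"]
    return ResponseCatalog(calls, gene_summary, line_summary,
                           fisher_induction, fisher_repression)


# ---------------------------------------------------------------------------
# Jaccard similarity clustering of the restricted response
# ---------------------------------------------------------------------------

def jaccard_matrix(sets_by_line: Dict[str, Set[str]]) -> pd.DataFrame:
    lines = list(sets_by_line)
    m = pd.DataFrame(0.0, index=lines, columns=lines)
    for a in lines:
        for b in lines:
            sa, sb = sets_by_line[a], sets_by_line[b]
            union = len(sa | sb)
            m.loc[a, b] = len(sa & sb) / union if union else 0.0
    return m


def jaccard_cluster(catalog: ResponseCatalog):
    """Average-linkage clustering of lines on 1 - Jaccard of restricted sets.

    Similarity is computed separately for induced and repressed restricted
    responses; the combined (union) similarity drives the dendrogram.
    Returns (similarity dict, linkage matrix, leaf order).
    """
    if catalog.n_lines < 2:
        raise CatalogError("clustering requires at least two lines")
    sims = {
        "induced": jaccard_matrix(catalog.restricted_sets("induced")),
        "repressed": jaccard_matrix(catalog.restricted_sets("repressed")),
        "combined": jaccard_matrix(catalog.restricted_sets(None)),
    }
    dist = 1.0 - sims["combined"].to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    from scipy.cluster.hierarchy import leaves_list
    order = [sims["combined"].index[i] for i in leaves_list(z)]
    return sims, z, order


# ---------------------------------------------------------------------------
# GO enrichment (flat term sets, hypergeometric upper tail)
# ---------------------------------------------------------------------------

def go_enrichment(gene_set: Iterable[str], universe: Iterable[str],
                  gene2go: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric term enrichment of `gene_set` against `universe`.

    `gene2go` has columns gene_id, term.  The universe is restricted to
    genes with at least one annotated term; terms with no annotated gene in
    the universe are skipped.
    """
    annotated = set(gene2go["gene_id"])
    universe = set(universe) & annotated
    gene_set = set(gene_set) & universe
    if not universe:
        raise CatalogError("empty annotated universe")
    m_total = len(universe)
    n_set = len(gene_set)
    rows = []
    for term, grp in gene2go.groupby("term"):
        term_genes = set(grp["gene_id"]) & universe
        if not term_genes:
            continue  # term absent from universe: skipped
        k = len(term_genes & gene_set)
        expected = len(term_genes) * n_set / m_total
        fold = k / expected if expected > 0 else np.nan
        p = stats.hypergeom.sf(k - 1, m_total, len(term_genes), n_set)
        rows.append({"term": term, "term_size": len(term_genes),
                     "overlap": k, "fold_enrichment": fold, "p": p})
    res = pd.DataFrame(rows).set_index("term")
    if len(res):
        res["q"] = multipletests(res["p"], method="fdr_bh")[1]
        res = res.sort_values("p")
    return res
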