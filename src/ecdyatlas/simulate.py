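"""Synthetic atlas generator with planted ground truth.

Emulates the study design downstream stages analyze: many cell lines sampled
at 0 and 5 hr around a hormone exposure, negative-binomial counts with a
dispersion--mean trend, a widespread responder set active in every line, a
restricted set whose response requires (a) the responsible TF expressed in
the line, (b) that TF's motif planted in the promoter, and (c) the per-line
receptor titer to exceed a per-gene threshold, weak sub-twofold consistent
responders, tandem/divergent gene-pair coupling, promoter-switching exon
events, and a 5-point time course for a subset of lines.

Firing of restricted responses is encoded as a per-gene uniform threshold on
the line's receptor titer: the margin is Bernoulli(titer), and the planted
count of firing genes is exactly nondecreasing in titer across lines.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig, derive_seed
from .countio import CountMatrix
from .genome import (Gene, GeneAnnotation, Transcript, promoter_from_genomic,
                     reverse_complement)
from .motifs import PWM, write_meme

__all__ = [
    "LineStates", "GroundTruth", "SimulatedDataset",
    "generate_annotation", "generate_line_states", "make_tf_pwms",
    "assign_truth", "generate_promoters", "simulate_counts",
    "simulate_dataset",
]

ECR_NAME = "EcR"
#: canonical receptor response element: inverted repeat AGGTCA/TGACCT
ECRE_CONSENSUS = "AGGTCAATGACCT"

_SHAPE_MULT = {
    "monotone": {0: 0.0, 1: 0.35, 3: 0.75, 5: 1.0, 7: 1.25},
    "fast": {0: 0.0, 1: 1.2, 3: 0.8, 5: 0.45, 7: 0.2},
    "flat": {0: 0.0, 1: 0.0, 3: 0.0, 5: 0.0, 7: 0.0},
}


# ---------------------------------------------------------------------------
# line states
# ---------------------------------------------------------------------------

@dataclass
class LineStates:
    """Per-line TF expression pattern, receptor titer, and isoform fraction."""

    expressed: pd.DataFrame      # lines x TFs, bool
    ecr_titer: pd.Series         # per line, within ecr_titer_range
    b12_fraction: pd.Series      # per line, within [0.31, 1.0]

    @property
    def tf_names(self) -> List[str]:
        return list(self.expressed.columns)

    @property
    def lines(self) -> List[str]:
        return list(self.expressed.index)

    def to_frame(self) -> pd.DataFrame:
        df = self.expressed.astype(int).copy()
        df.insert(0, "ecr_titer", self.ecr_titer)
        df.insert(1, "b12_fraction", self.b12_fraction)
        return df


def tf_gene_names(config: SimulationConfig) -> List[str]:
    return [ECR_NAME] + [f"TF{i + 2:02d}" for i in range(config.n_tfs - 1)]


def generate_line_states(config: SimulationConfig,
                         seed: Optional[int] = None) -> LineStates:
    config.validate()
    rng = np.random.default_rng(
        derive_seed(config.seed if seed is None else seed, "line_states"))
    lines = list(config.line_names)
    tfs = tf_gene_names(config)
    expressed = pd.DataFrame(
        rng.random((len(lines), len(tfs))) < config.tf_expression_prob,
        index=pd.Index(lines, name="cell_line"), columns=tfs)
    expressed[ECR_NAME] = True  # the receptor is expressed everywhere
    # every TF expressed somewhere, so the eligibility filter keeps them all
    for tf in tfs:
        if not expressed[tf].any():
            expressed.loc[lines[int(rng.integers(len(lines)))], tf] = True
    lo, hi = config.ecr_titer_range
    titer = pd.Series(rng.uniform(lo, hi, len(lines)), index=expressed.index,
                      name="ecr_titer")
    b12 = pd.Series(rng.uniform(0.31, 1.0, len(lines)), index=expressed.index,
                    name="b12_fraction")
    return LineStates(expressed, titer, b12)


def make_tf_pwms(config: SimulationConfig,
                 seed: Optional[int] = None) -> List[PWM]:
    """One PWM per TF; the receptor gets the canonical EcRE inverted repeat."""
    if len(ECRE_CONSENSUS) > config.promoter_len or \
            config.motif_width > config.promoter_len:
        raise ConfigError("PWM width exceeds promoter length")
    rng = np.random.default_rng(
        derive_seed(config.seed if seed is None else seed, "pwms"))
    pwms = [PWM.from_consensus(ECR_NAME, ECRE_CONSENSUS)]
    seen = {ECRE_CONSENSUS}
    for name in tf_gene_names(config)[1:]:
        while True:
            cons = "".join("ACGT"[i] for i in
                           rng.integers(0, 4, config.motif_width))
            if cons not in seen:
                seen.add(cons)
                break
        pwms.append(PWM.from_consensus(name, cons))
    return pwms


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _build_gene(gene_id: str, chrom: str, strand: str, start: int,
                body_len: int, two_tss: bool, rng) -> Gene:
    """Two-exon primary transcript; optionally a second, downstream TSS."""
    e1 = int(rng.integers(160, 240))
    g1 = int(rng.integers(450, 900))
    e1 = min(e1, body_len - g1 - 200) if body_len - g1 - 200 > 50 else 80
    tail_len = body_len - e1 - g1
    if tail_len < 50:
        g1 = max(60, body_len - e1 - 120)
        tail_len = body_len - e1 - g1
    s, L = start, body_len
    if strand == "+":
        t1 = Transcript(f"{gene_id}.t1",
                        [(s, s + e1), (s + e1 + g1, s + L)], strand)
    else:
        t1 = Transcript(f"{gene_id}.t1",
                        [(s, s + tail_len), (s + L - e1, s + L)], strand)
    transcripts = [t1]
    if two_tss:
        e2 = 150
        lo_d, hi_d = e1 + 10, e1 + g1 - e2 - 10
        if hi_d > lo_d:
            d = int(rng.integers(lo_d, hi_d))
            if strand == "+":
                t2 = Transcript(f"{gene_id}.t2",
                                [(s + d, s + d + e2), (s + e1 + g1, s + L)],
                                strand)
            else:
                t2 = Transcript(f"{gene_id}.t2",
                                [(s, s + tail_len),
                                 (s + L - d - e2, s + L - d)], strand)
            transcripts.append(t2)
    return Gene(gene_id, chrom, strand, transcripts)


def generate_annotation(config: SimulationConfig,
                        seed: Optional[int] = None) -> GeneAnnotation:
    """Place genes on >= 2 chromosomes with tandem and divergent pair units.

    Tandem pairs are same-strand consecutive genes with short bodies (TSS
    spacing well under 2 kb); divergent pairs are head-to-head with a TSS gap
    under 1 kb.  Intergenic gaps keep most neighbors within 20 kb so all four
    orientation classes are populated.
    """
    config.validate()
    rng = np.random.default_rng(
        derive_seed(config.seed if seed is None else seed, "annotation"))
    tf_names = tf_gene_names(config)
    n_other = config.n_genes - len(tf_names)
    if n_other < 2 * config.operon_pair_count + 2 * config.divergent_pair_count:
        raise ConfigError("n_genes too small for the requested pair counts")
    other_ids = [f"G{i + 1:04d}" for i in range(n_other)]

    # unit list: ("tandem", id_a, id_b) | ("divergent", id_a, id_b) | ("single", id)
    units: List[tuple] = []
    cursor = 0
    for k in range(config.operon_pair_count):
        units.append(("tandem", other_ids[cursor], other_ids[cursor + 1]))
        cursor += 2
    for k in range(config.divergent_pair_count):
        units.append(("divergent", other_ids[cursor], other_ids[cursor + 1]))
        cursor += 2
    singles = other_ids[cursor:] + tf_names
    units.extend(("single", gid) for gid in singles)
    rng.shuffle(units)

    chroms = ["chr2L", "chr2R", "chr3L"]
    positions = {c: 1000 for c in chroms}
    genes: List[Gene] = []
    pair_rows = []
    pair_no = 0
    two_tss_flags = rng.random(config.n_genes) < 0.15
    flag_iter = iter(two_tss_flags)

    for unit in units:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = positions[chrom]
        if unit[0] == "single":
            gid = unit[1]
            body = int(rng.integers(1000, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_build_gene(gid, chrom, strand, pos, body,
                                     next(flag_iter), rng))
            pos += body
        elif unit[0] == "tandem":
            _, ga, gb = unit
            strand = "+" if rng.random() < 0.5 else "-"
            la, lb = int(rng.integers(650, 1000)), int(rng.integers(650, 1000))
            gap = int(rng.integers(150, 500))
            genes.append(_build_gene(ga, chrom, strand, pos, la,
                                     next(flag_iter), rng))
            genes.append(_build_gene(gb, chrom, strand, pos + la + gap, lb,
                                     next(flag_iter), rng))
            pos += la + gap + lb
            pair_no += 1
            pair_rows.append({"pair_id": f"P{pair_no:03d}",
                              "pair_type": "tandem", "gene_a": ga, "gene_b": gb})
        else:  # divergent: left gene on '-', right gene on '+'
            _, ga, gb = unit
            la, lb = int(rng.integers(900, 2000)), int(rng.integers(900, 2000))
            tss_gap = int(rng.integers(300, 900))
            genes.append(_build_gene(ga, chrom, "-", pos, la,
                                     next(flag_iter), rng))
            genes.append(_build_gene(gb, chrom, "+", pos + la - 1 + tss_gap,
                                     lb, next(flag_iter), rng))
            pos += la - 1 + tss_gap + lb
            pair_no += 1
            pair_rows.append({"pair_id": f"P{pair_no:03d}",
                              "pair_type": "divergent",
                              "gene_a": ga, "gene_b": gb})
        positions[chrom] = pos + int(rng.integers(1500, 8000))

    chrom_sizes = {c: positions[c] + 1000 for c in chroms}
    for c, size in chrom_sizes.items():
        if size <= 2000:
            continue
    pairs = pd.DataFrame(pair_rows,
                         columns=["pair_id", "pair_type", "gene_a", "gene_b"])
    return GeneAnnotation(genes, chrom_sizes=chrom_sizes, pairs=pairs)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted classes, per-line firing, and true 5 hr log2 fold changes."""

    genes: pd.DataFrame          # index gene_id; class/direction/flags
    lfc: pd.DataFrame            # genes x lines true log2FC at 5 hr
    shapes: pd.DataFrame         # gene, cell_line, shape for timecourse lines
    states: LineStates

    def gene_class(self, cls: str) -> List[str]:
        return list(self.genes.index[self.genes["gene_class"] == cls])

    def verify(self) -> None:
        """Assert the structural invariants of the planted truth."""
        restricted = self.genes["gene_class"] == "restricted"
        for gid in self.genes.index[restricted]:
            tf = self.genes.loc[gid, "responsible_tf"]
            responding = self.lfc.loc[gid] != 0.0
            on = self.states.expressed[tf].reindex(self.lfc.columns)
            if (responding & ~on).any():
                raise AssertionError(
                    f"{gid} responds in a line not expressing {tf}")


def assign_truth(config: SimulationConfig, annotation: GeneAnnotation,
                 states: LineStates,
                 seed: Optional[int] = None) -> GroundTruth:
    config.validate()
    rng = np.random.default_rng(
        derive_seed(config.seed if seed is None else seed, "truth"))
    lines = states.lines
    tf_names = states.tf_names
    gene_ids = annotation.gene_ids()
    non_tf = [g for g in gene_ids if g not in set(tf_names)]

    genes = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    genes["gene_class"] = "null"
    genes["direction"] = 0
    genes["responsible_tf"] = ""
    genes["titer_threshold"] = np.nan
    genes["tss_switch"] = False
    genes["isoform_coupled"] = False
    genes["bidirectional"] = False
    genes["pair_id"] = ""
    genes["pair_type"] = ""

    for _, row in annotation.pairs.iterrows():
        for member in ("gene_a", "gene_b"):
            genes.loc[row[member], ["pair_id", "pair_type"]] = \
                [row["pair_id"], row["pair_type"]]

    # pair members consume the widespread / null quotas first
    widespread: List[str] = []
    nulls_reserved: List[str] = []
    for _, row in annotation.pairs.iterrows():
        if row["pair_type"] == "tandem":
            widespread += [row["gene_a"], row["gene_b"]]
        else:
            widespread.append(row["gene_a"])
            nulls_reserved.append(row["gene_b"])
    taken = set(widespread) | set(nulls_reserved)
    pool = [g for g in non_tf if g not in taken]
    rng.shuffle(pool)
    need_wide = config.n_widespread - len(widespread)
    widespread += pool[:need_wide]
    pool = pool[need_wide:]
    restricted = pool[:config.n_restricted]
    pool = pool[config.n_restricted:]
    weak = pool[:config.n_weak]

    genes.loc[widespread, "gene_class"] = "widespread"
    genes.loc[restricted, "gene_class"] = "restricted"
    genes.loc[weak, "gene_class"] = "weak"

    # directions: tandem pairs co-induced; ~2/3 of other responders induced
    genes.loc[widespread, "direction"] = np.where(
        rng.random(len(widespread)) < 0.68, 1, -1)
    tandem = genes.index[(genes["pair_type"] == "tandem")]
    genes.loc[tandem, "direction"] = 1
    divergent_wide = [g for g in widespread
                      if genes.loc[g, "pair_type"] == "divergent"]
    genes.loc[divergent_wide, "direction"] = 1
    genes.loc[restricted, "direction"] = np.where(
        rng.random(len(restricted)) < 0.6, 1, -1)
    genes.loc[weak, "direction"] = np.where(
        rng.random(len(weak)) < 0.5, 1, -1)

    # balanced assignment: each TF drives roughly the same number of
    # restricted genes (the response is conditional on dozens of TFs, none
    # of which dominates)
    other_tfs = [t for t in tf_names if t != ECR_NAME]
    if config.n_responsible_tfs is not None:
        other_tfs = other_tfs[:config.n_responsible_tfs]
    if restricted:
        reps = int(np.ceil(len(restricted) / len(other_tfs)))
        pool_tfs = np.array((other_tfs * reps)[:len(restricted)])
        rng.shuffle(pool_tfs)
        genes.loc[restricted, "responsible_tf"] = pool_tfs
    _, thi = config.ecr_titer_range
    genes.loc[restricted, "titer_threshold"] = rng.uniform(
        0.0, thi, len(restricted))

    bidir = restricted[:config.bidirectional_count]
    genes.loc[bidir, "bidirectional"] = True

    iso = [g for g in widespread
           if genes.loc[g, "direction"] > 0 and genes.loc[g, "pair_id"] == ""]
    genes.loc[iso[:config.isoform_coupled_count], "isoform_coupled"] = True

    two_tss_nulls = [g for g in non_tf
                     if genes.loc[g, "gene_class"] == "null"
                     and g not in nulls_reserved
                     and len(annotation[g].tsss) >= 2]
    genes.loc[two_tss_nulls[:config.tss_switch_count], "tss_switch"] = True

    # true per-(gene, line) log2 fold changes at 5 hr
    lfc = pd.DataFrame(0.0, index=genes.index, columns=pd.Index(lines))
    titer = states.ecr_titer
    b12 = states.b12_fraction
    for gid in widespread:
        d = genes.loc[gid, "direction"]
        if genes.loc[gid, "isoform_coupled"]:
            lfc.loc[gid] = d * config.effect_log2fc * (0.5 + 0.5 * b12.values)
        else:
            lfc.loc[gid] = d * config.effect_log2fc
    for gid in restricted:
        tf = genes.loc[gid, "responsible_tf"]
        fires = (states.expressed[tf].values
                 & (titer.values >= genes.loc[gid, "titer_threshold"]))
        if genes.loc[gid, "bidirectional"]:
            signs = np.where(rng.random(len(lines)) < 0.5, 1, -1)
        else:
            signs = genes.loc[gid, "direction"]
        lfc.loc[gid] = np.where(fires, signs * config.effect_log2fc, 0.0)
    n_weak_lines = int(round(config.weak_line_fraction * len(lines)))
    for gid in weak:
        chosen = rng.choice(len(lines), size=n_weak_lines, replace=False)
        v = np.zeros(len(lines))
        v[chosen] = genes.loc[gid, "direction"] * config.weak_log2fc
        lfc.loc[gid] = v

    # timecourse trajectory shapes
    shape_rows = []
    tc_lines = list(config.timecourse_lines or ())
    for line in tc_lines:
        responding = lfc[line] != 0.0
        for gid in genes.index:
            if not responding.loc[gid]:
                shape = "flat"
            elif config.fast_line is not None:
                shape = "fast" if line == config.fast_line else "monotone"
            else:
                shape = "fast" if rng.random() < 0.25 else "monotone"
            shape_rows.append({"gene_id": gid, "cell_line": line,
                               "shape": shape})
    shapes = pd.DataFrame(shape_rows,
                          columns=["gene_id", "cell_line", "shape"])
    return GroundTruth(genes, lfc, shapes, states)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def generate_promoters(annotation: GeneAnnotation, pwms: List[PWM],
                       truth: GroundTruth, seed: int = 0,
                       promoter_len: int = 500) -> Dict[str, str]:
    """i.i.d. uniform-ACGT promoters with planted consensus sites.

    Each gene's promoter is `promoter_len` bp upstream of its primary TSS,
    oriented along transcription (minus-strand genes are reverse-complemented
    from the plus-strand genomic window).  Restricted genes carry their
    responsible TF's consensus; widespread induced genes carry the receptor
    response element.
    """
    pwm_by_name = {p.name: p for p in pwms}
    for p in pwms:
        if p.width > promoter_len:
            raise ConfigError(
                f"PWM {p.name} wider than promoter ({p.width} > {promoter_len})")
    rng = np.random.default_rng(derive_seed(seed, "promoters"))
    bases = np.array(list("ACGT"))
    promoters: Dict[str, str] = {}
    for gene in annotation:
        window_plus = "".join(bases[rng.integers(0, 4, promoter_len)])
        seq = promoter_from_genomic(window_plus, gene.strand)
        gid = gene.gene_id
        planted = None
        cls = truth.genes.loc[gid, "gene_class"]
        if cls == "restricted":
            planted = pwm_by_name[truth.genes.loc[gid, "responsible_tf"]]
        elif cls == "widespread" and truth.genes.loc[gid, "direction"] > 0:
            planted = pwm_by_name.get(ECR_NAME)
        if planted is not None:
            site = planted.consensus
            pos = int(rng.integers(0, promoter_len - planted.width + 1))
            seq = seq[:pos] + site + seq[pos + planted.width:]
        promoters[gid] = seq
    return promoters


def write_fasta(seqs: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB with var = mean + alpha * mean**2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    n = 1.0 / np.maximum(alpha[pos], 1e-12)
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    lines = config.line_names
    replicated = set(lines[:config.n_replicated_lines])
    tc = set(config.timecourse_lines or ())
    for line in lines:
        reps = 2 if line in replicated else 1
        for t in (0, 5):
            for r in range(1, reps + 1):
                rows.append((f"{line}_t{t}_r{r}", line, t, r))
        if line in tc:
            for t in (1, 3, 7):
                rows.append((f"{line}_t{t}_r1", line, t, 1))
    return pd.DataFrame(rows,
                        columns=["sample_id", "cell_line", "time_hr",
                                 "replicate"])


def simulate_counts(annotation: GeneAnnotation, states: LineStates,
                    truth: GroundTruth, config: SimulationConfig,
                    seed: Optional[int] = None):
    """Draw gene, exon, and receptor-isoform counts for every sample.

    Returns ``(gene_cm, exon_cm, isoform_counts, isoform_lengths, size_truth)``.
    """
    config.validate()
    rng = np.random.default_rng(
        derive_seed(config.seed if seed is None else seed, "counts"))
    a0, a1 = config.dispersion_trend
    samples = _sample_table(config)
    lines = states.lines
    gene_ids = annotation.gene_ids()
    n_genes = len(gene_ids)

    # basal means: constant per gene, except TF genes which track expression
    lo, hi = config.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    base_by_line = pd.DataFrame(
        np.tile(base[:, None], (1, len(lines))), index=gene_ids, columns=lines)
    tf_on_mean = {tf: float(np.exp(rng.uniform(np.log(2000), np.log(20000))))
                  for tf in states.tf_names}
    for tf in states.tf_names:
        on = states.expressed[tf].values
        if tf == ECR_NAME:
            base_by_line.loc[tf] = 8000.0 * states.ecr_titer.values
        else:
            mu_on = tf_on_mean[tf]
            base_by_line.loc[tf] = np.where(on, mu_on, mu_on / 30.0)
    if (base_by_line.values <= 0).any():
        raise ConfigError("negative or zero expression means")

    shape_lookup = {}
    if not truth.shapes.empty:
        shape_lookup = {(r.gene_id, r.cell_line): r.shape
                        for r in truth.shapes.itertuples()}

    slo, shi = config.library_size_range
    sf = np.exp(rng.uniform(np.log(slo), np.log(shi), len(samples)))
    size_truth = pd.Series(sf, index=samples["sample_id"].values,
                           name="library_size")

    lfc = truth.lfc
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    exon_tab = annotation.exon_table()
    exon_gene_idx = pd.Index(gene_ids).get_indexer(exon_tab["gene_id"])
    exon_w = (exon_tab["length"]
              / exon_tab.groupby("gene_id")["length"].transform("sum")).values
    switch_genes = set(truth.genes.index[truth.genes["tss_switch"]])
    exon_switch_mult = np.ones(len(exon_tab))
    if switch_genes:
        for gid in switch_genes:
            mask = (exon_tab["gene_id"] == gid) & exon_tab["is_first"]
            idx = np.flatnonzero(mask.values)
            if len(idx) >= 2:
                # upstream TSS induced 64x, downstream repressed 64x
                order = np.argsort(exon_tab["tss"].values[idx])
                if annotation[gid].strand == "-":
                    order = order[::-1]
                exon_switch_mult[idx[order[0]]] = 64.0
                exon_switch_mult[idx[order[-1]]] = 1.0 / 64.0
    exon_counts = np.zeros((len(exon_tab), len(samples)), dtype=np.int64)

    lfc_arr = lfc.loc[gene_ids].values  # genes x lines
    line_pos = {ln: i for i, ln in enumerate(lines)}
    for j, row in enumerate(samples.itertuples()):
        li = line_pos[row.cell_line]
        mult_frac = np.ones(n_genes)
        if row.time_hr > 0:
            frac = np.array([
                _SHAPE_MULT[shape_lookup.get((gid, row.cell_line),
                                             "monotone")][row.time_hr]
                if lfc_arr[i, li] != 0 else 0.0
                for i, gid in enumerate(gene_ids)]) \
                if row.cell_line in (config.timecourse_lines or ()) \
                else np.where(lfc_arr[:, li] != 0, 1.0, 0.0)
            mult_frac = np.exp2(lfc_arr[:, li] * frac)
        q = base_by_line[row.cell_line].values * mult_frac  # normalized mean
        alpha = a0 + a1 / np.maximum(q, 1e-9)
        counts[:, j] = _nb_draw(rng, sf[j] * q, alpha)

        q_e = q[exon_gene_idx] * exon_w
        if row.time_hr > 0:
            t_frac = _SHAPE_MULT["monotone"][row.time_hr]
            q_e = q_e * np.exp2(np.log2(exon_switch_mult) * t_frac)
        alpha_e = a0 + a1 / np.maximum(q_e, 1e-9)
        exon_counts[:, j] = _nb_draw(rng, sf[j] * q_e, alpha_e)

    gene_cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="feature_id"),
                     columns=samples["sample_id"].values),
        samples)
    exon_cm = CountMatrix(
        pd.DataFrame(exon_counts, index=exon_tab.index.rename("feature_id"),
                     columns=samples["sample_id"].values),
        samples)

    # receptor isoform-group counts at the basal time point, per line
    iso_lengths = pd.Series({"EcR-A": 5400.0, "EcR-B1/2": 4800.0},
                            name="length")
    titer = states.ecr_titer.values
    b12 = states.b12_fraction.values
    a_b = titer * b12
    a_a = titer * (1.0 - b12)
    iso = pd.DataFrame(
        {"EcR-A": rng.poisson(a_a * iso_lengths["EcR-A"] * 0.5),
         "EcR-B1/2": rng.poisson(a_b * iso_lengths["EcR-B1/2"] * 0.5)},
        index=pd.Index(lines, name="cell_line")).T
    return gene_cm, exon_cm, iso, iso_lengths, size_truth


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GeneAnnotation
    pwms: List[PWM]
    states: LineStates
    truth: GroundTruth
    promoters: Dict[str, str]
    counts: CountMatrix
    exon_counts: CountMatrix
    isoform_counts: pd.DataFrame
    isoform_lengths: pd.Series
    size_truth: pd.Series

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        p = lambda name: os.path.join(outdir, name)
        self.config.to_yaml(p("config.yaml"))
        self.annotation.to_gff3(p("annotation.gff3"))
        self.annotation.pairs.to_csv(p("gene_pairs.tsv"), sep="\t", index=False)
        write_fasta(self.promoters, p("promoters.fasta"))
        write_meme(self.pwms, p("motifs.meme"))
        self.counts.to_tsv(p("gene_counts.tsv"), p("samples.tsv"))
        self.exon_counts.to_tsv(p("exon_counts.tsv"))
        self.annotation.exon_table().to_csv(p("exons.tsv"), sep="\t")
        self.truth.genes.to_csv(p("truth_genes.tsv"), sep="\t")
        self.truth.lfc.rename_axis("gene_id").to_csv(p("truth_lfc.tsv"), sep="\t")
        self.truth.shapes.to_csv(p("truth_shapes.tsv"), sep="\t", index=False)
        self.states.to_frame().to_csv(p("line_states.tsv"), sep="\t")
        self.isoform_counts.rename_axis("isoform_group").to_csv(
            p("isoform_counts.tsv"), sep="\t")
        self.isoform_lengths.rename_axis("isoform_group").to_csv(
            p("isoform_lengths.tsv"), sep="\t")
        self.size_truth.rename_axis("sample_id").to_csv(
            p("library_sizes.tsv"), sep="\t")


def simulate_dataset(config: SimulationConfig,
                     seed: Optional[int] = None) -> SimulatedDataset:
    """Generate the full synthetic dataset for one configuration."""
    config.validate()
    seed = config.seed if seed is None else seed
    annotation = generate_annotation(config, seed)
    states = generate_line_states(config, seed)
    pwms = make_tf_pwms(config, seed)
    truth = assign_truth(config, annotation, states, seed)
    promoters = generate_promoters(annotation, pwms, truth, seed,
                                   config.promoter_len)
    gene_cm, exon_cm, iso, iso_len, size_truth = simulate_counts(
        annotation, states, truth, config, seed)
    return SimulatedDataset(config, annotation, pwms, states, truth,
                            promoters, gene_cm, exon_cm, iso, iso_len,
                            size_truth)
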