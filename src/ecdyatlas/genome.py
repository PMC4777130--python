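"""Gene annotation: transcripts, exons, TSSs, promoters, GFF3 round-trip.

Internal coordinates are 0-based half-open throughout; GFF3 files are read
and written in the native 1-based inclusive convention, so there is a single
conversion boundary at I/O time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import gffutils
import pandas as pd

__all__ = [
    "Transcript", "Gene", "GeneAnnotation", "AnnotationError",
    "load_annotation", "reverse_complement", "promoter_from_genomic",
]

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    pass


@dataclass
class Transcript:
    transcript_id: str
    #: exon intervals, 0-based half-open, sorted by start
    exons: List[Tuple[int, int]]
    strand: str

    def __post_init__(self):
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty exon {(a, b)}")
        for (_, b), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based coordinate of the transcript 5' end, strand-aware."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def first_exon(self) -> Tuple[int, int]:
        return self.exons[0] if self.strand == "+" else self.exons[-1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: List[Transcript]

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', "
                f"got {self.strand!r}")
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def gene_length(self) -> float:
        """Mean of the transcript lengths (used for length normalization)."""
        return sum(t.length for t in self.transcripts) / len(self.transcripts)

    @property
    def tsss(self) -> List[int]:
        return sorted({t.tss for t in self.transcripts})

    @property
    def primary_tss(self) -> int:
        """Most upstream TSS with respect to the direction of transcription."""
        return min(self.tsss) if self.strand == "+" else max(self.tsss)

    def promoter_interval(self, length: int = 500,
                          tss: Optional[int] = None) -> Tuple[int, int]:
        """0-based half-open genomic interval of `length` bp upstream of a TSS."""
        t = self.primary_tss if tss is None else tss
        if self.strand == "+":
            return (max(0, t - length), t)
        return (t + 1, t + 1 + length)


def promoter_from_genomic(window_plus: str, strand: str) -> str:
    """Orient a promoter's plus-strand genomic sequence along transcription.

    Two genes sharing an upstream genomic window but transcribed from
    opposite strands therefore get reverse-complementary promoters.
    """
    return window_plus if strand == "+" else reverse_complement(window_plus)


class GeneAnnotation:
    """Container for genes plus optional gene-pair metadata."""

    def __init__(self, genes: Iterable[Gene],
                 chrom_sizes: Optional[Dict[str, int]] = None,
                 pairs: Optional[pd.DataFrame] = None):
        self.genes: Dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.chrom_sizes = dict(chrom_sizes or {})
        for g in self.genes.values():
            need = g.end
            if self.chrom_sizes.get(g.chrom, 0) < need:
                self.chrom_sizes[g.chrom] = need
        #: columns: pair_id, pair_type in {tandem, divergent}, gene_a, gene_b
        self.pairs = pairs if pairs is not None else pd.DataFrame(
            columns=["pair_id", "pair_type", "gene_a", "gene_b"])

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def gene_ids(self) -> List[str]:
        return list(self.genes)

    def require_nonempty(self) -> None:
        if not self.genes:
            raise AnnotationError("no genes in annotation")

    # -- tables -----------------------------------------------------------
    def gene_table(self) -> pd.DataFrame:
        rows = []
        for g in self:
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "start": g.start, "end": g.end,
                "primary_tss": g.primary_tss, "n_tss": len(g.tsss),
                "gene_length": g.gene_length,
            })
        return pd.DataFrame(rows).set_index("gene_id")

    def exon_table(self) -> pd.DataFrame:
        """Flattened exon table with first-exon/TSS labels for exon-level DE.

        Exons shared between transcripts collapse to one feature; an exon is
        `first` if it is the 5'-most exon of at least one transcript, and its
        `tss` column then records that transcript's TSS.
        """
        rows: Dict[Tuple[str, int, int], dict] = {}
        for g in self:
            for t in g.transcripts:
                for (a, b) in t.exons:
                    key = (g.gene_id, a, b)
                    rec = rows.setdefault(key, {
                        "gene_id": g.gene_id, "chrom": g.chrom,
                        "strand": g.strand, "start": a, "end": b,
                        "length": b - a, "is_first": False, "tss": -1,
                    })
                    if (a, b) == t.first_exon:
                        rec["is_first"] = True
                        rec["tss"] = t.tss
        df = pd.DataFrame(rows.values())
        if df.empty:
            return df
        df = df.sort_values(["gene_id", "start", "end"]).reset_index(drop=True)
        ordinal = df.groupby("gene_id").cumcount() + 1
        df.insert(0, "exon_id", df["gene_id"] + ":E" + ordinal.astype(str).str.zfill(2))
        return df.set_index("exon_id")

    # -- GFF3 -------------------------------------------------------------
    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, size in sorted(self.chrom_sizes.items()):
                fh.write(f"##sequence-region {chrom} 1 {size}\n")
            for g in self:
                fh.write("\t".join([
                    g.chrom, "ecdyatlas", "gene", str(g.start + 1), str(g.end),
                    ".", g.strand, ".", f"ID={g.gene_id}"]) + "\n")
                for t in g.transcripts:
                    fh.write("\t".join([
                        g.chrom, "ecdyatlas", "mRNA",
                        str(t.start + 1), str(t.end), ".", g.strand, ".",
                        f"ID={t.transcript_id};Parent={g.gene_id}"]) + "\n")
                    for (a, b) in t.exons:
                        fh.write("\t".join([
                            g.chrom, "ecdyatlas", "exon",
                            str(a + 1), str(b), ".", g.strand, ".",
                            f"ID={t.transcript_id}:exon:{a + 1};"
                            f"Parent={t.transcript_id}"]) + "\n")


def load_annotation(gff3_path) -> GeneAnnotation:
    """Read a GFF3 file with gene/mRNA/exon features into a GeneAnnotation.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Orphan exons (no Parent) and genes with unknown strand are rejected.
    """
    with open(gff3_path) as fh:
        text = fh.read()
    chrom_sizes: Dict[str, int] = {}
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                chrom_sizes[parts[1]] = int(parts[3])
    if not any(ln.strip() and not ln.startswith("#") for ln in text.splitlines()):
        return GeneAnnotation([], chrom_sizes=chrom_sizes)

    db = gffutils.create_db(
        text, ":memory:", from_string=True, merge_strategy="create_unique",
        keep_order=True)

    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) >= 9 and cols[2] == "exon" and "Parent=" not in cols[8]:
            raise AnnotationError(
                f"orphan exon without Parent at line {lineno}: {line[:80]}")

    genes: List[Gene] = []
    for gf in db.features_of_type("gene"):
        if gf.strand not in "+-":
            raise AnnotationError(
                f"gene {gf.id}: unknown strand {gf.strand!r} rejected")
        transcripts = []
        for tf in db.children(gf, featuretype=("mRNA", "transcript"), level=1):
            exons = [(ef.start - 1, ef.end)
                     for ef in db.children(tf, featuretype="exon", level=1)]
            if not exons:
                raise AnnotationError(f"transcript {tf.id}: no exons")
            transcripts.append(Transcript(tf.id, exons, gf.strand))
        if not transcripts:
            raise AnnotationError(f"gene {gf.id}: no transcripts")
        genes.append(Gene(gf.id, gf.seqid, gf.strand, transcripts))
    return GeneAnnotation(genes, chrom_sizes=chrom_sizes)
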