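# ecdyatlas

Tools for building and analyzing a catalog of early steroid-hormone
transcriptional responses across a large panel of *Drosophila* cell lines.
The biological setting: dozens of independently derived cell lines are
exposed to 20-hydroxyecdysone (ecdysone) for 5 hr and profiled by bulk
RNA-seq before and after exposure. A small cohort of genes responds in
nearly every line ("widespread" responders, the core hormone response
unit), while the vast majority respond in only one or a few lines
("restricted" responders) conditional on the initial cell state — which
transcription factors (TFs) are expressed, how much receptor (EcR) the
line carries, and which receptor isoform dominates.

The package is aimed at computational biologists who want a tested,
reusable implementation of this catalog-building analysis, exercised
end-to-end on synthetic data with planted ground truth.

## What it computes

- **Synthetic atlas generator** (`ecdyatlas.simulate`) — gene annotation
  (GFF3) with tandem and divergent gene pairs and multiple TSSs, promoter
  sequences with planted TF binding sites, per-line TF expression states
  and receptor titers, and negative-binomial count matrices
  (var = μ + αμ², α(μ) = a0 + a1/μ) with planted widespread, restricted,
  weak, and bidirectional responses, promoter-switching exon events, and a
  5-point (0/1/3/5/7 hr) time course for a subset of lines.
- **Differential expression** (`ecdyatlas.diffexpr`) — median-of-ratios
  size factors; gene-wise dispersions estimated from the replicated lines
  only and shared across all lines through a fitted a0 + a1/μ trend; a
  per-line Wald test of the 5 hr vs 0 hr contrast under the NB variance;
  BH adjustment within each line; a reduced exon-level usage test pooled
  across lines that flags promoter-switching candidates.
- **Response catalog** (`ecdyatlas.catalog`) — Fisher's method applied to
  within-line ranks (wrong-direction genes tied at the bottom), two-tier
  per-line calls (two-fold change gate plus either adjusted p < 0.01 or
  raw p < 0.01 rescued by a same-direction Fisher p < 1e-8), breadth
  classes (widespread = called in more than half the lines), weak and
  bidirectional flags, per-line Responsive Gene Counts (RGC), Jaccard
  similarity clustering of the restricted response, and hypergeometric GO
  term enrichment.
- **Rate-limiting-factor scans** (`ecdyatlas.association`) — per-gene
  Pearson correlation of log basal expression with the RGC across lines,
  OLS residualization on a conditioning gene, and a scan of the
  length-normalized EcR-B1/2 isoform fraction against per-gene fold
  changes.
- **Positional analysis** (`ecdyatlas.positional`) — ecdysone-relevant TSS
  selection, neighbor records within 20 kb classified by promoter
  architecture, trimmed directional scores (signed −log10 p clamped to
  ±10), 100-combination bins with LOESS smoothing, proximity enrichment of
  weak responders near induced genes, and PWM-based motif enrichment.
- **Restricted-response prediction** (`ecdyatlas.prediction`) — per-TF
  motif score thresholds calibrated to just under a 5% hit rate on
  nonresponsive promoters, matched positive/negative line sets per
  restricted gene, motif-masked TF expression features plus a gene
  expression rank, leave-one-cell-line-out random-forest evaluation, and
  subsampled learning curves extrapolated with an a − b/n asymptote.
- **Time-course shapes** (`ecdyatlas.timecourse`) — median-of-ratios
  normalization, per-(gene, line) mean centering across the five time
  points, division by a LOESS-fitted SD-vs-mean trend, and trajectory
  classification (early-peak / late-rise / other).

## Worked example

Run the whole pipeline on the default synthetic atlas (41 lines, 3000
genes, 4 duplicated lines, 3 time-course lines; takes a few minutes):

```python
import json
import pandas as pd
from ecdyatlas.config import SimulationConfig
from ecdyatlas.pipeline import run_pipeline

ws = run_pipeline(SimulationConfig(seed=1), "atlas_run")
cat = json.load(open("atlas_run/catalog_summary.json"))
print("responsive genes:", cat["n_responsive_genes"])
print("widespread induced/repressed:", cat["n_widespread_induced"], "/",
      cat["n_widespread_repressed"])
print("weak induced/repressed:", cat["n_weak_induced"], "/",
      cat["n_weak_repressed"])
scan = pd.read_csv("atlas_run/rgc_scan.tsv", sep="\t", index_col=0)
print("top RGC correlate:", scan.index[0], "r = %.2f" % scan.iloc[0]["r"])
pred = json.load(open("atlas_run/prediction_summary.json"))
print("LOCO accuracy (induction): %.2f" % pred["induction"]["accuracy"])
```

which prints:

```
responsive genes: 466
widespread induced/repressed: 84 / 38
weak induced/repressed: 35 / 52
top RGC correlate: EcR r = 0.82
LOCO accuracy (induction): 0.87
```

Reading the output: 466 of 3000 genes are called responsive in at least
one line; 84 genes are induced (38 repressed) in more than half of the 41
lines; 87 genes show a reproducible sub-twofold trend detected only by
cross-line aggregation; the receptor gene EcR is the strongest correlate
of per-line global responsiveness (it is the planted rate-limiting
factor); and held-out cell lines' restricted induction calls are predicted
with 87% accuracy from motif-masked TF expression (chance is exactly 50%
by the matched-set construction).

The same stages are available from the shell:

```bash
ecdyatlas simulate -o atlas_run --seed 1
ecdyatlas de -o atlas_run
ecdyatlas catalog -o atlas_run
ecdyatlas associate -o atlas_run
ecdyatlas positional -o atlas_run
ecdyatlas predict -o atlas_run
ecdyatlas timecourse -o atlas_run
# or all at once:
ecdyatlas all -o atlas_run --seed 1
```

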