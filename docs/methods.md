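# Methods

This note documents the statistical model behind each stage, the
assumptions of the synthetic-data generator, the numerical choices, and
the design decisions made where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The generative model

The generator emulates a hormone-exposure atlas: `n_lines` cell lines
sampled at 0 and 5 hr (a fraction with biological duplicates, three lines
with a 0/1/3/5/7 hr course), `n_genes` genes on three chromosomes, and
read counts

    K_gs ~ NB(mean = s_s * mu_gs,  var = mean + alpha * mean^2),
    alpha(mu) = a0 + a1 / mu,

the DESeq-style parameterization, with per-sample library factors `s_s`
drawn log-uniformly over a four-fold range. Basal means are log-uniform
over `baseline_mean_range`. Defaults `baseline_mean_range = (1000, 30000)`
and `dispersion_trend = (0.005, 1.0)` describe a deeply sequenced study
(tens to hundreds of millions of reads per line) with a ~7% asymptotic
coefficient of variation between biological duplicates of clonal lines —
the regime in which consistent sub-twofold responses are resolvable by
cross-line aggregation while never crossing the two-fold per-line gate.

Planted response classes:

- **widespread** — log2FC of ±`effect_log2fc` (default 2) in every line;
  roughly two-thirds induced. A subset is *isoform-coupled*: its log2FC is
  a linear function of the line's EcR-B1/2 fraction.
- **restricted** — a gene responds in a line iff (i) its responsible TF is
  expressed there, (ii) the line's receptor titer exceeds the gene's
  uniform threshold U_g, and (iii) the gene's promoter carries the TF's
  consensus site (planted by construction). The threshold construction
  gives a Bernoulli(titer) firing margin while making the planted firing
  count *exactly* nondecreasing in titer across lines. Responsible TFs
  are assigned in a balanced round-robin, so the response is conditional
  on many TFs none of which dominates. A few restricted genes flip
  direction at random per line (bidirectional).
- **weak** — ±log2(1.5) in `weak_line_fraction` (default 80%) of lines.
- **null** — no effect; divergent-pair partners are drawn from this class,
  so head-to-head neighbors are *not* co-regulated, while tandem
  (same-strand consecutive) pairs are built from co-induced widespread
  genes. This encodes the contrast the positional analysis measures.

Promoters are 500 bp of i.i.d. uniform ACGT upstream of the primary TSS,
oriented along transcription (minus-strand genes are reverse complements
of the plus-strand window), which makes motif hit rates analytically
checkable (an exact 8-mer match occurs in ~2·493·4⁻⁸ ≈ 1.5% of null
promoters). The receptor's motif is the canonical response-element
inverted repeat AGGTCA/TGACCT, planted in widespread induced promoters.
Divergent pairs closer than 500 bp would share promoter sequence in a real
genome; the generator draws their windows independently — a simplification
that does not affect any downstream statistic, since all promoter analyses
treat promoters as independent sequences.

What the generator does **not** emulate: GC/mappability bias, repeats,
isoform-level read assignment (receptor isoform-group counts are emitted
directly), correlated basal expression programs across lines, and batch
structure. Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to those
real-data artifacts.

## Differential expression

Size factors are median-of-ratios: the per-gene reference is the
geometric mean over samples (genes with any zero excluded) and each
sample's factor is its median count/reference ratio, not renormalized
afterward.

Dispersions are estimated only from replicated (line, time) groups by a
pooled method of moments on normalized counts,
`alpha_hat = sum_k w_k (s²_k − mu_k·E[1/s]) / sum_k w_k mu_k²`, and a
trend `alpha(mu) = a0 + a1/mu` is fitted by least squares across genes.
Two numerical choices matter:

- the trend regression uses the *untruncated* (signed) moment estimates.
  With few replicate groups the estimator's noise is of the order of
  alpha itself, so conditioning on positive estimates truncation-inflates
  a0 by tens of percent and visibly deflates the null p-value rate;
  the signed estimates are mean-unbiased. Per-gene raw estimates are
  reported clipped at zero.
- the dispersion used for testing is the trend value (`sharing="trend"`).
  Taking the per-gene maximum of raw and trend (`sharing="maximum"`,
  available as an option) is deliberately conservative and shifts the
  per-line p < 0.05 rate from ~0.05 to ~0.02–0.03 when only one line is
  replicated; the trend, fitted across thousands of genes, preserves
  calibration while still borrowing strength only from replicated lines.

The per-line test is a Wald z on the difference of normalized condition
means under the NB variance at the pooled mean,
`V_j = mu·sum(1/s_i)/n_j² + alpha·mu²/n_j`, two-sided normal reference,
BH across genes within the line. The log2 fold change uses a pseudocount
of 0.5 on the normalized scale for reporting only. Keeping the per-read
(shot-noise) term in V means p-values are not exactly invariant to
scaling one library's counts (they agree to within the shot-noise share,
~1/(alpha·mu)); dropping the term would restore exact invariance at the
cost of an ~8% anti-conservative inflation of |z| at these depths, so it
stays.

The exon-level analysis is a reduced surrogate for a full exon-usage GLM:
per exon, Δ = mean over lines of (exon log2FC − gene log2FC), a
delta-method SE treating exon and gene means as independent (conservative,
since their sampling covariance is positive), BH across exons, and a
significance rule of adjusted p < 0.01 together with a ≥50-fold usage
change. Genes with significant induced and repressed first exons of
distinct TSSs are promoter-switching candidates.

## Response catalog

For each direction, genes are ranked within each line by p-value after
setting wrong-direction genes to p = 1; u = rank/(N+1) and
X = −2 Σ ln u is referred to chi-square with 2k degrees of freedom. Tied
genes (the wrong-direction block) are placed at random, seeded,
deterministic ranks within their tied block: each line's u scores are then
an exact permutation of {1..N}/(N+1), i.e. exactly uniform marginally,
which is the premise of the combination. Mid-ranks (available as
`tie_method="average"`) concentrate the block at a single point and
deflate E[X] by ~1%, enough to fail a KS uniformity check at 5000 genes.

Per-line calls require |log2FC| ≥ 1 (the two-fold biological relevance
gate) and either adjusted p < 0.01, or raw p < 0.01 together with a
*same-direction* Fisher p < 1e-8. Widespread means called in strictly
more than half the lines (per direction); weak means Fisher p < 1e-8 with
zero per-line calls in that direction; bidirectional means at least one
induced and one repressed call. A consequence of rank-based aggregation
worth knowing: u ≥ (number of stronger responders)/(N+1) regardless of
p-value, so weak trends can only cross 1e-8 when the panel is large
relative to the strongly responsive cohort — with ~200 strong responders
among 3000 genes this needs ~30+ lines, which the 41-line design
provides.

Jaccard similarity of per-line restricted response sets (induced,
repressed, and their union) is clustered by average linkage (UPGMA) on
1 − J; J of two empty sets is defined as 0. Linkage choice and the use of
the combined set are conventions, as is flat-set (no graph propagation)
hypergeometric GO enrichment restricted to annotated genes.

## Association scans

Pearson correlation of log2(normalized basal expression + 1) with the
per-line responsive gene count, per gene, with a t reference at n−2 df
and BH FDR; genes basally expressed (normalized count ≥ 1) in fewer than
three lines, or constant across lines, are excluded. The correlation
flavor and transform are conventions; the log stabilizes the NB
mean–variance scaling. Residualization regresses the count vector on the
conditioning gene's log expression by OLS and re-runs the scan on the
residuals. The isoform fraction is
f_B = (c_B/L_B)/(c_A/L_A + c_B/L_B) from isoform-group counts and
lengths; lines with zero counts in both groups are excluded.

## Positional analysis

All distances are TSS-to-TSS; gene-body overlap is ignored. The
ecdysone-relevant TSS is the one whose first exon carries a significant
exon-level event, else the most expressed first exon (5 hr expression for
induced genes, 0 hr for repressed, the average otherwise). Neighbor
records within 20 kb carry the neighbor's responsive flag and trimmed
directional score sign(log2FC)·(−log10 p) clamped to ±10 (p = 0 maps to
the clamp). Records are grouped by orientation × focal direction, sorted
by distance, and aggregated in disjoint consecutive bins of 100
gene–line combinations (the last bin may be smaller); bin summaries are
smoothed by locally linear LOESS (tricube weights, span 0.5, a documented
default). Disjoint rather than sliding bins keep bin summaries
independent. The 10–20 kb responsive fraction is reported as background.

Proximity enrichment compares the fraction of weak genes with an induced
gene's TSS within 2.5 kb against the same fraction over all non-weak
genes, with an upper-tail binomial p. Motif enrichment calls a promoter a
hit when any window on either strand reaches the calibrated score
threshold and compares foreground and background hit rates with a
hypergeometric tail.

## Prediction

PWM scoring is the log2-odds sum against a uniform background, both
strands; the per-TF threshold is the smallest candidate cutoff (among
observed per-promoter best scores) whose hit rate on nonresponsive
promoters is just below 5%. For each restricted gene the positive lines
are its calls and the negatives are an equal number of the most
oppositely-responding lines by log2FC, so chance accuracy is exactly 0.5.
Features: per-TF log2 normalized expression masked to zero unless the
gene's promoter has a hit for that TF's motif, plus the gene's basal
expression rank in the line scaled to [0, 1]. TFs are eligible when some
line expresses them above the 20th percentile of detected genes. The
classifier is a random forest (500 trees, sqrt(p) split candidates, no
depth limit, impurity importances — conventional defaults), evaluated by
leaving out entire cell lines and averaging held-out accuracy. Learning
curves resample line subsets, rebuild restricted/matched sets from the
subset alone, and re-run the leave-one-line-out loop; the mean accuracies
are fitted with a − b/n (the simplest monotone form with a finite limit)
and `a` is reported with a bootstrap percentile interval.

## Time-course shapes

Counts from lines with the full 0/1/3/5/7 hr course are size-factor
normalized, replicates averaged within (line, time), mean-centered per
(gene, line), and divided by a fitted SD: a locally linear LOESS of the
per-combination SD on the per-combination mean (span 0.75) over all
gene–line combinations, floored at 1e-6 (combinations at the floor are
excluded). The SD trend is a function of mean expression only, not of
line. Units are SDs from the mean across time. Trajectory classes used
for planted-shape verification: early-peak (maximum at 1 hr, strictly
decreasing after), late-rise (maximum at 7 hr), other.

## Verification experiment sizes

The experiments in `ecdyatlas.experiments` (used by the acceptance tests
and `scripts/acceptance.py`) run at sizes chosen so each completes in
seconds to a few minutes on one CPU with the measured quantity well away
from its decision boundary: null calibration at 5000 genes × 10 lines;
widespread/specificity at 5000 genes × 20 lines with 50 + 500 planted
responders; weak power as 100 planted genes across 20 simulations of
1000 genes (planting few weak genes per simulation avoids rank crowding
between them); the rate-limiting analysis at 350 genes × 200 lines —
deliberately more lines than the emulated 41-line study, because a
genome-wide maximum-|r| check is only meaningful when the null maximum
correlation (~3.3/sqrt(n−3)) sits well below the reporting threshold;
the positional contrast at 2000 genes × 20 lines with 40 tandem and 40
divergent pairs; prediction at 2000 genes × 20 lines with 5 responsible
TFs among 20, learning curves over n ∈ {5,7,9,11,14,18} with 10
resamples; the time course at 900 genes × 2 course lines.

## Known limitations

- The per-line test's normal reference degrades below ~50 counts; the
  generator never operates there, but real shallow data would warrant an
  exact or likelihood-ratio NB test.
- The exon-usage surrogate tests one pooled shift, not per-line
  interaction terms, and its SE ignores the exon–gene covariance
  (conservative).
- Rank-based Fisher aggregation loses power for weak trends when the
  strongly responsive cohort is large relative to the gene universe (see
  above); this is intrinsic to rank combination, not an implementation
  artifact.
- Isoform fractions are taken from isoform-group counts as provided;
  no isoform deconvolution from exon overlaps is attempted.
- The learning-curve asymptote model a − b/n is a convenience
  extrapolation; an exponential saturation is equally defensible and
  would give slightly different asymptotes.
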