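# Methods

This note documents the statistical models behind `heteromics`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Study design

Three genotypes are compared: the female parent (F), the male parent (M) and
their F1 hybrid (H), each with three biological replicates. The mid-parent
value (MPV) is the additive expectation: for expression it is built as
paired pseudo-replicates MPV_i = (F_i + M_i)/2 on the normalized scale, so
the hybrid-vs-MPV contrast retains a replicate-level variance estimate; for
methylation windows it is the rounded element-wise half-sum of parental
(methylated, total) counts, which keeps the count-based Fisher machinery
applicable; for phenotypes it is the plain mid-parent mean.

## Expression testing

Counts are normalized by median-of-ratios size factors (per-gene geometric
mean reference over genes nonzero in all samples). The differential test is
a two-sample t on log2(x + 1). The pooled-variance (Student) form is the
default engine: with three replicates per group, the Welch form loses
Satterthwaite degrees of freedom and becomes conservative (empirical type-I
around 0.035-0.04 at the nominal 0.05 under the package's own null
simulations), while the pooled form with equal group sizes is calibrated and
robust to the modest variance reduction of the MPV pseudo-replicates. Welch
remains available (`engine="welch"`), and the engine argument is the hook
for substituting e.g. a negative-binomial exact test.

Significance gates (configurable):

| use              | \|log2FC\| | p     | BH q  |
|------------------|-----------|-------|-------|
| mRNA DEGs        | >= 2      | 0.01  | 0.01  |
| miRNA            | >= 1      | 0.01  | 0.05  |
| ELD relations    | >= 1      | 0.05  | (none)|
| siRNA clusters   | >= log2(1.5) | (none) | 0.05 |

The ELD equality gate is deliberately looser than the DEG gate: a 4-fold
equality band would over-call "equal". Relation p-values are per-pair
decisions, not a discovery set, so no FDR is applied there.

A structural consequence of the gates worth knowing: under exact
arithmetic-midpoint additivity the hybrid/parent and hybrid/MPV ratios are
bounded by 2, so a gene planted exactly at the midpoint between 8-fold
separated parents classifies as high-parent dominance under the 2-fold
equality band, and no ELD-shaped gene can pass the 4-fold MPV gate. The
generator therefore records, next to the planted scenario, the *expected*
label obtained by applying the same gates to the noise-free planted means;
recovery is always scored against that expected label. MPV-DEG recall is
measured on genes planted beyond the fold-change gate (the transgressive
classes, hybrid at 8x the extreme parent by default — the planted
transgressive condition is "at least 4x", and exactly 4x would sit exactly
on the gate).

## Cis/trans allele tests

PA tests homogeneity of the parental allelic ratio F:M against the hybrid's
HF:HM on the 2x2 table (Pearson chi-square, df=1, no continuity correction;
Fisher exact when any expected cell < 5). PB tests HF:HM against 1:1 (df=1
goodness of fit; exact binomial when HF+HM < 25). Omitting the continuity
correction keeps the nominal alpha calibration testable; the exact fallbacks
guard the small-count regime. No multiple-testing correction is applied to
PA/PB, and alpha is fixed at 0.05; counts are summed over a gene's SNPs
before testing. The filter removes genes with minimum FPKM < 2 across
genotypes or fewer than 20 allelic reads in either generation (the 20-read
floor operationalizes "low SNP coverage").

## Methylome

Site calling is a one-sided exact binomial test of the methylated count
against the residual non-conversion rate (default 0.006, the error level of
a > 99%-efficient bisulfite conversion), BH-corrected per context, called at
q <= 0.01 with coverage >= 4.

DMRs: non-overlapping 100-bp windows, minimum covered cytosines 4 (CG), 4
(CHG), 6 (CHH) and >= 10 reads per genotype; Fisher's exact test on pooled
window counts, BH per context, q <= 0.05 plus a context minimum difference
of 0.4 / 0.2 / 0.1 for CG / CHG / CHH; adjacent same-direction windows
within 200 bp are merged. Hybrid windows are tested against the MPV counts;
q <= 0.01 marks an interactive window, split into TCM (hybrid above MPV) and
TCdM (below). The window size, minima and deltas are standard sliding-window
bisulfite practice and all configurable.

The eight parental patterns are the 2^3 methylated/unmethylated states of
(F, M, H) from the site caller, with (0,0,1) as de novo methylation;
(0,0,0) is excluded from "of total methylated" summaries. Promoters are 2 kb
upstream of the TSS, strand-aware. Metaplots use 20 relative body bins and
30 absolute flank bins; the coverage-weighted mean over all bins equals the
regional level exactly because each site lands in exactly one bin.

The two-sided Fisher p-value is computed by a vectorizable log-gamma
hypergeometric enumeration (sum of outcomes no more probable than the
observed table, with the usual 1e-7 relative tolerance); the test suite
checks it against scipy's implementation and an exact-fraction enumeration
to 1e-9.

## siRNA clusters

Discovery pools all samples and sweeps reads sorted by start: a new cluster
opens when a read start exceeds the running cluster end by more than
max_gap = 100 bp; clusters need >= 10 pooled reads and >= 50 bp span.
Quantification re-tallies per sample against the final intervals so all
genotypes share one coordinate set. Defaults were chosen so the emitted span
distribution falls in the 100-1000 nt range with a 150-250 nt mode on the
default simulations. Annotation precedence is TE > gene body > flank >
intergenic, requiring >= 50% of the cluster length (flank default 2 kb; the
1-kb convention is a config change away).

Cluster abundance is reads per million aligned 24-nt reads (RPM). RPM is a
relative measure: when a fixed total is redistributed, every null feature
shifts by the compositional factor. The generator accounts for this by
recording, next to the planted absolute hybrid ratio, the
composition-adjusted ratio (`ratio_H_rpm`) and deriving the expected
up/down/ns label from it; defaults (20% nonadditive clusters, 3-fold planted
shift, 70% of shifts upward) keep adjusted null ratios inside the 1.5-fold
gate.

## Integration

TCM/TCdM-cluster association is >= 1 bp containment, reported per context.
The siRNA-presence methylation contrast uses a label permutation over
100-bp windows (default 1000 permutations, seeded, one-sided with the
add-one p estimate) rather than a t test because region sizes are strongly
unbalanced. The hybrid methylation increase is the positive part
max(0, level_H − (level_F + level_M)/2) summed per (parental state x siRNA
presence) cell; parental states come from the same binomial site caller
("F = M" means the same called state, not identical levels), so the cells
partition the total exactly.

Heterosis metrics follow the field's formulas: MPH% = (F1 − MP)/MP x 100 and
BPH = (F1 − BP)/BP, the better parent being the max (or min for
lower-is-better traits). BPH is reported as a ratio, not a percentage,
matching the convention of its source formula.

## The synthetic-data generator

All draws come from named substreams of a single seed (annotation, counts,
alleles, methylome, siRNA), so identical seed + config give byte-identical
outputs and adding a simulator never perturbs the others.

What it emulates: a two-chromosome (An + Dn) ~1 Mb-per-chromosome toy genome
with 1:1 homoeolog pairs, 3-exon gene models and TEs of five classes (DNA,
LTR-copia, LTR-gypsy, LINE, SINE) in intergenic space; negative-binomial
counts (dispersion 0.1, lognormal baseline means) over planted
additive/ELD/transgressive/null classes with an 8-fold ELD effect (log2FC 3,
comfortably past the 2-fold gates so classifier error is separated from
effect-size marginality); binomial allele splits at Poisson read depth with
planted cis ratios (default 3-5) and trans architectures; beta-binomial
cytosine reports with context baselines CG 0.60 > CHG 0.35 > CHH 0.10,
site propensities shared across genotypes, Poisson(20) coverage, elevated TE
bodies, planted DMR windows (deltas 0.5/0.3/0.2 with the shift direction
chosen to keep the level inside (0,1) — shifting CG 0.60 upward by 0.5 would
clamp below the 0.4 call threshold) and planted loci for all eight parental
states; and clustered 24-nt reads (75% on TEs, lognormal spans clipped to
100-1000 nt, 0.2 reads/bp/sample, background sparse enough that its pooled
spacing far exceeds the clustering gap).

What it does not emulate: sequencing error and bisulfite conversion failure
beyond the flat error rate; mappability, GC or coverage biases; linked SNP
structure (allele counts are pre-aggregated per gene); chromatin context or
realistic TE nesting; inter-replicate batch effects. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under its
stated noise models, not robustness to the full messiness of real
sequencing data.

Problem sizes are chosen for single-CPU friendliness: the default genome is
2 x 1 Mb (~560k cytosines per genotype), 200 genes, 240 TEs, 120 clusters;
calibration runs use 2000 genes/records. All sizes scale through `SimConfig`.

## Numerical conventions and degenerate inputs

Internal coordinates are 0-based half-open everywhere; GFF3 and CX positions
are converted at the I/O boundary and converted back exactly on write.
Zero-variance equal groups give p = 1 (not NaN); degenerate chi-square
margins and empty hybrids give p = 1 with the warning path; windows with
all-zero totals are excluded; the divergence-change stabilizer c = 0.25
keeps the ratio defined for perfectly balanced pairs; quartile ties break by
gene id; BH caps at 1 and preserves input order. Float output uses a fixed
%.6g format so fixed seeds give byte-identical files.

## Known limitations

- The DE engine is a t test on transformed counts, not a count model; there
  is no dispersion moderation across genes (deliberately out of scope).
- PA treats the parental F:M ratio as estimated from allelic read counts;
  if parent-level expression were used instead, the test's calibration would
  change with library-size imbalance.
- CHG/CHH DMR calling at the lower delta gates picks up occasional
  overdispersion-driven windows; the CG gate (0.4) is effectively immune.
  A beta-binomial window test would tighten this at the cost of calibration
  transparency.
- The permutation test assumes exchangeable windows under the null; strong
  spatial autocorrelation of methylation would make it liberal.
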