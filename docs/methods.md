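# Methods

## Scope and model overview

The package implements the quantitative core of a splicing–metabolism
integration analysis: intron-retention quantification and differential
testing, retained-intron sequence characterization, metabolite pathway
differential-abundance scoring, single-cell spliceosome-activity
classification, and cohort-level expression distance analysis. Each stage
is a pure function over standard containers (pandas frames, plain
sequence strings); the pipeline module only sequences them and handles
file formats.

## Intron retention

PSI for a retained intron is estimated as ir / (ir + sj) from retention
and spliced-junction read counts. No intron-length normalization is
applied by default: the bundled generator produces both count classes on
the same scale, and for real data length-aware estimation is a documented
extension point rather than the default. When both counts are zero the
estimate is missing (NaN), never 0 — absence of evidence is not evidence
of splicing.

Differential retention pools counts within each condition group and
applies a two-sided Fisher exact test to the 2×2 table
[(ir_A, sj_A), (ir_B, sj_B)], BH-adjusted across all tested events. The
pooled exact test was chosen because it is oracle-verifiable by direct
hypergeometric enumeration and well calibrated at the 3-vs-3 design the
generator emulates; a replicate-aware model (e.g. beta-binomial) is a
plug-in alternative, not the default. Significance requires FDR < 0.05
and |ΔPSI| > 0.02; the ΔPSI gate is applied two-sided since retention can
move in either direction, with ΔPSI = PSI(group B) − PSI(group A).

The qPCR route uses PSI = 2^(CT(All) − CT(In)). Measurement noise can push
estimates above 1; such values are returned as computed and flagged rather
than clipped, so downstream summaries can decide how to treat them. A true
PSI of 0 has no finite CT(In) and is rejected by the simulator; callers
must adopt a detection-limit convention.

Coding consequences of a retained intron use a deliberate synthetic
convention: translation starts at transcript nucleotide 1 (real ORF
annotation is out of scope). Frameshift is decided solely by intron length
mod 3; the premature-stop scan finds the first in-frame stop codon at or
after the intron's transcript position, and the truncation flag compares
that stop against where the normally spliced transcript's first stop maps
in retained coordinates (strictly upstream → truncating).

## Splice-site model

The scorer is a position-weight-matrix log2-odds model over the standard
donor window (3 exonic + 6 intronic nt) and acceptor window (20 intronic +
3 exonic nt). Background defaults to uniform 0.25 per base and the build
pseudocount to 0.5, giving finite weights for unobserved bases and
symmetric smoothing. Windows are extracted strand-aware: minus-strand
sites are reverse-complemented into transcript orientation before scoring.
The model family is a design decision: the downstream retained- vs
non-retained comparison is a rank test, which consumes any monotone
strength score, so a trained maximum-entropy scorer can be substituted
through the same `score(sequence)` interface without changing conclusions.
The bundled consensus models are PWMs built from the consensus donor
CAGGTAAGT and a polypyrimidine-tract acceptor; under them the consensus
sequence is the unique score maximum (verified by enumeration on a toy
window in the tests).

The GC ratio trims 20 nt from each intron end and 3 nt from each exon end
(removing the splice-site signals themselves) and divides intron-core GC
content by the mean of the two flanking exon cores. Empty cores after
trimming yield a missing value with a logged reason, which is why the
generator enforces a 70-nt minimum intron length.

The NRI (non-retained intron) comparison set is defined as all introns of
genes harboring at least one significant retained intron, minus the
retained introns themselves, so RI and NRI share gene-level covariates.
Rank comparisons use the exact Mann–Whitney null when both groups have at
most 10 tie-free observations, otherwise the tie-corrected normal
approximation with continuity correction.

## Pathway DA score

Per-metabolite testing is a two-sided Mann–Whitney U; the BH family is
all metabolites in the table, not per pathway, which is conservative and
makes q-values invariant to pathway membership and row order. Direction is
the sign of the group-B − group-A median difference (rank-coherent with
the test statistic) for metabolites with q < alpha (default 0.05,
configurable). The pathway score DA = (n_increased − n_decreased) /
n_measured is computed in exact rational arithmetic; its endpoints are
identities: DA = 1 iff every measured member increased, −1 iff every
member decreased. Pathways with fewer than 2 measured members are dropped.
The volcano classifier exposes an optional |log2FC| cutoff defaulting to
0, so significance alone decides unless the caller tightens it.

## Single-cell activity

The rank-AUC score ranks a cell's genes by decreasing expression, breaking
ties deterministically by gene id (no random jitter, so no seed is needed
for reproducibility), builds the recovery curve of the gene set over the
top ceil(top_fraction × n_genes) ranks, and normalizes the area by the
maximum achievable with min(|set|, k) genes at the very top. top_fraction
defaults to 0.05, the cited scoring tool's convention. Because only
within-cell ranks enter, the score is invariant to monotone per-cell
normalization — raw or normalized counts give identical results.

Threshold detection fits a Gaussian KDE (Scott bandwidth) to the AUC
values on a 512-point grid over the observed range. With two or more
density modes, the threshold is the density minimum between the two
highest modes; with one mode the fallback mean + 3·SD (clipped to the
observed range) is used and flagged "unimodal". Cells strictly above the
threshold are SG⁺; a cell exactly at the threshold is SG⁻, following the
strict "above" convention. SG⁺ proportions between cell groups are
compared by Pearson chi-square (1 df) without continuity correction by
default; zero-margin tables are rejected with a pointer to exact tests.

The packaged 42-gene spliceosome list is a synthetic stand-in of
well-known core spliceosome components (including the U5 snRNP genes
SNRNP200, PRPF8 and EFTUD2); any newline-delimited gene list can replace
it.

## Cohort distances

The distribution distance between two samples is the root-mean-square
difference of log expression over a configured gene subset (the 42-gene
and 109-gene spliceosome lists are both just inputs). Tumor strata are
paired with their matched normals through pair ids; strata without
matching (e.g. the normal-vs-normal baseline) use the all-cross-pairs
policy. Distance distributions are compared pairwise by the two-sided
Wilcoxon rank-sum test and across ≥3 strata by Kruskal–Wallis.

The per-sample enrichment score bundled for the spliceosome–pathway
correlation standardizes each gene across samples and averages z-scores
within a sample over the pathway's genes; pathway scores therefore have
cohort mean 0 by construction. It is a documented stand-in: the Spearman
correlation stage accepts any per-sample score, and only the correlation
structure, not the score's scale, matters there. Spearman p-values use the
exact permutation null (all n! pairings, two-sided on |rho|) for n ≤ 9 and
the t approximation otherwise.

## Synthetic data

The generators define the study conditions the tests run under:

- **Annotation**: three-exon genes on alternating strands, one contig per
  gene, exon length 60 nt, intron lengths uniform on [80, 130] nt
  (≥ 70 nt so trimmed GC cores stay scorable). All boundaries carry the
  consensus donor/acceptor except a weak_fraction (default 0.5) of genes
  whose first-intron donor has three consensus positions mutated.
- **Retention counts**: control PSI per event uniform on [0.05, 0.2];
  weak-donor genes gain ir_effect (default +0.3) in the knockdown
  condition, clipped to [0, 1] with a logged warning if more than 10% of
  events clip. Trials per sample are Poisson around depth (default 200);
  retention reads are binomial. 3 samples per group by default.
- **Metabolites**: log-normal abundances (baseline log2 ~ N(10, 1),
  noise SD 0.5 log2 units) with group-B shifts per a pathway spec; 10
  samples per group by default — metabolomics cohorts are larger than the
  3-vs-3 RNA-seq design, and the two sample sizes are independent knobs.
- **Cells**: negative-binomial counts (size 2) with gene means log-normal;
  a sg_fraction (default 0.4) of cells express the gene set at 8× mean,
  producing well-separated AUC modes.
- **Cohort**: matched tumor/normal pairs per subtype with subtype-graded
  shifts on the spliceosome subset (MPS2, the glycolytic subtype, largest
  by default), emulating the stratified distance comparison. This
  generator is an addition beyond the core simulators so the distance
  stage has a self-contained input.
- **qPCR**: CT(All) fixed at 20 cycles; CT(In) = CT(All) − log2(PSI) plus
  Gaussian replicate noise.

One global seed fans out to fixed per-generator child streams, so adding a
generator never perturbs another's draws and identical configs reproduce
outputs byte for byte. What the simulations do **not** model: read-level
sequencing (mapping bias, positional coverage), overdispersion between
biological replicates beyond Poisson trial variation, correlated
metabolites within a pathway, ambient RNA or doublets, and batch effects.
Passing tests therefore demonstrate correctness of the statistical
machinery and recovery of planted effects under clean assumptions, not
robustness to every artifact of real data.

## Problem sizes and numerics

The default demonstration run uses 100 genes, 3 samples per group at depth
200, 40 metabolites, 1000 cells × 500 genes, and 60 cohort pairs — sizes
chosen so every stage's statistics are well inside their operating range
while the full pipeline stays interactive (a few seconds on one CPU).
Exact enumeration paths (Fisher, small-sample Mann–Whitney, small-n
Spearman permutation) switch to asymptotic approximations past the sizes
noted above. KDE thresholding evaluates on a fixed 512-point grid;
degenerate inputs (constant AUC, zero-variance genes, empty trimmed cores,
zero-count events) are rejected or logged rather than silently coerced.

## Known limitations

Only retained-intron events are quantified (other event types pass
through as labels); the differential test ignores replicate-level
overdispersion by design; the splice-site scorer is a PWM, not a trained
maximum-entropy model; the enrichment stand-in is a z-score mean, not
GSVA; and the PTC caller's reading-frame convention is synthetic. Each of
these is an explicit interface seam where a heavier component can be
substituted.
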