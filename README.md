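# spliceometab

Toolkit for integrating RNA-splicing and metabolic readouts in tumor
cohorts, built around the analysis of spliceosome (U5 snRNP) activity in
triple-negative breast cancer: when core spliceosome components such as
SNRNP200 are depleted, introns with weak 5′ splice sites are retained,
metabolic enzyme transcripts are disrupted, and pathway-level metabolite
abundances shift. The package provides the quantitative machinery for each
step of that analysis, plus a synthetic-data generator with known ground
truth so the whole pipeline is testable without patient data.

## What it computes

- **Intron-retention PSI** — from read counts, PSI = ir / (ir + sj);
  from qPCR cycle thresholds, PSI = 2^(CT(All) − CT(In)) with primers
  spanning the adjacent exons (All) and inside the retained intron (In).
- **Differential retention** — per-event two-sided Fisher exact test on
  pooled group counts, Benjamini–Hochberg correction across events, and
  significance at FDR < 0.05 and |ΔPSI| > 0.02.
- **Splice-site strength** — PWM log2-odds scores over the standard donor
  (9-nt) and acceptor (23-nt) windows, strand-aware extraction, motif
  matrices with per-position information content, and the trimmed
  intron/exon GC ratio (20 nt off intron ends, 3 nt off exon ends).
  Retained vs non-retained introns are compared by the Wilcoxon rank-sum
  test.
- **Coding consequences** — frameshift (intron length mod 3) and
  premature-termination-codon detection for retained introns.
- **Pathway DA score** — per-metabolite Mann–Whitney U with one BH family
  across the table, then DA = (n_increased − n_decreased) / n_measured
  per pathway, ranging −1 (all members down) to 1 (all members up).
- **Single-cell spliceosome activity** — AUCell-style rank-AUC of a
  spliceosome gene set within each cell's top-ranked 5% of genes,
  automatic bimodal threshold (KDE valley between the two highest modes),
  SG⁺/SG⁻ labels (strictly above the threshold → SG⁺), and chi-square
  comparison of SG⁺ proportions between cell groups.
- **Cohort distribution distances** — per-pair r.m.s.d. of log expression
  over a spliceosome gene subset between tumors and matched normals, with
  Wilcoxon and Kruskal–Wallis tests across strata, plus Spearman
  correlation against per-sample pathway scores.

## Worked example

Run the six-stage synthetic demonstration from the shell:

```
spliceometab simulate --outdir demo --seed 3
spliceometab diff-ir --counts demo/counts.tsv \
    --group-a control --group-b knockdown --out demo/events.tsv
# -> 50 significant events (FDR < 0.05, |dPSI| > 0.02) of 100 tested
spliceometab site-features --gtf demo/annotation.gtf --fasta demo/genome.fa \
    --events demo/events.tsv --out demo/features.tsv
# -> RI vs NRI donor strength: Wilcoxon p = 2.628e-23
spliceometab sg-score --matrix demo/cells.mtx \
    --gene-set demo/gene_set.txt --out demo/sg.tsv
# -> {"threshold": 0.3455, "method": "bimodal", "n_sg_pos": 400, "n_cells": 1000}
```

The simulation plants a +0.3 ΔPSI retention effect in the 50 genes given
degenerate donor sites; the differential test recovers exactly those 50,
their donor windows score far below consensus (hence the tiny rank-sum p),
and the 40% of cells simulated as spliceosome-high fall above the
automatically detected AUC valley. The pathway DA stage on the same run
prints:

```
   pathway_id  n_measured  n_increased  n_decreased   da
glycolysis_up           8            8            0  1.0
 null_pathway          24            0            0  0.0
   lipid_down           8            0            8 -1.0
```

i.e. a pathway whose 8 metabolites all significantly increase scores
DA = 1, one whose members all decrease scores −1, and a null pathway stays
at 0. Equivalently in Python:

```python
from spliceometab.pipeline import RunConfig, demo_config_path, run_pipeline
manifest = run_pipeline(RunConfig.from_yaml(demo_config_path()))
```

which executes simulate → diff-ir → site-features → da → sg-score →
cohort-dist deterministically (re-running with the same seed reproduces
every output byte for byte) and writes a manifest of row counts per stage.

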