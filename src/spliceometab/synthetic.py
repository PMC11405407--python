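"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the shapes of the study's inputs — gene models with
strong or degenerate 5' splice sites, intron-retention read counts under two
conditions, pathway-structured metabolite tables, qPCR cycle thresholds, and
single-cell count matrices with a planted high-spliceosome-activity
population — without modelling sequencing reads themselves. Read evidence for
retention is binomial, metabolite abundances log-normal, and cell counts
negative-binomial; these are deliberately simple, standard choices whose
injected effects the downstream statistics must recover.

Determinism: one global seed fans out to per-generator child streams through
fixed offsets, so adding a generator never perturbs the draws of another.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, write_fasta, write_gtf

logger = logging.getLogger("spliceometab")

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "DONOR_CONSENSUS",
    "ACCEPTOR_CONSENSUS",
    "WEAK_DONOR",
    "generate_annotation",
    "generate_ir_counts",
    "generate_metabolites",
    "generate_cells",
    "generate_qpcr",
    "generate_expression_cohort",
]

# Donor window: 3 exonic + 6 intronic nt; acceptor: 20 intronic + 3 exonic.
DONOR_CONSENSUS = "CAGGTAAGT"
ACCEPTOR_CONSENSUS = "TTTTTTTTTTTTTTTTTCAGGCT"
# Degenerate donor: three intronic consensus positions mutated (GTAAGT -> GTCCAT).
WEAK_DONOR = "CAGGTCCAT"

MIN_INTRON_LEN = 70  # trimming 20 nt off each end must leave a scorable core

# fixed child-stream offsets
_ANNOT, _COUNTS, _METAB, _CELLS, _QPCR, _COHORT = 11, 23, 37, 53, 71, 97


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, seed])


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults define the study conditions."""

    seed: int = 0
    n_genes: int = 100
    weak_fraction: float = 0.5
    depth: float = 200.0
    ir_effect: float = 0.3
    n_samples_per_group: int = 3
    n_cells: int = 1000
    sg_fraction: float = 0.4
    noise_sd: float = 0.5
    # gene-structure knobs (rarely changed)
    exon_len: int = 60
    intron_len_range: tuple[int, int] = (80, 130)
    base_psi_range: tuple[float, float] = (0.05, 0.2)
    n_cell_genes: int = 500
    sg_strength: float = 8.0
    # metabolomics cohorts are larger than the 3v3 RNA-seq design
    n_metab_samples_per_group: int = 10

    def __post_init__(self) -> None:
        for name in ("weak_fraction", "sg_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_samples_per_group", "n_cells", "n_cell_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, keyed the way downstream results are keyed."""

    weak_donor_genes: dict[str, bool] = field(default_factory=dict)
    true_psi: dict[str, dict[str, float]] = field(default_factory=dict)
    true_direction: dict[str, str] = field(default_factory=dict)
    true_cell_label: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        self.weak_donor_genes.update(other.weak_donor_genes)
        self.true_psi.update(other.true_psi)
        self.true_direction.update(other.true_direction)
        self.true_cell_label.update(other.true_cell_label)
        return self

    def to_dict(self) -> dict:
        return {
            "weak_donor_genes": self.weak_donor_genes,
            "true_psi": self.true_psi,
            "true_direction": self.true_direction,
            "true_cell_label": self.true_cell_label,
        }


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------


def generate_annotation(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[list[TranscriptModel], dict[str, str], GroundTruth]:
    """Three-exon gene models, one contig per gene, alternating strands.

    Every exon/intron boundary carries the donor/acceptor consensus except
    that a ``weak_fraction`` of genes get a degenerate donor (>= 2 consensus
    positions mutated) at their first intron — the intron later used as the
    retention event. Returns transcripts, the genome, and weak-donor flags;
    writes GTF + FASTA when ``outdir`` is given.
    """
    rng = _rng(config.seed, _ANNOT)
    lo, hi = config.intron_len_range
    n_weak = round(config.weak_fraction * config.n_genes)
    weak_idx = set(rng.choice(config.n_genes, size=n_weak, replace=False).tolist())

    transcripts: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    gt = GroundTruth()
    bases = np.array(list("ACGT"))

    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        strand = "+" if g % 2 == 0 else "-"
        intron_lens = rng.integers(lo, hi + 1, size=2).tolist()
        for il in intron_lens:
            if il < MIN_INTRON_LEN:
                raise ValueError(
                    f"{gene_id}: intron length {il} below minimum {MIN_INTRON_LEN}; "
                    "raise intron_len_range"
                )
        exon_lens = [config.exon_len] * 3
        tx_len = sum(exon_lens) + sum(intron_lens)
        seq = rng.choice(bases, size=tx_len)

        # lay out exon/intron blocks in transcript orientation
        pos, blocks = 0, []
        for i in range(3):
            blocks.append(("exon", pos, pos + exon_lens[i]))
            pos += exon_lens[i]
            if i < 2:
                blocks.append(("intron", pos, pos + intron_lens[i]))
                pos += intron_lens[i]

        weak = g in weak_idx
        intron_no = 0
        for kind, s, e in blocks:
            if kind != "intron":
                continue
            donor = WEAK_DONOR if (weak and intron_no == 0) else DONOR_CONSENSUS
            seq[s - 3 : s + 6] = list(donor)
            seq[e - 20 : e + 3] = list(ACCEPTOR_CONSENSUS)
            intron_no += 1

        tx_seq = "".join(seq)
        # pad the contig so boundary windows never touch contig ends
        pad5 = "".join(rng.choice(bases, size=25))
        pad3 = "".join(rng.choice(bases, size=25))
        if strand == "+":
            contig_seq = pad5 + tx_seq + pad3
            offset = len(pad5)
            exon_iv = []
            pos = offset
            for i in range(3):
                exon_iv.append((pos, pos + exon_lens[i]))
                pos += exon_lens[i] + (intron_lens[i] if i < 2 else 0)
        else:
            from .annotation import reverse_complement

            contig_seq = pad5 + reverse_complement(tx_seq) + pad3
            offset = len(pad5)
            # transcript blocks map to genome in reverse order
            exon_iv = []
            pos = offset
            for i in range(2, -1, -1):
                exon_iv.append((pos, pos + exon_lens[i]))
                pos += exon_lens[i] + (intron_lens[i - 1] if i > 0 else 0)
            exon_iv.sort()

        chrom = f"ctg_{gene_id}"
        genome[chrom] = contig_seq
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.T1",
                chrom=chrom,
                strand=strand,
                exons=exon_iv,
            )
        )
        gt.weak_donor_genes[gene_id] = weak

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(transcripts, outdir / "annotation.gtf")
        write_fasta(genome, outdir / "genome.fa")
    return transcripts, genome, gt


# ---------------------------------------------------------------------------
# intron-retention counts
# ---------------------------------------------------------------------------


def generate_ir_counts(
    transcripts: list[TranscriptModel],
    ground_truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Binomial retention/junction read counts for one event per gene.

    The event is each gene's first transcript-order intron. Control-condition
    PSI is drawn per event from ``base_psi_range``; weak-donor genes gain
    ``ir_effect`` in the knockdown condition (clipped to [0, 1]; more than 10%
    of events clipped raises a logged warning). Trial counts per sample are
    Poisson around ``depth``.
    """
    rng = _rng(config.seed, _COUNTS)
    gt = GroundTruth(weak_donor_genes=dict(ground_truth.weak_donor_genes))
    lo, hi = config.base_psi_range

    rows = []
    n_clipped = 0
    for t in transcripts:
        event_id = f"{t.gene_id}.I1"
        base = float(rng.uniform(lo, hi))
        kd_raw = base + (config.ir_effect if ground_truth.weak_donor_genes[t.gene_id] else 0.0)
        kd = min(max(kd_raw, 0.0), 1.0)
        if kd != kd_raw:
            n_clipped += 1
        gt.true_psi[event_id] = {"control": base, "knockdown": kd}
        for condition, psi in (("control", base), ("knockdown", kd)):
            for s in range(1, config.n_samples_per_group + 1):
                n = int(rng.poisson(config.depth))
                ir = int(rng.binomial(n, psi)) if n > 0 else 0
                rows.append(
                    {
                        "event_id": event_id,
                        "event_type": "RI",
                        "sample": f"{condition}_{s}",
                        "condition": condition,
                        "ir_reads": ir,
                        "sj_reads": n - ir,
                    }
                )
    if n_clipped > 0.10 * len(transcripts):
        logger.warning(
            "generate_ir_counts: %d/%d events had true PSI clipped to [0, 1]",
            n_clipped,
            len(transcripts),
        )
    return pd.DataFrame(rows), gt


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------


def generate_metabolites(
    config: SimulationConfig,
    pathway_spec: dict[str, dict[str, float]],
) -> tuple[pd.DataFrame, GroundTruth]:
    """Log-normal metabolite table with pathway-structured group-B shifts.

    ``pathway_spec`` maps pathway id -> {metabolite id -> log2 effect};
    effect 0 means a null metabolite. A metabolite listed in several pathways
    must carry the same effect in each. Column order: metabolite_id,
    pathways (semicolon-joined), then group-A and group-B samples.
    """
    effects: dict[str, float] = {}
    membership: dict[str, list[str]] = {}
    for pw, members in pathway_spec.items():
        if not members:
            raise ValueError(f"pathway {pw!r} has zero metabolites")
        for met, eff in members.items():
            if met in effects and effects[met] != eff:
                raise ValueError(f"metabolite {met!r} has conflicting effects across pathways")
            effects[met] = float(eff)
            membership.setdefault(met, []).append(pw)

    rng = _rng(config.seed, _METAB)
    n = config.n_metab_samples_per_group
    mets = list(effects)
    gt = GroundTruth()
    rows = []
    for met in mets:
        eff = effects[met]
        base = rng.normal(10.0, 1.0)
        log_a = base + rng.normal(0.0, config.noise_sd, size=n)
        log_b = base + eff + rng.normal(0.0, config.noise_sd, size=n)
        gt.true_direction[met] = "up" if eff > 0 else ("down" if eff < 0 else "null")
        row = {"metabolite_id": met, "pathways": ";".join(membership[met])}
        row.update({f"A_{i + 1}": 2.0 ** v for i, v in enumerate(log_a)})
        row.update({f"B_{i + 1}": 2.0 ** v for i, v in enumerate(log_b)})
        rows.append(row)
    return pd.DataFrame(rows), gt


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------


def generate_cells(
    config: SimulationConfig,
    gene_set: list[str],
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial gene x cell counts with a planted SG+ population.

    ``sg_fraction`` of cells express the gene set from a mean inflated by
    ``sg_strength``; all other genes share one background regime. Returns a
    dense genes x cells frame (genes 'G0001'.., cells 'cell_0001'..); writes
    MatrixMarket + genes.txt + barcodes.txt when ``outdir`` is given.
    """
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    genes = [f"G{i + 1:04d}" for i in range(config.n_cell_genes)]
    missing = set(gene_set) - set(genes)
    if missing:
        raise ValueError(f"gene_set members not among simulated genes: {sorted(missing)[:5]}")

    rng = _rng(config.seed, _CELLS)
    n_sg = round(config.sg_fraction * config.n_cells)
    labels = np.array(["SG+"] * n_sg + ["SG-"] * (config.n_cells - n_sg))
    rng.shuffle(labels)

    gene_mu = rng.lognormal(0.0, 1.0, size=config.n_cell_genes)
    set_mask = np.isin(np.array(genes), np.array(list(gene_set)))
    mu = np.tile(gene_mu[:, None], (1, config.n_cells))
    mu[np.ix_(set_mask, labels == "SG+")] *= config.sg_strength

    r = 2.0  # NB size (inverse dispersion)
    counts = rng.negative_binomial(r, r / (r + mu))
    cells = [f"cell_{i + 1:05d}" for i in range(config.n_cells)]
    mat = pd.DataFrame(counts, index=genes, columns=cells)

    gt = GroundTruth(true_cell_label={c: l for c, l in zip(cells, labels)})

    if outdir is not None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "cells.mtx"), csr_matrix(counts))
        (outdir / "genes.txt").write_text("\n".join(genes) + "\n")
        (outdir / "barcodes.txt").write_text("\n".join(cells) + "\n")
    return mat, gt


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def generate_qpcr(
    true_psi: float,
    noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    ct_all_baseline: float = 20.0,
) -> pd.DataFrame:
    """Cycle-threshold pairs whose 2^(CT(All)-CT(In)) recovers ``true_psi``.

    CT(All) is a fixed baseline; CT(In) = CT(All) - log2(psi) + Gaussian
    noise per replicate. A PSI of exactly 0 would put the intron primer pair
    beyond any cycle count and is rejected; callers must apply their own
    detection-limit convention.
    """
    if not 0.0 < true_psi <= 1.0:
        raise ValueError(f"true_psi must be in (0, 1], got {true_psi}")
    rng = _rng(seed, _QPCR)
    ct_all = ct_all_baseline
    rows = [
        {
            "replicate": rep + 1,
            "ct_all": ct_all,
            "ct_in": ct_all - math.log2(true_psi) + rng.normal(0.0, noise_sd),
        }
        for rep in range(replicates)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression cohort (for the distribution-distance stage)
# ---------------------------------------------------------------------------


def generate_expression_cohort(
    config: SimulationConfig,
    gene_subset: list[str] | None = None,
    n_pairs_per_subtype: int = 20,
    subtype_shifts: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched tumor/normal log-expression cohort with subtype-graded shifts.

    Each subtype contributes ``n_pairs_per_subtype`` tumor/normal pairs; the
    tumor of each pair is shifted on ``gene_subset`` by the subtype's effect
    plus per-sample noise. Returns (expression genes x samples, annotation
    with sample/type/subtype/pair_id).
    """
    rng = _rng(config.seed, _COHORT)
    genes = [f"G{i + 1:04d}" for i in range(config.n_cell_genes)]
    if gene_subset is None:
        gene_subset = genes[:42]
    if subtype_shifts is None:
        subtype_shifts = {"MPS1": 0.5, "MPS2": 1.5, "MPS3": 1.0}

    base = rng.normal(8.0, 2.0, size=len(genes))
    sub_mask = np.isin(np.array(genes), np.array(list(gene_subset)))

    cols, annot = {}, []
    for subtype, shift in subtype_shifts.items():
        for p in range(1, n_pairs_per_subtype + 1):
            pair_id = f"{subtype}_p{p:02d}"
            normal = base + rng.normal(0.0, config.noise_sd, size=len(genes))
            tumor = normal + rng.normal(0.0, config.noise_sd, size=len(genes))
            tumor[sub_mask] += shift
            for kind, vec in (("normal", normal), ("tumor", tumor)):
                sid = f"{pair_id}_{kind}"
                cols[sid] = vec
                annot.append(
                    {"sample": sid, "type": kind, "subtype": subtype, "pair_id": pair_id}
                )
    expr = pd.DataFrame(cols, index=genes)
    return expr, pd.DataFrame(annot)
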