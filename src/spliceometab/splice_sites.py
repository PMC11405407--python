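"""Splice-site strength scoring, motif matrices, and the trimmed GC ratio.

The scorer is a position-weight-matrix log2-odds model over the standard
donor window (9 nt: last 3 exonic + first 6 intronic) and acceptor window
(23 nt: last 20 intronic + first 3 exonic). The model family is a design
choice: a PWM with pluggable background/pseudocount gives a monotone
strength score that supports the retained- vs non-retained-intron rank
comparison; any external scorer honouring ``score(sequence) -> float`` can
be dropped in.

GC composition of an intron relative to its flanking exons is measured
after deleting 20 nucleotides from either end of the intron and 3
nucleotides from each exon end adjoining it, then dividing intron-core GC
content by the mean of the two exon-core GC contents.

Retained vs non-retained comparisons use the two-sided Wilcoxon rank-sum
(Mann–Whitney U) test: exact when both groups are small and tie-free,
otherwise the tie-corrected normal approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel, reverse_complement

logger = logging.getLogger("spliceometab")

__all__ = [
    "SpliceSiteModel",
    "DONOR_WINDOW",
    "ACCEPTOR_WINDOW",
    "build_site_model",
    "score_splice_site",
    "consensus_donor_model",
    "consensus_acceptor_model",
    "extract_donor_window",
    "extract_acceptor_window",
    "relative_gc",
    "compare_ri_nri",
    "intron_features",
]

BASES = "ACGT"
DONOR_WINDOW = 9  # 3 exonic + 6 intronic
ACCEPTOR_WINDOW = 23  # 20 intronic + 3 exonic
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


@dataclass
class SpliceSiteModel:
    """Per-position log2-odds weights over a fixed window."""

    site_kind: str  # "donor" | "acceptor"
    weights: np.ndarray  # (window, 4), bits vs background
    background: np.ndarray  # (4,), sums to 1
    pseudocount: float

    @property
    def window(self) -> int:
        return self.weights.shape[0]

    def max_score(self) -> float:
        """Upper bound: sum of per-position maxima."""
        return float(self.weights.max(axis=1).sum())

    def information_content(self) -> np.ndarray:
        """Per-position IC (bits) of the source frequencies vs background."""
        freqs = self.background[None, :] * (2.0 ** self.weights)
        freqs = freqs / freqs.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(freqs > 0, freqs * np.log2(freqs / self.background[None, :]), 0.0)
        return terms.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, columns=list(BASES)).rename_axis("position")


def _expected_window(site_kind: str) -> int:
    if site_kind == "donor":
        return DONOR_WINDOW
    if site_kind == "acceptor":
        return ACCEPTOR_WINDOW
    raise ValueError(f"site_kind must be 'donor' or 'acceptor', got {site_kind!r}")


def build_site_model(
    aligned_sequences: list[str],
    site_kind: str,
    background=UNIFORM_BG,
    pseudocount: float = 0.5,
) -> SpliceSiteModel:
    """PWM log2-odds model from an alignment of fixed-width site sequences."""
    window = _expected_window(site_kind)
    if not aligned_sequences:
        raise ValueError("need at least one sequence")
    for s in aligned_sequences:
        if len(s) != window:
            raise ValueError(f"sequence {s!r} has length {len(s)}, expected {window}")
        bad = set(s.upper()) - set(BASES)
        if bad:
            raise ValueError(f"sequence {s!r} contains non-ACGT characters {bad}")
    counts = np.zeros((window, 4))
    for s in aligned_sequences:
        for i, b in enumerate(s.upper()):
            counts[i, BASES.index(b)] += 1
    freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    with np.errstate(divide="ignore"):
        weights = np.log2(freqs / bg[None, :])
    return SpliceSiteModel(site_kind=site_kind, weights=weights, background=bg,
                           pseudocount=pseudocount)


def score_splice_site(sequence: str, model: SpliceSiteModel, skip_ambiguous: bool = False):
    """Sum of per-position log2-odds weights (bits) for one site sequence.

    Ambiguity codes raise by default; with ``skip_ambiguous`` the call
    returns NaN instead.
    """
    seq = sequence.upper()
    if len(seq) != model.window:
        raise ValueError(f"sequence length {len(seq)} != model window {model.window}")
    if set(seq) - set(BASES):
        if skip_ambiguous:
            return float("nan")
        raise ValueError(f"ambiguous bases in {sequence!r}")
    return float(sum(model.weights[i, BASES.index(b)] for i, b in enumerate(seq)))


def consensus_donor_model(pseudocount: float = 0.5) -> SpliceSiteModel:
    """Bundled donor model built from the consensus 5' splice site."""
    from .synthetic import DONOR_CONSENSUS

    return build_site_model([DONOR_CONSENSUS] * 20, "donor", pseudocount=pseudocount)


def consensus_acceptor_model(pseudocount: float = 0.5) -> SpliceSiteModel:
    """Bundled acceptor model built from the consensus 3' splice site."""
    from .synthetic import ACCEPTOR_CONSENSUS

    return build_site_model([ACCEPTOR_CONSENSUS] * 20, "acceptor", pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# strand-aware window extraction
# ---------------------------------------------------------------------------


def _tx_intron_bounds(t: TranscriptModel, intron_index: int) -> tuple[int, int]:
    gi = t._genomic_intron_index(intron_index)
    return t.introns[gi]


def extract_donor_window(
    t: TranscriptModel, intron_index: int, genome: dict[str, str]
) -> str:
    """9-mer around the 5' splice site of an intron, transcript orientation."""
    s, e = _tx_intron_bounds(t, intron_index)
    contig = genome[t.chrom]
    if t.strand == "+":
        return contig[s - 3 : s + 6].upper()
    return reverse_complement(contig[e - 6 : e + 3]).upper()


def extract_acceptor_window(
    t: TranscriptModel, intron_index: int, genome: dict[str, str]
) -> str:
    """23-mer around the 3' splice site of an intron, transcript orientation."""
    s, e = _tx_intron_bounds(t, intron_index)
    contig = genome[t.chrom]
    if t.strand == "+":
        return contig[e - 20 : e + 3].upper()
    return reverse_complement(contig[s - 3 : s + 20]).upper()


# ---------------------------------------------------------------------------
# GC composition
# ---------------------------------------------------------------------------


def _gc_fraction(seq: str) -> float:
    return sum(1 for b in seq if b in "GCgc") / len(seq)


def relative_gc(
    intron_seq: str,
    exon_up_seq: str,
    exon_down_seq: str,
    intron_trim: int = 20,
    exon_trim: int = 3,
) -> float:
    """GC of the trimmed intron over the mean GC of the trimmed flanking exons.

    Both introns and exons are trimmed at both ends (20 nt and 3 nt
    respectively by default). Returns NaN with a log record when any core is
    empty after trimming.
    """
    intron_core = intron_seq[intron_trim : len(intron_seq) - intron_trim]
    up_core = exon_up_seq[exon_trim : len(exon_up_seq) - exon_trim]
    down_core = exon_down_seq[exon_trim : len(exon_down_seq) - exon_trim]
    if not intron_core or not up_core or not down_core:
        logger.info("relative_gc: empty core after trimming, returning NaN")
        return float("nan")
    exon_gc = (_gc_fraction(up_core) + _gc_fraction(down_core)) / 2.0
    if exon_gc == 0.0:
        logger.info("relative_gc: flanking exon cores have zero GC, returning NaN")
        return float("nan")
    return _gc_fraction(intron_core) / exon_gc


# ---------------------------------------------------------------------------
# RI vs NRI rank comparison
# ---------------------------------------------------------------------------


def compare_ri_nri(values_ri, values_nri, alternative: str = "two-sided"):
    """Wilcoxon rank-sum of retained-intron vs non-retained-intron features.

    Exact null enumeration when both groups have <= 10 observations with no
    ties; otherwise the tie-corrected normal approximation (with continuity
    correction). Returns (U statistic, p).
    """
    x = np.asarray(values_ri, dtype=float)
    y = np.asarray(values_nri, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 observations")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


def intron_features(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    retained_events: set[str],
    donor_model: SpliceSiteModel | None = None,
    acceptor_model: SpliceSiteModel | None = None,
) -> pd.DataFrame:
    """Per-intron donor/acceptor scores and GC ratio with RI/NRI labels.

    Restricted to genes harbouring at least one retained event: their
    non-retained introns form the NRI comparison set. Event ids follow the
    ``<gene>.I<k>`` convention with k counting introns in transcript order.
    """
    donor_model = donor_model or consensus_donor_model()
    acceptor_model = acceptor_model or consensus_acceptor_model()
    retained_genes = {e.rsplit(".I", 1)[0] for e in retained_events}

    rows = []
    for t in transcripts:
        if t.gene_id not in retained_genes:
            continue
        for k in range(t.n_introns()):
            event_id = f"{t.gene_id}.I{k + 1}"
            gi = t._genomic_intron_index(k)
            istart, iend = t.introns[gi]
            contig = genome[t.chrom]
            intron = contig[istart:iend]
            exon_up_g = contig[slice(*t.exons[gi])]
            exon_down_g = contig[slice(*t.exons[gi + 1])]
            if t.strand == "-":
                intron = reverse_complement(intron)
                exon_up_g, exon_down_g = (
                    reverse_complement(exon_down_g),
                    reverse_complement(exon_up_g),
                )
            rows.append(
                {
                    "event_id": event_id,
                    "gene_id": t.gene_id,
                    "donor_score": score_splice_site(
                        extract_donor_window(t, k, genome), donor_model
                    ),
                    "acceptor_score": score_splice_site(
                        extract_acceptor_window(t, k, genome), acceptor_model
                    ),
                    "gc_ratio": relative_gc(intron, exon_up_g, exon_down_g),
                    "retained": event_id in retained_events,
                }
            )
    return pd.DataFrame(rows)
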