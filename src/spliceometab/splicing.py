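"""Intron-retention PSI quantification and differential retention testing.

PSI (percent spliced in) for a retained intron is estimated from read
evidence as ir / (ir + sj), where ir counts reads supporting retention and
sj counts spliced-junction reads; no length normalization is applied because
both count classes are generated on the same scale here (an optional hook is
left for length-aware inputs). Differential retention between two conditions
pools counts within each group and applies a two-sided Fisher exact test per
event with Benjamini–Hochberg correction across events; an event is called
significant when FDR < 0.05 and |ΔPSI| > 0.02 (both thresholds
configurable). The qPCR route estimates PSI = 2^(CT(All) − CT(In)) from
primer pairs spanning the adjacent exons (All) and inside the retained
intron (In).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptModel

logger = logging.getLogger("spliceometab")

__all__ = [
    "compute_psi",
    "diff_ir",
    "qpcr_psi",
    "qpcr_table",
    "detect_ptc",
    "CodingConsequence",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


def compute_psi(ir_reads: int, sj_reads: int) -> float:
    """Retention PSI from counts; NaN (never 0) when both counts are zero."""
    if ir_reads < 0 or sj_reads < 0:
        raise ValueError("read counts must be nonnegative")
    total = ir_reads + sj_reads
    if total == 0:
        return float("nan")
    return ir_reads / total


def diff_ir(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    fdr_threshold: float = 0.05,
    dpsi_threshold: float = 0.02,
) -> pd.DataFrame:
    """Per-event differential retention between two condition groups.

    Expects long-format counts with columns event_id, condition, ir_reads,
    sj_reads (one row per event x sample). Counts are pooled within each
    group; the 2x2 table [(ir_A, sj_A), (ir_B, sj_B)] is tested by two-sided
    Fisher exact, and p-values are BH-adjusted across all tested events.
    ΔPSI = psi_B − psi_A. Events where either group has zero total counts
    are skipped with a log record.
    """
    conditions = set(table["condition"])
    for g in (group_a, group_b):
        if g not in conditions:
            raise ValueError(f"unknown group label {g!r}; table has {sorted(conditions)}")

    pooled = (
        table[table["condition"].isin([group_a, group_b])]
        .groupby(["event_id", "condition"], sort=True)[["ir_reads", "sj_reads"]]
        .sum()
    )
    rows = []
    for event_id in pooled.index.get_level_values(0).unique():
        try:
            a = pooled.loc[(event_id, group_a)]
            b = pooled.loc[(event_id, group_b)]
        except KeyError:
            logger.info("diff_ir: %s missing a group, skipped", event_id)
            continue
        ir_a, sj_a = int(a["ir_reads"]), int(a["sj_reads"])
        ir_b, sj_b = int(b["ir_reads"]), int(b["sj_reads"])
        if ir_a + sj_a == 0 or ir_b + sj_b == 0:
            logger.info("diff_ir: %s has zero total counts in a group, skipped", event_id)
            continue
        psi_a = compute_psi(ir_a, sj_a)
        psi_b = compute_psi(ir_b, sj_b)
        _, p = stats.fisher_exact([[ir_a, sj_a], [ir_b, sj_b]], alternative="two-sided")
        rows.append(
            {
                "event_id": event_id,
                "ir_a": ir_a,
                "sj_a": sj_a,
                "ir_b": ir_b,
                "sj_b": sj_b,
                "psi_a": psi_a,
                "psi_b": psi_b,
                "delta_psi": psi_b - psi_a,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no testable events (every event lacked counts in a group)")
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = (out["fdr"] < fdr_threshold) & (
        out["delta_psi"].abs() > dpsi_threshold
    )
    return out.reset_index(drop=True)


def qpcr_psi(ct_all: float, ct_in: float) -> float:
    """PSI = 2^(CT(All) − CT(In)); values above 1 are returned as computed."""
    if not (math.isfinite(ct_all) and math.isfinite(ct_in)):
        raise ValueError("CT values must be finite")
    return 2.0 ** (ct_all - ct_in)


def qpcr_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Apply qpcr_psi row-wise; flags estimates exceeding 1 as out of range.

    Expects columns ct_all and ct_in (extra columns pass through).
    """
    out = measurements.copy()
    out["psi"] = [qpcr_psi(a, i) for a, i in zip(out["ct_all"], out["ct_in"])]
    out["out_of_range"] = out["psi"] > 1.0
    return out


# ---------------------------------------------------------------------------
# coding consequences of intron retention
# ---------------------------------------------------------------------------


@dataclass
class CodingConsequence:
    event_id: str
    frameshift: bool
    ptc_offset: int | None  # codon index of the first in-frame stop at/after the intron
    truncation_flag: bool


def _first_stop_at_or_after(mrna: str, nt_from: int) -> int | None:
    """Codon index of the first frame-0 stop whose codon starts at or after nt_from."""
    start_codon = max(0, -(-nt_from // 3))  # ceil division
    for c in range(start_codon, len(mrna) // 3):
        if mrna[3 * c : 3 * c + 3] in STOP_CODONS:
            return c
    return None


def detect_ptc(
    transcript: TranscriptModel,
    retained_intron_index: int,
    genome: dict[str, str],
    event_id: str | None = None,
) -> CodingConsequence:
    """Frameshift and premature-stop consequences of retaining one intron.

    Translation is taken to start at transcript nucleotide 1 (synthetic
    convention; real ORFs are not reproduced). The retained transcript is
    scanned for the first in-frame stop at or after the intron's transcript
    position; the truncation flag is set when that stop lands upstream of
    where the normally spliced transcript's first stop maps in retained
    coordinates.
    """
    introns = transcript.introns
    gi = transcript._genomic_intron_index(retained_intron_index)
    intron_len = introns[gi][1] - introns[gi][0]
    frameshift = intron_len % 3 != 0

    retained = transcript.retained_mrna(genome, retained_intron_index)
    tx_off = transcript.intron_tx_offset(genome, retained_intron_index)
    ptc_offset = _first_stop_at_or_after(retained, tx_off)

    spliced = transcript.spliced_mrna(genome)
    norm_stop = _first_stop_at_or_after(spliced, 0)
    if ptc_offset is None:
        truncation = False
    elif norm_stop is None:
        truncation = True
    else:
        norm_nt = 3 * norm_stop
        # map the normal stop into retained-transcript coordinates
        mapped = norm_nt if norm_nt < tx_off else norm_nt + intron_len
        truncation = 3 * ptc_offset < mapped
    return CodingConsequence(
        event_id=event_id or f"{transcript.gene_id}.I{retained_intron_index + 1}",
        frameshift=frameshift,
        ptc_offset=ptc_offset,
        truncation_flag=truncation,
    )
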