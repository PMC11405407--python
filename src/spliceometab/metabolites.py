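"""Metabolite differential abundance and the pathway DA score.

Each metabolite is compared between two sample groups with a two-sided
Mann–Whitney U test; Benjamini–Hochberg correction is applied once across
all metabolites in the table (a single family, so pathway membership never
changes a q-value). A metabolite counts as increased (decreased) for a
pathway when its q-value clears alpha and its group-B median is higher
(lower). The pathway's differential-abundance score is

    DA = (n_increased − n_decreased) / n_measured

which ranges from −1 (every measured member significantly decreased) to 1
(every member significantly increased).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("spliceometab")

__all__ = [
    "test_metabolites",
    "da_score",
    "pathway_da",
    "classify_volcano",
    "PathwayDAResult",
    "parse_metabolite_table",
]


def parse_metabolite_table(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Split a metabolite TSV into an abundance matrix and pathway membership.

    Expects columns metabolite_id, pathways (semicolon-separated, may be
    empty), then one column per sample.
    """
    membership: dict[str, set[str]] = {}
    for met, pw in zip(df["metabolite_id"], df["pathways"].fillna("")):
        for p in str(pw).split(";"):
            if p:
                membership.setdefault(p, set()).add(met)
    abundance = df.drop(columns=["pathways"]).set_index("metabolite_id")
    return abundance, membership


def test_metabolites(
    abundance: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite Mann–Whitney U with one BH family across the table.

    ``abundance`` is metabolite x sample. Direction is the sign of the
    median difference (group_b − group_a) for metabolites with q < alpha,
    otherwise 'null'. Metabolites constant across all samples get p = 1.
    Returns a frame indexed by metabolite with p, q, direction, log2fc.
    """
    for g, name in ((group_a, "group_a"), (group_b, "group_b")):
        if len(g) < 2:
            raise ValueError(f"{name} needs at least 2 samples")
        missing = set(g) - set(abundance.columns)
        if missing:
            raise ValueError(f"{name} samples not in table: {sorted(missing)}")

    a = abundance[group_a].to_numpy(dtype=float)
    b = abundance[group_b].to_numpy(dtype=float)
    pvals = np.ones(len(abundance))
    for i in range(len(abundance)):
        if np.all(np.concatenate([a[i], b[i]]) == a[i, 0]):
            logger.info("test_metabolites: %s constant, p = 1", abundance.index[i])
            continue
        pvals[i] = stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    med_diff = np.median(b, axis=1) - np.median(a, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(np.median(b, axis=1) / np.median(a, axis=1))
    direction = np.where(
        (qvals < alpha) & (med_diff > 0),
        "up",
        np.where((qvals < alpha) & (med_diff < 0), "down", "null"),
    )
    return pd.DataFrame(
        {"p": pvals, "q": qvals, "direction": direction, "log2fc": log2fc},
        index=abundance.index,
    )


def da_score(n_increased: int, n_decreased: int, n_measured: int) -> float:
    """(increased − decreased) / measured, exact rational arithmetic."""
    if n_measured < 1:
        raise ValueError("n_measured must be >= 1")
    if n_increased < 0 or n_decreased < 0:
        raise ValueError("counts must be nonnegative")
    if n_increased + n_decreased > n_measured:
        raise ValueError("significant counts exceed measured metabolites")
    return float(Fraction(n_increased - n_decreased, n_measured))


@dataclass
class PathwayDAResult:
    pathway_id: str
    n_measured: int
    n_increased: int
    n_decreased: int
    da: float


def pathway_da(
    abundance: pd.DataFrame,
    pathways: dict[str, set[str]],
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    min_size: int = 2,
) -> pd.DataFrame:
    """Pathway DA scores from one table-wide BH family.

    A metabolite belonging to several pathways contributes to each.
    Pathways with fewer than ``min_size`` measured members are dropped with
    a log record. Results are sorted by DA score (descending), ties by
    pathway id.
    """
    per_met = test_metabolites(abundance, group_a, group_b, alpha=alpha)
    rows = []
    for pw, members in pathways.items():
        measured = sorted(members & set(abundance.index))
        if len(measured) < min_size:
            logger.info("pathway_da: %s has %d measured metabolites (< %d), dropped",
                        pw, len(measured), min_size)
            continue
        dirs = per_met.loc[measured, "direction"]
        n_inc = int((dirs == "up").sum())
        n_dec = int((dirs == "down").sum())
        rows.append(
            {
                "pathway_id": pw,
                "n_measured": len(measured),
                "n_increased": n_inc,
                "n_decreased": n_dec,
                "da": da_score(n_inc, n_dec, len(measured)),
            }
        )
    out = pd.DataFrame(rows, columns=["pathway_id", "n_measured", "n_increased",
                                      "n_decreased", "da"])
    return out.sort_values(["da", "pathway_id"], ascending=[False, True]).reset_index(
        drop=True
    )


def classify_volcano(
    per_metabolite: pd.DataFrame, alpha: float = 0.05, log2fc_cutoff: float = 0.0
) -> pd.Series:
    """Volcano-style class per metabolite: up / down / ns.

    Significance requires q < alpha and |log2fc| > cutoff (cutoff defaults
    to 0, i.e. significance alone decides).
    """
    sig = (per_metabolite["q"] < alpha) & (per_metabolite["log2fc"].abs() > log2fc_cutoff)
    return pd.Series(
        np.where(sig & (per_metabolite["log2fc"] > 0), "up",
                 np.where(sig & (per_metabolite["log2fc"] < 0), "down", "ns")),
        index=per_metabolite.index,
        name="volcano_class",
    )
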