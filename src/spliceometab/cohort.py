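"""Distribution distances of spliceosome expression between sample groups.

The distance between two samples is the root-mean-square difference
(r.m.s.d.) of their log-expression over a configured gene subset — e.g. the
42 tumor-upregulated or the 109 core spliceosome genes. Comparisons pair a
tumor stratum with its matched normals (matched-pairs policy) or take all
tumor x normal combinations (all-cross-pairs, used for the
normal-vs-normal baseline). Distance distributions are compared by the
two-sided Wilcoxon rank-sum test pairwise and by Kruskal–Wallis across
three or more strata.

A per-sample pathway-activity score (gene-wise z-score, averaged within
sample over the pathway's genes) is bundled for correlating spliceosome
gene expression with metabolic pathway activity by Spearman's rho; any
external per-sample enrichment score can be substituted — only the
correlation structure matters downstream.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("spliceometab")

__all__ = [
    "ExpressionCohort",
    "Comparison",
    "pair_rmsd",
    "group_distances",
    "ss_enrichment",
    "correlate",
]


@dataclass
class ExpressionCohort:
    """Log-expression genes x samples plus sample annotations.

    ``annot`` needs columns sample, type (tumor/normal), subtype, pair_id;
    a pair_id links at most one tumor to one normal.
    """

    expr: pd.DataFrame
    annot: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sample", "type", "subtype", "pair_id"} - set(self.annot.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        unknown = set(self.annot["sample"]) - set(self.expr.columns)
        if unknown:
            raise ValueError(f"annotated samples absent from matrix: {sorted(unknown)[:5]}")
        dup = self.annot.groupby(["pair_id", "type"]).size()
        if (dup > 1).any():
            bad = dup[dup > 1].index.tolist()
            raise ValueError(f"pair_id links more than one sample of a type: {bad[:5]}")


@dataclass
class Comparison:
    """One distance stratum: tumor samples of a subtype vs normals."""

    label: str
    stratum_a: dict  # annotation filters, e.g. {"type": "tumor", "subtype": "MPS1"}
    stratum_b: dict
    policy: str = "matched-pairs"  # or "all-cross-pairs"


def pair_rmsd(vector_a: pd.Series, vector_b: pd.Series, gene_subset) -> float:
    """sqrt(mean squared log-expression difference) over a gene subset.

    Genes missing a value in either vector are dropped with a log record;
    an empty effective subset is an error.
    """
    genes = [g for g in gene_subset if g in vector_a.index and g in vector_b.index]
    a = vector_a.loc[genes].to_numpy(dtype=float)
    b = vector_b.loc[genes].to_numpy(dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    if keep.sum() < len(genes):
        logger.info("pair_rmsd: dropped %d genes with missing values", len(genes) - keep.sum())
    if keep.sum() == 0:
        raise ValueError("no usable genes in subset")
    d = a[keep] - b[keep]
    return float(np.sqrt(np.mean(d * d)))


def _select(annot: pd.DataFrame, filters: dict) -> pd.DataFrame:
    mask = pd.Series(True, index=annot.index)
    for col, val in filters.items():
        mask &= annot[col] == val
    return annot[mask]


def group_distances(
    cohort: ExpressionCohort,
    comparisons: list[Comparison],
    gene_subset,
) -> dict:
    """r.m.s.d. distributions per comparison plus rank tests between them.

    matched-pairs: only samples sharing a pair_id across the two strata are
    used (unpaired samples excluded with a log record); all-cross-pairs:
    every cross combination contributes one distance. Comparisons yielding
    fewer than 2 pairs are dropped with a warning. Returns
    {"distances": long frame, "pairwise": Wilcoxon frame, "kruskal": (H, p)
    or None}.
    """
    dist_rows = []
    kept: dict[str, list[float]] = {}
    for comp in comparisons:
        ann_a = _select(cohort.annot, comp.stratum_a)
        ann_b = _select(cohort.annot, comp.stratum_b)
        pairs: list[tuple[str, str]] = []
        if comp.policy == "matched-pairs":
            by_pair_b = ann_b.set_index("pair_id")["sample"]
            for pid, sa in zip(ann_a["pair_id"], ann_a["sample"]):
                if pid in by_pair_b.index:
                    pairs.append((sa, by_pair_b.loc[pid]))
                else:
                    logger.info("group_distances[%s]: %s lacks a partner, excluded",
                                comp.label, sa)
        elif comp.policy == "all-cross-pairs":
            pairs = [
                (sa, sb)
                for sa, sb in itertools.product(ann_a["sample"], ann_b["sample"])
                if sa != sb
            ]
        else:
            raise ValueError(f"unknown pairing policy {comp.policy!r}")
        if len(pairs) < 2:
            logger.warning("group_distances: comparison %s has %d pairs (< 2), dropped",
                           comp.label, len(pairs))
            continue
        vals = [
            pair_rmsd(cohort.expr[sa], cohort.expr[sb], gene_subset) for sa, sb in pairs
        ]
        kept[comp.label] = vals
        dist_rows += [
            {"comparison": comp.label, "sample_a": sa, "sample_b": sb, "rmsd": v}
            for (sa, sb), v in zip(pairs, vals)
        ]

    pw_rows = []
    for (la, va), (lb, vb) in itertools.combinations(kept.items(), 2):
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        pw_rows.append({"comparison_a": la, "comparison_b": lb,
                        "u_statistic": float(res.statistic), "p": float(res.pvalue)})
    kruskal = None
    if len(kept) >= 3:
        h = stats.kruskal(*kept.values())
        kruskal = (float(h.statistic), float(h.pvalue))
    return {
        "distances": pd.DataFrame(dist_rows),
        "pairwise": pd.DataFrame(pw_rows),
        "kruskal": kruskal,
    }


def ss_enrichment(expr: pd.DataFrame, pathway_genes) -> pd.Series:
    """Per-sample pathway score: mean over genes of the gene's z-score.

    Genes are standardized across samples first, so each pathway's scores
    have cohort mean 0 by construction. Zero-variance genes are dropped
    with a warning; fewer than 2 usable genes is an error.
    """
    genes = [g for g in pathway_genes if g in expr.index]
    if len(genes) < 2:
        raise ValueError("pathway needs at least 2 genes present in the matrix")
    sub = expr.loc[genes].astype(float)
    sd = sub.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        logger.warning("ss_enrichment: dropped %d zero-variance genes", int((~keep).sum()))
    sub = sub[keep]
    if len(sub) < 2:
        raise ValueError("fewer than 2 genes with variance; cannot score")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    return z.mean(axis=0).rename("enrichment")


def correlate(x_scores, y_scores, method: str = "spearman") -> tuple[float, float]:
    """Spearman correlation with an exact permutation p for small n.

    Tie-average ranks; for n <= 9 the p-value enumerates all n!
    permutations (two-sided on |rho|), otherwise the usual t
    approximation.
    """
    if method != "spearman":
        raise ValueError("only method='spearman' is supported")
    x = np.asarray(x_scores, dtype=float)
    y = np.asarray(y_scores, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired scores with n >= 4")
    rho, p_t = stats.spearmanr(x, y)
    if len(x) <= 9:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                count += 1
        return float(rho), count / total
    return float(rho), float(p_t)
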