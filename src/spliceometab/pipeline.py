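"""Deterministic orchestration of the analysis stages.

One YAML config (one seed) drives the whole run: simulate → diff-ir →
site-features → da → sg-score → cohort-dist. Every stage writes plain-text
outputs under the configured directory and records its row counts in a
manifest keyed by a hash of the canonical config, so a re-run with the same
config and seed reproduces every file byte for byte. A failing stage stops
the run with the stage's name; dependents are never silently skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import read_fasta, read_gtf
from .cohort import Comparison, ExpressionCohort, correlate, group_distances, ss_enrichment
from .metabolites import classify_volcano, parse_metabolite_table, pathway_da, test_metabolites
from .sc_activity import (
    compare_proportions,
    find_threshold,
    label_cells,
    read_cell_matrix,
    score_cells,
)
from .splice_sites import build_site_model, extract_donor_window, intron_features
from .splicing import diff_ir
from .synthetic import (
    SimulationConfig,
    generate_annotation,
    generate_cells,
    generate_expression_cohort,
    generate_ir_counts,
    generate_metabolites,
    generate_qpcr,
)

logger = logging.getLogger("spliceometab")

STAGES = ["simulate", "diff-ir", "site-features", "da", "sg-score", "cohort-dist"]


def demo_config_path() -> Path:
    """Bundled YAML config for the end-to-end synthetic demonstration."""
    return Path(__file__).parent / "data" / "demo_config.yaml"

_THRESHOLD_KEYS = {"fdr", "dpsi", "alpha", "top_fraction"}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "spliceometab_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    fdr: float = 0.05
    dpsi: float = 0.02
    alpha: float = 0.05
    top_fraction: float = 0.05
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        thresholds = d.pop("thresholds", {})
        unknown = set(thresholds) - _THRESHOLD_KEYS
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        known = {"seed", "outdir", "stages", "simulation"}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for s in d.get("stages", []):
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
        return cls(**d, **thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "stages": self.stages,
            "thresholds": {
                "fdr": self.fdr,
                "dpsi": self.dpsi,
                "alpha": self.alpha,
                "top_fraction": self.top_fraction,
            },
            "simulation": dict(sorted(self.simulation.items())),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _default_pathway_spec() -> dict[str, dict[str, float]]:
    """Three synthetic pathways: coordinately up, down, and null."""
    spec = {
        "glycolysis_up": {f"met_up_{i:02d}": 2.0 for i in range(1, 9)},
        "lipid_down": {f"met_dn_{i:02d}": -2.0 for i in range(1, 9)},
        "null_pathway": {f"met_nl_{i:02d}": 0.0 for i in range(1, 9)},
    }
    # unannotated background metabolites keep the BH family honest
    spec["null_pathway"].update({f"met_bg_{i:02d}": 0.0 for i in range(1, 17)})
    return spec


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(seed=config.seed, **config.simulation)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }

    def record(stage: str, rows: int, outputs: list[str]) -> None:
        manifest["stages"][stage] = {"rows": rows, "outputs": sorted(outputs)}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                transcripts, genome, gt = generate_annotation(sim, outdir=out)
                counts, gt_counts = generate_ir_counts(transcripts, gt, sim)
                gt.merge(gt_counts)
                counts.to_csv(out / "counts.tsv", sep="\t", index=False)
                metab, gt_m = generate_metabolites(sim, _default_pathway_spec())
                gt.merge(gt_m)
                metab.to_csv(out / "metabolites.tsv", sep="\t", index=False)
                gene_set = [f"G{i + 1:04d}" for i in range(42)]
                cells, gt_c = generate_cells(sim, gene_set, outdir=out)
                gt.merge(gt_c)
                (out / "gene_set.txt").write_text("\n".join(gene_set) + "\n")
                # per-cell patient-response groups, enriched for SG+ responders
                rng = np.random.default_rng([131, sim.seed])
                cells_order = list(cells.columns)
                p_resp = np.array(
                    [0.6 if gt.true_cell_label[c] == "SG+" else 0.4 for c in cells_order]
                )
                groups = np.where(rng.random(len(cells_order)) < p_resp,
                                  "responder", "non-responder")
                pd.DataFrame({"cell_id": cells_order, "group": groups}).to_csv(
                    out / "cell_groups.tsv", sep="\t", index=False
                )
                expr, annot = generate_expression_cohort(sim)
                expr.to_csv(out / "cohort_expr.tsv", sep="\t")
                annot.to_csv(out / "cohort_annot.tsv", sep="\t", index=False)
                qpcr = generate_qpcr(0.25, noise_sd=sim.noise_sd / 5, replicates=3,
                                     seed=sim.seed)
                qpcr.insert(0, "event_id", "demo_event")
                qpcr.to_csv(out / "qpcr.tsv", sep="\t", index=False)
                with open(out / "ground_truth.json", "w") as fh:
                    json.dump(gt.to_dict(), fh, sort_keys=True, indent=1)
                record(stage, len(counts), [
                    "annotation.gtf", "genome.fa", "counts.tsv", "metabolites.tsv",
                    "cells.mtx", "genes.txt", "barcodes.txt", "gene_set.txt",
                    "cell_groups.tsv", "cohort_expr.tsv", "cohort_annot.tsv",
                    "qpcr.tsv", "ground_truth.json",
                ])

            elif stage == "diff-ir":
                counts = pd.read_csv(out / "counts.tsv", sep="\t")
                events = diff_ir(counts, "control", "knockdown",
                                 fdr_threshold=config.fdr, dpsi_threshold=config.dpsi)
                events.to_csv(out / "events.tsv", sep="\t", index=False)
                record(stage, len(events), ["events.tsv"])

            elif stage == "site-features":
                transcripts = read_gtf(out / "annotation.gtf")
                genome = read_fasta(out / "genome.fa")
                events = pd.read_csv(out / "events.tsv", sep="\t")
                retained = set(events.loc[events["significant"], "event_id"])
                feats = intron_features(transcripts, genome, retained)
                feats.to_csv(out / "features.tsv", sep="\t", index=False)
                ri_ids = set(feats.loc[feats["retained"], "event_id"])
                donors = [
                    extract_donor_window(t, int(e.rsplit(".I", 1)[1]) - 1, genome)
                    for t in transcripts
                    for e in sorted(ri_ids)
                    if e.rsplit(".I", 1)[0] == t.gene_id
                ]
                if donors:
                    model = build_site_model(donors, "donor")
                    model.to_frame().to_csv(out / "motif_donor.tsv", sep="\t")
                record(stage, len(feats), ["features.tsv", "motif_donor.tsv"])

            elif stage == "da":
                table = pd.read_csv(out / "metabolites.tsv", sep="\t")
                abundance, membership = parse_metabolite_table(table)
                groups_a = [c for c in abundance.columns if c.startswith("A_")]
                groups_b = [c for c in abundance.columns if c.startswith("B_")]
                per_met = test_metabolites(abundance, groups_a, groups_b,
                                           alpha=config.alpha)
                per_met["volcano_class"] = classify_volcano(per_met, alpha=config.alpha)
                per_met.to_csv(out / "metabolite_tests.tsv", sep="\t")
                da = pathway_da(abundance, membership, groups_a, groups_b,
                                alpha=config.alpha)
                da.to_csv(out / "pathway_da.tsv", sep="\t", index=False)
                record(stage, len(da), ["metabolite_tests.tsv", "pathway_da.tsv"])

            elif stage == "sg-score":
                cells = read_cell_matrix(out / "cells.mtx", out / "genes.txt",
                                         out / "barcodes.txt")
                gene_set = (out / "gene_set.txt").read_text().split()
                aucs = score_cells(cells, gene_set, top_fraction=config.top_fraction)
                thr = find_threshold(aucs)
                labels = label_cells(aucs, thr.threshold)
                pd.DataFrame({"cell_id": aucs.index, "auc": aucs.values,
                              "label": labels.values}).to_csv(
                    out / "cell_activity.tsv", sep="\t", index=False)
                groups = pd.read_csv(out / "cell_groups.tsv", sep="\t").set_index(
                    "cell_id")["group"]
                stat, p, tab = compare_proportions(labels, groups.loc[labels.index])
                props = (tab.loc["SG+"] / tab.sum(axis=0)).to_dict()
                summary = {
                    "threshold": thr.threshold,
                    "threshold_method": thr.method,
                    "n_sg_pos": int((labels == "SG+").sum()),
                    "n_sg_neg": int((labels == "SG-").sum()),
                    "sg_pos_proportion_by_group": props,
                    "chi_square": stat,
                    "chi_square_p": p,
                }
                with open(out / "sg_summary.json", "w") as fh:
                    json.dump(summary, fh, sort_keys=True, indent=1)
                record(stage, len(labels), ["cell_activity.tsv", "sg_summary.json"])

            elif stage == "cohort-dist":
                expr = pd.read_csv(out / "cohort_expr.tsv", sep="\t", index_col=0)
                annot = pd.read_csv(out / "cohort_annot.tsv", sep="\t")
                cohort = ExpressionCohort(expr=expr, annot=annot)
                subset = expr.index[:42].tolist()
                comps = [
                    Comparison(f"{st}-vs-normal",
                               {"type": "tumor", "subtype": st},
                               {"type": "normal", "subtype": st})
                    for st in sorted(annot["subtype"].unique())
                ] + [
                    Comparison("normal-vs-normal", {"type": "normal"},
                               {"type": "normal"}, policy="all-cross-pairs")
                ]
                res = group_distances(cohort, comps, subset)
                res["distances"].to_csv(out / "distances.tsv", sep="\t", index=False)
                res["pairwise"].to_csv(out / "distance_tests.tsv", sep="\t", index=False)
                ss = ss_enrichment(expr, subset)
                other = ss_enrichment(expr, expr.index[42:84].tolist())
                rho, p = correlate(ss.values, other.values)
                pd.DataFrame([
                    {"x": "spliceosome_set", "y": "pathway_set", "rho": rho, "p": p}
                ]).to_csv(out / "correlation.tsv", sep="\t", index=False)
                record(stage, len(res["distances"]),
                       ["distances.tsv", "distance_tests.tsv", "correlation.tsv"])
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
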