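"""Intron-retention PSI, differential retention, qPCR PSI, and PTC calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceometab import (
    SimulationConfig,
    compute_psi,
    detect_ptc,
    diff_ir,
    generate_annotation,
    generate_ir_counts,
    qpcr_psi,
    qpcr_table,
)

from .conftest import make_transcript
from .oracles import bh_adjust, fisher_exact_two_sided, translate_first_stop


class TestComputePsi:
    @pytest.mark.parametrize(
        "ir,sj,expected", [(0, 50, 0.0), (30, 30, 0.5), (10, 30, 0.25)]
    )
    def test_count_ratio(self, ir, sj, expected):
        assert compute_psi(ir, sj) == expected

    def test_no_evidence_is_missing_not_zero(self):
        assert math.isnan(compute_psi(0, 0))

    @given(ir=st.integers(0, 10_000), sj=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_bounded(self, ir, sj):
        psi = compute_psi(ir, sj)
        assert math.isnan(psi) or 0.0 <= psi <= 1.0


class TestQpcrPsi:
    def test_equal_cts_give_full_retention(self):
        assert qpcr_psi(20.0, 20.0) == 1.0

    def test_five_cycle_difference(self):
        assert qpcr_psi(20.0, 25.0) == 2.0**-5

    def test_out_of_range_returned_and_flagged(self):
        df = qpcr_table(pd.DataFrame({"ct_all": [25.0, 20.0], "ct_in": [20.0, 22.0]}))
        assert df["psi"].tolist() == [32.0, 0.25]
        assert df["out_of_range"].tolist() == [True, False]

    def test_monotone_decreasing_in_ct_in(self):
        cts = np.linspace(18, 30, 25)
        psis = [qpcr_psi(20.0, c) for c in cts]
        assert all(a > b for a, b in zip(psis, psis[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            qpcr_psi(float("nan"), 20.0)


class TestDiffIr:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["event_id", "sample", "condition", "ir_reads", "sj_reads"]
        )

    def test_identical_counts_not_significant(self):
        t = self._table(
            [("e1", "a1", "ctl", 10, 90), ("e1", "b1", "kd", 10, 90)]
        )
        res = diff_ir(t, "ctl", "kd")
        assert res.loc[0, "p_value"] == 1.0
        assert not res.loc[0, "significant"]
        assert res.loc[0, "delta_psi"] == 0.0

    @pytest.mark.parametrize(
        "cells",
        [(1, 99, 50, 50), (5, 5, 5, 5), (0, 40, 12, 28), (33, 17, 8, 92), (2, 3, 4, 1)],
    )
    def test_fisher_matches_hypergeometric_enumeration(self, cells):
        ir_a, sj_a, ir_b, sj_b = cells
        t = self._table(
            [("e1", "a1", "ctl", ir_a, sj_a), ("e1", "b1", "kd", ir_b, sj_b)]
        )
        res = diff_ir(t, "ctl", "kd")
        expected = fisher_exact_two_sided(ir_a, sj_a, ir_b, sj_b)
        assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_delta_sign_is_b_minus_a(self):
        t = self._table(
            [("e1", "a1", "ctl", 10, 90), ("e1", "b1", "kd", 40, 60)]
        )
        res = diff_ir(t, "ctl", "kd")
        assert res.loc[0, "delta_psi"] == pytest.approx(0.3)

    def test_unknown_group_rejected(self):
        t = self._table([("e1", "a1", "ctl", 1, 1)])
        with pytest.raises(ValueError, match="unknown group"):
            diff_ir(t, "ctl", "nope")

    def test_zero_count_event_skipped(self):
        t = self._table(
            [
                ("e1", "a1", "ctl", 0, 0),
                ("e1", "b1", "kd", 10, 10),
                ("e2", "a1", "ctl", 5, 5),
                ("e2", "b1", "kd", 5, 5),
            ]
        )
        res = diff_ir(t, "ctl", "kd")
        assert res["event_id"].tolist() == ["e2"]

    def test_bh_invariant_to_row_order(self, rng):
        rows = []
        for i in range(20):
            ir_a, ir_b = rng.integers(0, 50, 2)
            rows += [
                (f"e{i}", "a1", "ctl", int(ir_a), 50),
                (f"e{i}", "b1", "kd", int(ir_b), 50),
            ]
        t = self._table(rows)
        res1 = diff_ir(t, "ctl", "kd").set_index("event_id")
        shuffled = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res2 = diff_ir(shuffled, "ctl", "kd").set_index("event_id")
        pd.testing.assert_series_equal(res1["fdr"], res2["fdr"])

    def test_bh_matches_stepup_arithmetic(self):
        # plant four events with distinct p-values, then compare to the
        # direct step-up computation on those same raw values
        rows = []
        for i, (ir_b) in enumerate([30, 24, 20, 10]):
            rows += [
                (f"e{i}", "a1", "ctl", 10, 90),
                (f"e{i}", "b1", "kd", ir_b, 100 - ir_b),
            ]
        res = diff_ir(self._table(rows), "ctl", "kd")
        expected = bh_adjust(res["p_value"].tolist())
        assert res["fdr"].tolist() == pytest.approx(expected, rel=1e-12)

    def test_recovery_of_injected_retention(self):
        cfg = SimulationConfig(seed=42, n_genes=100, weak_fraction=0.5,
                               depth=200, ir_effect=0.3, n_samples_per_group=3)
        tx, genome, gt = generate_annotation(cfg)
        counts, gt = generate_ir_counts(tx, gt, cfg)
        res = diff_ir(counts, "control", "knockdown").set_index("event_id")
        truth = {
            f"{g}.I1": weak for g, weak in gt.weak_donor_genes.items()
        }
        called = set(res.index[res["significant"]])
        true_events = {e for e, w in truth.items() if w}
        sensitivity = len(called & true_events) / len(true_events)
        assert sensitivity >= 0.9
        if called:
            fdr_obs = len(called - true_events) / len(called)
            assert fdr_obs <= 0.1


class TestDetectPtc:
    def test_in_frame_intron_without_stop(self):
        # 90-nt stop-free intron: frame preserved, no premature truncation
        t, genome = make_transcript(
            ["ATGGCA" * 10, "GCAGCA" * 9 + "TAAGCA"], ["GGC" * 30]
        )
        res = detect_ptc(t, 0, genome)
        assert not res.frameshift
        assert not res.truncation_flag

    def test_frameshift_from_length_mod_three(self):
        t, genome = make_transcript(
            ["ATGGCA" * 10, "GCAGCA" * 9 + "TAAGCA"], ["G" + "GCC" * 30]
        )
        res = detect_ptc(t, 0, genome)
        assert res.frameshift

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_ptc_offset_matches_brute_force_translation(self, strand):
        # TAA planted in frame 0 at codon 5 of the intron
        exon1 = "ATGGCA" * 10  # 60 nt -> intron starts at codon 20
        intron = "GCC" * 5 + "TAA" + "GCC" * 24  # 90 nt
        exon2 = "GCAGCA" * 9 + "TAAGCA"
        t, genome = make_transcript([exon1, exon2], [intron], strand=strand)
        res = detect_ptc(t, 0, genome)
        retained = exon1 + intron + exon2
        assert t.retained_mrna(genome, 0) == retained
        expected = translate_first_stop(retained, len(exon1))
        assert res.ptc_offset == expected == 25
        assert res.truncation_flag

    def test_intron_index_out_of_range(self):
        t, genome = make_transcript(["ATGGCA" * 10, "GCA" * 20], ["GGC" * 30])
        with pytest.raises(IndexError):
            detect_ptc(t, 5, genome)
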