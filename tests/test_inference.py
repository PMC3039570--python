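"""Two-engine merge, identification rules, grouping, FDR calibration."""

import numpy as np
import pandas as pd
import pytest

from centralprot import inference as inf
from centralprot import synthetic as syn
from conftest import make_psm_rows

PEP1 = "ELVISLIVESK"
PEP2 = "PEPTIDEK"
PEP3 = "SAMPLEPEPK"


class TestMerge:
    def test_agreeing_spectrum_collapses(self):
        a = make_psm_rows([("S1", PEP2, 20.0, "P1")], engine="A")
        b = make_psm_rows([("S1", PEP2, 5.0, "P1")], engine="B")
        merged = inf.merge_engine_results(a, b)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert row.score_A == 20.0 and row.score_B == 5.0

    def test_conflicting_spectrum_removed(self):
        a = make_psm_rows([("S2", PEP2, 20.0, "P1")], engine="A")
        b = make_psm_rows([("S2", PEP1, 5.0, "P2")], engine="B")
        merged = inf.merge_engine_results(a, b)
        assert "S2" not in set(merged["spectrum_id"])

    def test_single_engine_spectrum_retained(self):
        a = make_psm_rows([("S3", PEP2, 20.0, "P1")], engine="A")
        b = make_psm_rows([], engine="B")
        merged = inf.merge_engine_results(a, b)
        assert set(merged["spectrum_id"]) == {"S3"}

    def test_duplicate_spectrum_within_engine_rejected(self):
        a = make_psm_rows(
            [("S1", PEP2, 20.0, "P1"), ("S1", PEP2, 21.0, "P1")], engine="A"
        )
        with pytest.raises(ValueError, match="duplicated spectrum_id"):
            inf.merge_engine_results(a, make_psm_rows([], engine="B"))

    def test_mixed_cell_lines_rejected(self):
        a = make_psm_rows([("S1", PEP2, 20.0, "P1")], cell_line="CL1")
        b = make_psm_rows([("S2", PEP2, 5.0, "P1")], cell_line="CL2", engine="B")
        with pytest.raises(ValueError, match="cell lines"):
            inf.merge_engine_results(a, b)

    def test_merge_never_adds_peptides(self, psm_data):
        """Discarding conflicts is contraction-only per protein."""
        tables, _ = psm_data
        a, b = tables[("CL1", "A")], tables[("CL1", "B")]
        merged = inf.merge_engine_results(a, b)
        before: dict = {}
        for table in (a, b):
            for r in table.itertuples(index=False):
                for pid in r.protein_ids.split(";"):
                    before.setdefault(pid, set()).add(r.peptide)
        for r in merged.itertuples(index=False):
            for pid in r.protein_ids:
                assert r.peptide in before[pid]


class TestIdentificationRules:
    SEQS = {"P1": PEP2 + PEP1 + PEP3 + "A" * 200, "P2": PEP1 + "A" * 400}

    def _evidence(self, rows, thresholds=inf.Thresholds(), seqs=None):
        a = make_psm_rows(rows, engine="A")
        merged = inf.merge_engine_results(a, make_psm_rows([], engine="B"))
        return inf.apply_identification_rules(
            merged, seqs or self.SEQS, thresholds
        )

    def test_two_peptides_above_primary_accept_and_export_additional(self):
        ev = self._evidence(
            [
                ("S1", PEP2, 19.0, "P1"),
                ("S2", PEP1, 20.0, "P1"),
                ("S3", PEP3, 12.0, "P1"),  # above additional only
                ("S4", "AAAAAAK", 9.0, "P1"),  # below additional
            ]
        )
        assert ev["P1"]["peptides"] == {PEP2, PEP1, PEP3}

    def test_single_peptide_below_sph_threshold_rejected(self):
        ev = self._evidence([("S1", PEP2, 49.0, "P1")])
        assert "P1" not in ev

    def test_sph_requires_coverage(self):
        # P2 is 411 residues; an 11-mer covers 2.7% >= 2.5%
        ev = self._evidence([("S1", PEP1, 55.0, "P2")])
        assert ev["P2"]["peptides"] == {PEP1}
        # 500 residues -> 2.2% coverage: rejected
        ev = self._evidence(
            [("S1", PEP1, 55.0, "P2")], seqs={"P2": PEP1 + "A" * 489}
        )
        assert "P2" not in ev

    def test_engine_b_needs_z_and_pvalue(self):
        # two primary passes; the bad-p peptide still exports via the
        # additional threshold (no P-value condition there)
        b = make_psm_rows(
            [
                ("S1", PEP2, 5.0, "P1", False, 0.0005),
                ("S2", PEP1, 4.6, "P1", False, 0.01),  # p too large for primary
                ("S3", PEP3, 4.8, "P1", False, 0.0001),
            ],
            engine="B",
        )
        merged = inf.merge_engine_results(make_psm_rows([], engine="A"), b)
        ev = inf.apply_identification_rules(merged, self.SEQS)
        assert ev["P1"]["peptides"] == {PEP1, PEP2, PEP3}
        # with only one valid primary pass the protein is rejected
        b2 = make_psm_rows(
            [
                ("S1", PEP2, 5.0, "P1", False, 0.0005),
                ("S2", PEP1, 4.6, "P1", False, 0.01),
            ],
            engine="B",
        )
        merged2 = inf.merge_engine_results(make_psm_rows([], engine="A"), b2)
        assert "P1" not in inf.apply_identification_rules(merged2, self.SEQS)

    def test_missing_sequence_for_sph_coverage_raises(self):
        with pytest.raises(KeyError, match="P9"):
            self._evidence([("S1", PEP1, 60.0, "P9")], seqs={})

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            inf.Thresholds(A_primary_score=18, A_additional_score=20)


def _ev(mapping):
    return {
        pid: {"peptides": frozenset(peps), "is_decoy": pid.startswith("DECOY")}
        for pid, peps in mapping.items()
    }


class TestGrouping:
    def test_identical_sets_merge(self):
        groups = inf.group_proteins(_ev({"P1": {"p1", "p2"}, "P2": {"p1", "p2"}}))
        assert len(groups) == 1
        assert groups[0].member_ids == {"P1", "P2"}
        assert groups[0].specific_peptides == {"p1", "p2"}

    def test_strict_subset_absorbed(self):
        groups = inf.group_proteins(_ev({"P1": {"p1", "p2"}, "P2": {"p2"}}))
        assert len(groups) == 1
        assert groups[0].member_ids == {"P1", "P2"}
        assert groups[0].peptides == {"p1", "p2"}

    def test_groups_without_specific_peptides_discarded(self):
        groups = inf.group_proteins(
            _ev({"P1": {"p1", "p2"}, "P2": {"p2", "p3"}, "P3": {"p1", "p3"}})
        )
        assert groups == []

    def test_order_independence(self):
        mapping = {
            "P1": {"p1", "p2"},
            "P2": {"p2"},
            "P3": {"p3", "p4"},
            "P4": {"p4", "p5"},
            "P5": {"p5"},
        }
        base = inf.group_proteins(_ev(mapping))
        for order in ([4, 2, 0, 3, 1], [1, 0, 4, 3, 2]):
            keys = list(mapping)
            shuffled = {keys[i]: mapping[keys[i]] for i in order}
            assert inf.group_proteins(_ev(shuffled)) == base

    def test_empty_evidence_rejected(self):
        with pytest.raises(ValueError):
            inf.group_proteins({})


class TestSpliceVariantFilter:
    def _group(self, members):
        return inf.ProteinGroup(
            member_ids=frozenset(members), peptides=frozenset({"p1"* 3}),
            specific_peptides=frozenset({"p1" * 3}),
        )

    def test_same_gene_isoforms_retained(self):
        gm = {"P1-1": "G1", "P1-2": "G1"}
        kept = inf.splice_variant_filter([self._group(["P1-1", "P1-2"])], gm)
        assert len(kept) == 1 and kept[0].gene_ids == {"G1"}

    def test_multi_gene_group_discarded(self):
        gm = {"P1": "G1", "P2": "G2"}
        assert inf.splice_variant_filter([self._group(["P1", "P2"])], gm) == []

    def test_singleton_retained(self):
        assert len(inf.splice_variant_filter([self._group(["P1"])], {"P1": "G1"})) == 1

    def test_missing_mapping_raises(self):
        with pytest.raises(KeyError, match="P2"):
            inf.splice_variant_filter([self._group(["P1", "P2"])], {"P1": "G1"})


class TestCalibration:
    def _grid(self):
        return [
            inf.Thresholds(),
            inf.Thresholds(
                A_primary_score=22, A_additional_score=12, A_sph_score=55,
                B_primary_z=5.0, B_additional_z=4.0, B_sph_z=6.5,
            ),
        ]

    def test_zero_decoys_selects_least_stringent(self, psm_data, sequences):
        tables, _ = psm_data
        cfg = syn.SyntheticConfig(seed=2, n_proteins=120, false_match_rate=0.0)
        prot = syn.generate_proteome(syn.SyntheticConfig(seed=1, n_proteins=120))
        clean, _ = syn.generate_psm_tables(prot, cfg)
        pairs = [(clean[("CL1", "A")], clean[("CL1", "B")])]
        res = inf.calibrate_group_fdr(pairs, sequences, self._grid())
        assert res.passed
        assert res.achieved_fdr == 0.0
        assert res.thresholds == self._grid()[0]

    def test_all_decoy_input_flags_failure(self, psm_data, sequences):
        tables, _ = psm_data
        a = tables[("CL1", "A")]
        a = a[a["is_decoy"]].reset_index(drop=True)
        b = tables[("CL1", "B")]
        b = b[b["is_decoy"]].reset_index(drop=True)
        res = inf.calibrate_group_fdr([(a, b)], sequences, self._grid())
        assert not res.passed

    def test_calibrated_fdr_meets_bound_on_synthetic_data(
        self, psm_data, sequences, small_config
    ):
        tables, truth = psm_data
        lines = [f"CL{i+1}" for i in range(small_config.n_cell_lines)]
        pairs = [(tables[(cl, "A")], tables[(cl, "B")]) for cl in lines]
        res = inf.calibrate_group_fdr(pairs, sequences, self._grid())
        assert res.passed and res.achieved_fdr <= 0.0025
        false = total = 0
        for cl, (a, b) in zip(lines, pairs):
            groups = inf.run_inference_chain(a, b, sequences, res.thresholds)
            f, t = inf.realized_false_discovery(groups, truth.expressed[cl])
            false += f
            total += t
        assert total > 0
        assert false / total <= 0.0025 + 3 * np.sqrt(0.0025 / total)

    def test_empty_grid_rejected(self, sequences):
        with pytest.raises(ValueError):
            inf.calibrate_group_fdr([], sequences, [])
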