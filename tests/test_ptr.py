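"""Post-transcriptional regulation inference: quintile and transition rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haloatlas import atlas, ptr, simulate


class TestQuintileThresholds:
    def test_linear_interpolation_percentiles(self):
        q20, q80 = ptr.quintile_thresholds(list(range(1, 11)))
        assert q20 == pytest.approx(2.8)
        assert q80 == pytest.approx(8.2)

    def test_constant_vector(self):
        q20, q80 = ptr.quintile_thresholds([7.0] * 6)
        assert q20 == q80 == 7.0

    def test_undetected_values_excluded(self):
        values = list(range(1, 11)) + [np.nan] * 5
        assert ptr.quintile_thresholds(values) == ptr.quintile_thresholds(
            list(range(1, 11))
        )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            ptr.quintile_thresholds([1.0, 2.0, np.nan, np.nan, np.nan])


class TestAbsoluteApproach:
    @staticmethod
    def cohort(n=20):
        genes = [f"g{i}" for i in range(n)]
        mrna = pd.DataFrame({"TP1": np.arange(1.0, n + 1)}, index=genes)
        protein = pd.DataFrame({"TP1": np.arange(1.0, n + 1) * 10}, index=genes)
        return genes, mrna, protein

    def test_high_mrna_undetected_protein(self):
        genes, mrna, protein = self.cohort()
        protein.loc["g19", "TP1"] = np.nan
        calls = ptr.absolute_approach(mrna, protein)
        (call,) = [c for c in calls if c.gene_id == "g19"]
        assert call.category == "candidate_undetected"
        assert call.mrna_quintile == 5
        assert call.protein_status == "undetected"

    def test_high_mrna_low_protein(self):
        genes, mrna, protein = self.cohort()
        protein.loc["g19", "TP1"] = 1.0  # lowest detected protein
        (call,) = ptr.absolute_approach(mrna, protein)
        assert call.gene_id == "g19"
        assert call.category == "candidate_detected"
        assert call.protein_status == "quintile 1"

    def test_mid_mrna_undetected_protein_is_not_a_candidate(self):
        genes, mrna, protein = self.cohort()
        protein.loc["g10", "TP1"] = np.nan
        assert ptr.absolute_approach(mrna, protein) == []

    def test_concordant_cohort_has_no_candidates(self):
        _, mrna, protein = self.cohort()
        assert ptr.absolute_approach(mrna, protein) == []


class TestTrypticDigest:
    def test_cleaves_after_k_and_r(self):
        peptides, suitable = ptr.tryptic_digest("AAAKAAAAAAR")
        assert peptides == ["AAAK", "AAAAAAR"]
        assert suitable  # 7-mer present

    def test_no_cleavage_before_proline(self):
        peptides, _ = ptr.tryptic_digest("AKPAAAK")
        assert peptides == ["AKPAAAK"]

    def test_all_short_peptides_unsuitable(self):
        peptides, suitable = ptr.tryptic_digest("KRKRKR")
        assert not suitable
        assert all(len(p) < 7 for p in peptides)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            ptr.tryptic_digest("AAB1AA")

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    def test_peptides_concatenate_to_input(self, seq):
        peptides, _ = ptr.tryptic_digest(seq)
        assert "".join(peptides) == seq


class TestFilterUndetected:
    def test_each_exclusion_reason_logged(self):
        retained, log = ptr.filter_undetected(
            ["tm", "absent", "badpep", "ok"],
            tm_probability={"tm": 0.95, "ok": 0.1},
            in_assay_library={"tm", "badpep", "ok"},
            protein_seqs={
                "tm": "MKTAAAAAAK",
                "badpep": "KRKRKR",
                "ok": "MKTAAAAAAK",
            },
        )
        assert retained == ["ok"]
        reasons = dict(zip(log["gene_id"], log["reasons"]))
        assert reasons["tm"] == "transmembrane"
        assert reasons["absent"] == "not_in_assay_library"
        assert reasons["badpep"] == "no_suitable_tryptic_peptide"

    def test_exclusion_log_partitions_removed_genes(self):
        candidates = ["a", "b", "c"]
        retained, log = ptr.filter_undetected(
            candidates,
            tm_probability={"a": 0.99},
            in_assay_library={"a", "b", "c"},
            protein_seqs={},
        )
        assert sorted(retained + log["gene_id"].tolist()) == candidates
        assert log["gene_id"].is_unique

    def test_manual_exclusion_list(self):
        retained, log = ptr.filter_undetected(
            ["x"], {}, ["x"], {}, manual_exclusions=["x"]
        )
        assert retained == []
        assert log.loc[0, "reasons"] == "manual"


def de_table(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "transition", "lfc", "p", "p_adj"])
    return df.set_index("gene_id")


class TestRelativeApproach:
    def test_mrna_up_protein_down_detected(self):
        mrna = de_table([("g1", "TP1-TP2", 1.5, 0.001, 0.01)])
        protein = de_table([("g1", "TP1-TP2", -1.2, 0.002, 0.03)])
        (call,) = ptr.relative_approach(mrna, protein)
        assert call.category == "mrna_up_protein_down"

    def test_subthreshold_lfc_is_not_de(self):
        mrna = de_table([("g1", "t", 0.8, 0.001, 0.001)])
        protein = de_table([("g1", "t", -1.2, 0.002, 0.03)])
        (call,) = ptr.relative_approach(mrna, protein)
        assert call.category == "mrna_ns_protein_down"

    def test_insignificant_adjusted_p_not_counted(self):
        mrna = de_table([("g1", "t", 1.5, 0.001, 0.01)])
        protein = de_table([("g1", "t", -1.2, 0.01, 0.2)])
        (call,) = ptr.relative_approach(mrna, protein)
        assert call.category == "mrna_up_protein_ns"

    def test_raw_p_kind_for_array_contrasts(self):
        mrna = de_table([("g1", "t", 1.5, 0.01, 0.2)])
        protein = de_table([("g1", "t", -1.5, 0.01, 0.2)])
        (call,) = ptr.relative_approach(mrna, protein, p_kind="raw")
        assert call.category == "mrna_up_protein_down"

    def test_tightening_cuts_never_grows_candidate_class(self):
        rng = np.random.default_rng(9)
        rows_m, rows_p = [], []
        for i in range(60):
            rows_m.append((f"g{i}", "t", rng.normal(0, 2), 0.0, rng.random() * 0.1))
            rows_p.append((f"g{i}", "t", rng.normal(0, 2), 0.0, rng.random() * 0.1))
        mrna, protein = de_table(rows_m), de_table(rows_p)

        def n_candidates(lfc_cut, p_cut):
            calls = ptr.relative_approach(mrna, protein, lfc_cut=lfc_cut, p_cut=p_cut)
            return sum(c.category == "mrna_up_protein_down" for c in calls)

        assert n_candidates(1.5, 0.05) <= n_candidates(1.0, 0.05)
        assert n_candidates(1.0, 0.01) <= n_candidates(1.0, 0.05)


class TestNaiveDe:
    def test_identical_groups_are_null(self):
        table = pd.DataFrame(
            {"a1": [8.0], "a2": [8.0], "b1": [8.0], "b2": [8.0]}, index=["g"]
        )
        out = ptr.naive_de(table, ["a1", "a2"], ["b1", "b2"])
        assert out.loc["g", "lfc"] == 0
        assert out.loc["g", "p"] == 1.0

    def test_two_fold_shift_recovered_at_low_noise(self):
        rng = np.random.default_rng(10)
        base = rng.lognormal(3, 0.5, size=50)
        noise = lambda: rng.normal(1, 0.01, size=50)
        table = pd.DataFrame(
            {
                "a1": base * noise(),
                "a2": base * noise(),
                "a3": base * noise(),
                "b1": 2 * base * noise(),
                "b2": 2 * base * noise(),
                "b3": 2 * base * noise(),
            },
            index=[f"g{i}" for i in range(50)],
        )
        out = ptr.naive_de(table, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert out["lfc"].mean() == pytest.approx(1.0, abs=0.1)
        assert (out["p_adj"] < 0.05).mean() > 0.9

    def test_single_replicate_rejected(self):
        table = pd.DataFrame({"a1": [1.0], "b1": [2.0]})
        with pytest.raises(ValueError, match="replicates"):
            ptr.naive_de(table, ["a1"], ["b1"])


class TestIntegrateCandidates:
    def test_gene_in_both_approaches_gets_two_tags(self):
        q = [ptr.QuintileCall("g1", "TP1", 5, "undetected", "candidate_undetected")]
        t = [ptr.TransitionCall("g1", "TP1-TP2", 1.5, 0.01, -1.5, 0.01, "mrna_up_protein_down")]
        (cand,) = ptr.integrate_candidates(q, t)
        assert cand.evidence == {"absolute_undetected", "relative"}
        assert cand.timepoints == {"TP1"} and cand.transitions == {"TP1-TP2"}

    def test_empty_inputs_give_empty_output(self):
        assert ptr.integrate_candidates([], []) == []

    def test_disjoint_sets_add(self):
        q = [ptr.QuintileCall("g1", "TP1", 5, "quintile 1", "candidate_detected")]
        t = [ptr.TransitionCall("g2", "t", 1.5, 0.01, -1.5, 0.01, "mrna_up_protein_down")]
        candidates = ptr.integrate_candidates(q, t)
        assert [c.gene_id for c in candidates] == ["g1", "g2"]

    def test_non_candidate_calls_ignored(self):
        q = [ptr.QuintileCall("g1", "TP1", 3, "quintile 3", "none")]
        t = [ptr.TransitionCall("g2", "t", 1.5, 0.01, 1.5, 0.01, "mrna_up_protein_up")]
        assert ptr.integrate_candidates(q, t) == []


class TestPlantRecover:
    def test_noise_free_quintile_recovery_is_exact(self):
        protein, mrna, _, truth = simulate.gen_abundance_tables(
            400,
            planted_ptr_frac=0.05,
            missing_protein_frac=0.5,
            noise_sigma=0.0,
            protein_scatter=0.0,
            seed=14,
        )
        calls = ptr.absolute_approach(
            atlas.average_replicates(mrna), atlas.average_replicates(protein)
        )
        called = {c.gene_id for c in calls}
        planted = {r["gene_id"] for r in truth.records}
        assert called == planted

    def test_undetected_class_matches_truth(self):
        protein, mrna, _, truth = simulate.gen_abundance_tables(
            200, planted_ptr_frac=0.1, missing_protein_frac=0.5,
            noise_sigma=0.0, protein_scatter=0.0, seed=15,
        )
        calls = ptr.absolute_approach(
            atlas.average_replicates(mrna), atlas.average_replicates(protein)
        )
        undetected_called = {
            c.gene_id for c in calls if c.category == "candidate_undetected"
        }
        undetected_truth = {
            r["gene_id"] for r in truth.records if r["ptr_class"] == "undetected"
        }
        assert undetected_called == undetected_truth
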