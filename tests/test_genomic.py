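"""MAF parsing, class filtering, deduplication, synonym handling and tallies."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oncofreq import (
    MutationRecord,
    SampleInfo,
    conditional_matrix,
    dedup_samples,
    filter_mutation_classes,
    parse_maf,
    standardize_gene_names,
    tally_cohort,
)
from oncofreq.genomic import GenomicError, dedup_roster


def rec(patient, gene, cls="Missense_Mutation", study="s1", sample=None,
        order=1, date="2016-01-01"):
    return MutationRecord(
        study_id=study,
        patient_id=patient,
        sample_id=sample or f"{patient}-S{order}",
        gene_symbol=gene,
        variant_classification=cls,
        sample_order_hint=order,
        study_date=date,
    )


class TestParseMaf:
    MAF = (
        "#version 2.4\n"
        "Hugo_Symbol\tVariant_Classification\tTumor_Sample_Barcode\tPatient_ID\n"
        "TP53\tMissense_Mutation\tS-01-A\tP01\n"
        "KRAS\tSplice_Site\tS-01-A\tP01\n"
        "BRAF\tMissense_Mutation\tS-02-A\tP02\n"
    )

    def test_rows_and_comment_skipping(self, tmp_path):
        p = tmp_path / "toy.maf.tsv"
        p.write_text(self.MAF)
        records = parse_maf(p, study_id="s1", study_date="2016-01-01")
        assert len(records) == 3
        assert records[0].patient_id == "P01"
        assert records[2].gene_symbol == "BRAF"

    def test_missing_mandatory_column_is_error(self, tmp_path):
        p = tmp_path / "bad.maf.tsv"
        p.write_text("Hugo_Symbol\tTumor_Sample_Barcode\nTP53\tS-01\n")
        with pytest.raises(GenomicError, match="Variant_Classification"):
            parse_maf(p, study_id="s1")

    def test_barcode_prefix_patient_rule(self, tmp_path):
        p = tmp_path / "toy.maf.tsv"
        p.write_text(
            "Hugo_Symbol\tVariant_Classification\tTumor_Sample_Barcode\n"
            "TP53\tMissense_Mutation\tTCGA-AB-1234-01\n"
        )
        (r,) = parse_maf(p, study_id="s1", barcode_prefix_len=12)
        assert r.patient_id == "TCGA-AB-1234"


class TestClassFilter:
    @pytest.mark.parametrize(
        "cls, kept",
        [
            ("Missense_Mutation", True),
            ("missense", True),
            ("NONSENSE_MUTATION", True),
            ("In_Frame_Del", True),
            ("in frame ins", True),     # space dialect
            ("Frame_Shift_Del", True),
            ("Nonstop_Mutation", True),
            ("Splice_Site", False),
            ("Fusion", False),
            ("Silent", False),
            ("3'UTR", False),
        ],
    )
    def test_whitelist(self, cls, kept):
        out = filter_mutation_classes([rec("P1", "TP53", cls=cls)])
        assert (len(out) == 1) is kept


class TestDedup:
    def test_latest_study_wins_for_shared_patient(self):
        records = [
            rec("P", "TP53", study="A", date="2015-01-01"),
            rec("P", "KRAS", study="B", date="2018-01-01"),
        ]
        out = dedup_samples(records)
        assert [(r.study_id, r.gene_symbol) for r in out] == [("B", "KRAS")]

    def test_first_sample_wins_within_study(self):
        records = [
            rec("P", "TP53", order=1),
            rec("P", "EGFR", order=2),
        ]
        out = dedup_samples(records)
        assert [r.gene_symbol for r in out] == ["TP53"]

    def test_single_sample_patient_unchanged(self):
        records = [rec("P", "TP53"), rec("P", "KRAS")]
        assert dedup_samples(records) == records

    def test_date_tie_broken_lexicographically(self):
        records = [
            rec("P", "TP53", study="A", date="2018-01-01"),
            rec("P", "KRAS", study="B", date="2018-01-01"),
        ]
        out = dedup_samples(records)
        assert {r.study_id for r in out} == {"B"}

    def test_roster_guides_choice_when_first_sample_has_no_rows(self):
        # First sample exists but carries no mutation calls: without the
        # roster the second sample would wrongly survive.
        roster = [
            SampleInfo("s1", "P", "P-S1", 1, "2016-01-01"),
            SampleInfo("s1", "P", "P-S2", 2, "2016-01-01"),
        ]
        records = [rec("P", "TP53", order=2)]
        assert dedup_samples(records, roster=roster) == []
        assert [s.sample_id for s in dedup_roster(roster)] == ["P-S1"]


class TestStandardize:
    def test_alias_replaced(self):
        out = standardize_gene_names([rec("P", "MLL3")], {"MLL3": "KMT2C"})
        assert out[0].gene_symbol == "KMT2C"

    def test_unknown_symbol_passes_through(self):
        out = standardize_gene_names([rec("P", "TP53")], {"MLL3": "KMT2C"})
        assert out[0].gene_symbol == "TP53"

    def test_two_aliases_collapse_to_one_mutated_patient(self):
        records = standardize_gene_names(
            [rec("P", "MLL3", sample="P-S1"), rec("P", "KMT2C", sample="P-S1")],
            {"MLL3": "KMT2C"},
        )
        cohort = tally_cohort(records, {"P": "lung_ac"})
        assert cohort.m("KMT2C", "lung_ac") == 1


class TestTally:
    def test_multiplicity_collapses_to_presence(self):
        records = [rec("P", "TP53") for _ in range(3)]
        cohort = tally_cohort(records, {"P": "lung_ac"})
        assert cohort.m("TP53", "lung_ac") == 1
        assert cohort.n("lung_ac") == 1

    def test_zero_mutation_patient_counts_in_denominator(self):
        cohort = tally_cohort([rec("P1", "TP53")], {"P1": "lung_ac", "P2": "lung_ac"})
        assert cohort.n("lung_ac") == 2
        assert cohort.m("TP53", "lung_ac") == 1

    def test_unrostered_patient_is_error(self):
        with pytest.raises(GenomicError, match="unrostered"):
            tally_cohort([rec("P", "TP53")], {})

    def test_unmapped_patients_excluded(self):
        from oncofreq import UNMAPPED

        cohort = tally_cohort([rec("P", "TP53")], {"P": UNMAPPED})
        assert cohort.n(UNMAPPED) == 0
        assert cohort.genes() == []

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["P1", "P2", "P3", "P4"]),
                st.sampled_from(["TP53", "KRAS", "BRAF"]),
            ),
            max_size=40,
        )
    )
    def test_agrees_with_bruteforce_set_oracle(self, pairs):
        assignments = {"P1": "catA", "P2": "catA", "P3": "catB", "P4": "catB"}
        records = [rec(p, g) for p, g in pairs]
        cohort = tally_cohort(records, assignments)
        # Independent oracle: direct per-(gene, category) patient sets.
        for gene in {"TP53", "KRAS", "BRAF"}:
            for cat in {"catA", "catB"}:
                expected = {
                    p for p, g in pairs if g == gene and assignments[p] == cat
                }
                assert cohort.m(gene, cat) == len(expected)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["P1", "P2"]),
                st.sampled_from(["s_old", "s_new"]),
                st.sampled_from(["TP53", "KRAS"]),
                st.sampled_from(["Missense_Mutation", "Splice_Site"]),
            ),
            max_size=30,
        )
    )
    def test_filter_and_dedup_commute(self, rows):
        dates = {"s_old": "2014-01-01", "s_new": "2019-01-01"}
        roster = [
            SampleInfo(s, p, f"{p}-{s}", 1, dates[s])
            for p in ("P1", "P2")
            for s in ("s_old", "s_new")
        ]
        records = [
            rec(p, g, cls=c, study=s, sample=f"{p}-{s}", date=dates[s])
            for p, s, g, c in rows
        ]
        a = dedup_samples(filter_mutation_classes(records), roster=roster)
        b = filter_mutation_classes(dedup_samples(records, roster=roster))
        assert sorted(map(repr, a)) == sorted(map(repr, b))


class TestConditionalMatrix:
    def test_fractions(self):
        records = [rec("P1", "TP53"), rec("P2", "TP53")]
        assignments = {f"P{i}": "lung_ac" for i in range(1, 5)}
        C = conditional_matrix(tally_cohort(records, assignments))
        assert C.values.loc["TP53", "lung_ac"] == pytest.approx(0.5)
        assert C.n["lung_ac"] == 4

    def test_gene_universe_extension_gives_zero_rows(self):
        cohort = tally_cohort([rec("P", "TP53")], {"P": "lung_ac"})
        C = conditional_matrix(cohort, gene_universe=["NRAS"])
        assert C.values.loc["NRAS", "lung_ac"] == 0.0

    def test_empty_category_excluded(self):
        cohort = tally_cohort([rec("P", "TP53")], {"P": "lung_ac"})
        C = conditional_matrix(cohort)
        assert C.category_list == ["lung_ac"]
        assert ((C.values >= 0) & (C.values <= 1)).all().all()
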