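"""Weighted proportions, unions, subclass estimates and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oncofreq import (
    IncidenceVector,
    MutationRecord,
    compare_unweighted,
    contribution_breakdown,
    gene_set_view,
    subclass_estimates,
    tally_cohort,
    union_proportion,
    weighted_proportions,
)
from oncofreq.estimator import EstimatorError
from oncofreq.genomic import ConditionalMatrix, conditional_matrix


def make_C(values: dict[str, dict[str, float]], n: dict[str, int]) -> ConditionalMatrix:
    v = pd.DataFrame(values).T  # genes x categories
    nn = pd.Series(n, dtype=float).reindex(v.columns)
    m = v * nn
    return ConditionalMatrix(values=v, m=m, n=nn)


def sprime(values: dict[str, float]) -> IncidenceVector:
    return IncidenceVector(values, normalized=True)


class TestWeightedProportions:
    def test_hand_dot_product(self):
        C = make_C({"TP53": {"A": 0.5, "B": 0.1}}, {"A": 10, "B": 10})
        G = weighted_proportions(C, sprime({"A": 0.6, "B": 0.4}))
        assert G["TP53"] == pytest.approx(0.34)

    def test_single_category_identity(self):
        C = make_C({"TP53": {"A": 0.37}}, {"A": 100})
        G = weighted_proportions(C, sprime({"A": 1.0}))
        assert G["TP53"] == pytest.approx(0.37)

    def test_all_zero_row(self):
        C = make_C({"GENEX": {"A": 0.0, "B": 0.0}}, {"A": 5, "B": 5})
        assert weighted_proportions(C, sprime({"A": 0.5, "B": 0.5}))["GENEX"] == 0.0

    def test_misaligned_categories_error(self):
        C = make_C({"TP53": {"A": 0.5}}, {"A": 10})
        with pytest.raises(EstimatorError, match="differ"):
            weighted_proportions(C, sprime({"B": 1.0}))

    def test_unnormalized_sprime_rejected(self):
        C = make_C({"TP53": {"A": 0.5}}, {"A": 10})
        with pytest.raises(EstimatorError, match="normalized"):
            weighted_proportions(C, IncidenceVector({"A": 10.0}))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_loop(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(5)]
        cats = [f"c{i}" for i in range(4)]
        vals = pd.DataFrame(rng.random((5, 4)), index=genes, columns=cats)
        C = ConditionalMatrix(values=vals, m=vals * 10, n=pd.Series(10.0, index=cats))
        s = rng.dirichlet(np.ones(4))
        Sp = sprime(dict(zip(cats, s)))
        G = weighted_proportions(C, Sp)
        for g in genes:
            brute = sum(vals.loc[g, c] * Sp.values[c] for c in cats)
            assert abs(G[g] - brute) < 1e-12

    @given(st.integers(0, 2**31 - 1))
    def test_weighted_mean_bounds(self, seed):
        rng = np.random.default_rng(seed)
        cats = list("abcd")
        vals = pd.DataFrame(rng.random((3, 4)), index=list("xyz"), columns=cats)
        C = ConditionalMatrix(values=vals, m=vals, n=pd.Series(1.0, index=cats))
        Sp = sprime(dict(zip(cats, rng.dirichlet(np.ones(4)))))
        G = weighted_proportions(C, Sp)
        for g in "xyz":
            assert vals.loc[g].min() - 1e-12 <= G[g] <= vals.loc[g].max() + 1e-12


def _ras_cohort():
    """One category, 10 patients: KRAS in P0, NRAS in P1-P2, both in nobody."""
    records = [
        MutationRecord("s", "P0", "P0-S1", "KRAS", "Missense_Mutation"),
        MutationRecord("s", "P1", "P1-S1", "NRAS", "Missense_Mutation"),
        MutationRecord("s", "P2", "P2-S1", "NRAS", "Missense_Mutation"),
    ]
    assignments = {f"P{i}": "catA" for i in range(10)}
    return tally_cohort(records, assignments)


class TestUnionProportion:
    def test_disjoint_patients_add(self):
        cohort = _ras_cohort()
        u = union_proportion(cohort, ["KRAS", "NRAS"], sprime({"catA": 1.0}))
        assert u == pytest.approx(0.3)

    def test_identical_patient_sets_idempotent(self):
        records = [
            MutationRecord("s", "P0", "P0-S1", "KRAS", "Missense_Mutation"),
            MutationRecord("s", "P0", "P0-S1", "NRAS", "Missense_Mutation"),
        ]
        cohort = tally_cohort(records, {f"P{i}": "catA" for i in range(4)})
        u = union_proportion(cohort, ["KRAS", "NRAS"], sprime({"catA": 1.0}))
        assert u == pytest.approx(0.25)

    def test_single_gene_union_equals_weighted(self):
        cohort = _ras_cohort()
        C = conditional_matrix(cohort)
        Sp = sprime({"catA": 1.0})
        assert union_proportion(cohort, ["NRAS"], Sp) == pytest.approx(
            weighted_proportions(C, Sp)["NRAS"]
        )

    def test_bonferroni_bracket(self):
        cohort = _ras_cohort()
        Sp = sprime({"catA": 1.0})
        singles = [union_proportion(cohort, [g], Sp) for g in ("KRAS", "NRAS")]
        u = union_proportion(cohort, ["KRAS", "NRAS"], Sp)
        assert max(singles) <= u <= sum(singles) + 1e-12

    def test_empty_gene_set_error(self):
        with pytest.raises(EstimatorError):
            union_proportion(_ras_cohort(), [], sprime({"catA": 1.0}))


class TestSubclassEstimates:
    def test_two_equal_incidence_categories_average(self, toy_map):
        C = make_C(
            {"TP53": {"colorectal_ac": 0.2, "lung_ac": 0.4, "lung_scc": 0.9}},
            {"colorectal_ac": 10, "lung_ac": 10, "lung_scc": 10},
        )
        S = IncidenceVector({"colorectal_ac": 100, "lung_ac": 100, "lung_scc": 50})
        sub = subclass_estimates(C, S, "adenocarcinoma", toy_map)
        assert sub["TP53"] == pytest.approx(0.3)

    def test_single_category_subclass_equals_column(self, toy_map):
        C = make_C(
            {"TP53": {"colorectal_ac": 0.2, "lung_scc": 0.9}},
            {"colorectal_ac": 10, "lung_scc": 10},
        )
        S = IncidenceVector({"colorectal_ac": 100, "lung_scc": 50})
        sub = subclass_estimates(C, S, "squamous_cell_carcinoma", toy_map)
        assert sub["TP53"] == pytest.approx(0.9)

    def test_unsequenced_subclass_is_error(self, toy_map):
        C = make_C({"TP53": {"colorectal_ac": 0.2}}, {"colorectal_ac": 10})
        S = IncidenceVector({"colorectal_ac": 100, "melanoma": 10})
        with pytest.raises(Exception):
            subclass_estimates(C, S, "malignant_melanoma", toy_map)


class TestContributions:
    def test_hand_shares(self):
        C = make_C({"TP53": {"A": 0.06, "B": 0.02}}, {"A": 100, "B": 100})
        contribs = contribution_breakdown("TP53", C, sprime({"A": 0.5, "B": 0.5}))
        assert contribs == [("A", pytest.approx(0.75)), ("B", pytest.approx(0.25))]

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(0)
        cats = list("abcde")
        vals = pd.DataFrame(rng.random((1, 5)), index=["g"], columns=cats)
        C = ConditionalMatrix(values=vals, m=vals, n=pd.Series(1.0, index=cats))
        Sp = sprime(dict(zip(cats, rng.dirichlet(np.ones(5)))))
        contribs = contribution_breakdown("g", C, Sp)
        assert sum(s for _, s in contribs) == pytest.approx(1.0)
        assert [s for _, s in contribs] == sorted((s for _, s in contribs), reverse=True)

    def test_zero_gene_empty(self):
        C = make_C({"g": {"A": 0.0}}, {"A": 10})
        assert contribution_breakdown("g", C, sprime({"A": 1.0})) == []

    def test_single_category_full_share(self):
        C = make_C({"g": {"A": 0.2}}, {"A": 10})
        assert contribution_breakdown("g", C, sprime({"A": 1.0})) == [("A", 1.0)]


class TestCompareUnweighted:
    def test_oversampled_rare_category_inflates_pooled(self):
        # Rare cancer: 10% of incidence but 5x the cohort of the common one.
        C = make_C(
            {"MARKER": {"common": 0.02, "rare": 0.5}}, {"common": 200, "rare": 1000}
        )
        G = weighted_proportions(C, sprime({"common": 0.9, "rare": 0.1}))
        table = compare_unweighted(C, G)
        assert table.loc["MARKER", "pooled"] > table.loc["MARKER", "weighted"]
        assert table.loc["MARKER", "difference"] == pytest.approx(
            table.loc["MARKER", "pooled"] - table.loc["MARKER", "weighted"]
        )

    def test_proportional_sampling_pooled_equals_weighted(self):
        # Cohort sizes exactly proportional to incidence shares.
        C = make_C(
            {"g": {"A": 0.3, "B": 0.1}}, {"A": 600, "B": 400}
        )
        G = weighted_proportions(C, sprime({"A": 0.6, "B": 0.4}))
        table = compare_unweighted(C, G)
        assert table.loc["g", "difference"] == pytest.approx(0.0, abs=1e-12)

    def test_absent_gene_both_zero(self):
        C = make_C({"g": {"A": 0.0}}, {"A": 10})
        G = weighted_proportions(C, sprime({"A": 1.0}))
        table = compare_unweighted(C, G)
        assert table.loc["g", "pooled"] == 0.0 and table.loc["g", "weighted"] == 0.0


class TestGeneSetView:
    def test_ranking_and_missing_genes(self):
        G = pd.Series({"TP53": 0.3, "KRAS": 0.1})
        view = gene_set_view(G, ["KRAS", "TP53", "NEVERSEEN"], top_n=10)
        assert list(view["gene"]) == ["TP53", "KRAS", "NEVERSEEN"]
        assert view["proportion"].tolist() == pytest.approx([0.3, 0.1, 0.0])

    def test_truncation_and_tie_break(self):
        G = pd.Series({"B": 0.2, "A": 0.2, "C": 0.5})
        view = gene_set_view(G, ["A", "B", "C"], top_n=2)
        assert list(view["gene"]) == ["C", "A"]
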