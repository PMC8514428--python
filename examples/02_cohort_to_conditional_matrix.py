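"""From raw multi-study mutation calls to the conditional matrix C.

Shows the three cleaning rules in action — variant-class whitelist,
first-sample / latest-study deduplication, and gene-symbol standardization —
on a small hand-built record set.
"""

from oncofreq import (
    MutationRecord,
    SampleInfo,
    build_cohort_matrix,
    CategoryMap,
    StudyAssignment,
)

cmap = CategoryMap()
cmap.categories["lung_ac"] = "adenocarcinoma"
cmap.studies["old_study"] = StudyAssignment("old_study", default_category="lung_ac")
cmap.studies["new_study"] = StudyAssignment("new_study", default_category="lung_ac")
cmap.validate()

roster = [
    SampleInfo("old_study", "P1", "P1-S1", 1, "2015-01-01"),
    SampleInfo("old_study", "P1", "P1-S2", 2, "2015-01-01"),  # longitudinal follow-up
    SampleInfo("new_study", "P1", "P1-N1", 1, "2019-01-01"),  # re-published patient
    SampleInfo("new_study", "P2", "P2-N1", 1, "2019-01-01"),
    SampleInfo("new_study", "P3", "P3-N1", 1, "2019-01-01"),  # sequenced, no mutations
]
records = [
    # P1 in the old study: superseded by new_study, so these never count.
    MutationRecord("old_study", "P1", "P1-S1", "TP53", "Missense_Mutation", 1, "2015-01-01"),
    MutationRecord("old_study", "P1", "P1-S2", "EGFR", "Missense_Mutation", 2, "2015-01-01"),
    # P1 re-published: two calls in one gene still count the patient once.
    MutationRecord("new_study", "P1", "P1-N1", "TP53", "Nonsense_Mutation", 1, "2019-01-01"),
    MutationRecord("new_study", "P1", "P1-N1", "TP53", "Missense_Mutation", 1, "2019-01-01"),
    # P2: an alias symbol, and a splice-site call that the whitelist drops.
    MutationRecord("new_study", "P2", "P2-N1", "MLL3", "Frame_Shift_Del", 1, "2019-01-01"),
    MutationRecord("new_study", "P2", "P2-N1", "KRAS", "Splice_Site", 1, "2019-01-01"),
]

cohort, C = build_cohort_matrix(roster, records, cmap, synonyms={"MLL3": "KMT2C"})
print("denominator n(lung_ac):", cohort.n("lung_ac"), "(P1, P2, P3 — one each)")
print("counts m per gene:", {g: cohort.m(g, "lung_ac") for g in cohort.genes()})
print("conditional matrix C:")
print(C.values.round(3))
# TP53 1/3 (P1 once, from the latest study), KMT2C 1/3 (alias standardized),
# EGFR 0 (follow-up sample dropped), KRAS 0 (splice-site excluded).
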