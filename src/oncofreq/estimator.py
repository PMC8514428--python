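"""Incidence-weighted mutation proportion estimates.

The population-level probability that a newly diagnosed cancer carries a
qualifying mutation in gene g is the incidence-weighted average of the
per-category conditional rates:

    G_g = sum_h c_gh * s'_h          (in matrix form G = C · S')

where c_gh is the mutated fraction among sequenced patients of category h
and s'_h is the category's share of incidence among sequenced categories,
renormalized to sum to 1.  The estimate over the sequenced coverage is
reported as the estimate for all cancers, under the stated assumption that
the unsequenced remainder behaves like the sequenced majority; the coverage
fraction is always carried alongside so that assumption stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CategoryMap
from .epi import IncidenceVector, restrict_and_normalize, subclass_vector
from .genomic import ConditionalMatrix, MutationCohort


class EstimatorError(ValueError):
    pass


@dataclass
class ProportionEstimate:
    """Per-gene weighted proportions with optional CIs and coverage context."""

    estimates: pd.Series
    ci: pd.DataFrame | None = None
    coverage: float | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"proportion": self.estimates})
        if self.ci is not None:
            df["ci_low"] = self.ci["ci_low"]
            df["ci_high"] = self.ci["ci_high"]
        return df.sort_values("proportion", ascending=False, kind="mergesort")


def _aligned_shares(C: ConditionalMatrix, S_prime: IncidenceVector) -> pd.Series:
    if not S_prime.normalized:
        raise EstimatorError("S' must be normalized (use restrict_and_normalize)")
    if set(C.category_list) != S_prime.categories():
        missing = set(C.category_list) ^ S_prime.categories()
        raise EstimatorError(
            f"category lists of C and S' differ (no silent reindexing): {sorted(missing)}"
        )
    return pd.Series(S_prime.values).reindex(C.category_list)


def weighted_proportions(C: ConditionalMatrix, S_prime: IncidenceVector) -> pd.Series:
    """G = C · S': per-gene weighted mutation proportion over the categories of C."""
    s = _aligned_shares(C, S_prime)
    return pd.Series(C.values.to_numpy() @ s.to_numpy(), index=C.gene_list, name="proportion")


def contribution_breakdown(
    gene: str, C: ConditionalMatrix, S_prime: IncidenceVector
) -> list[tuple[str, float]]:
    """Decompose a gene's weighted proportion into per-category shares.

    Share of category h is c_gh·s'_h / G_g, sorted descending (ties broken
    by category id).  Empty when G_g = 0.
    """
    s = _aligned_shares(C, S_prime)
    if gene not in C.values.index:
        raise EstimatorError(f"gene {gene!r} not in conditional matrix")
    terms = C.values.loc[gene] * s
    total = float(terms.sum())
    if total <= 0:
        return []
    shares = (terms / total).sort_index()
    return sorted(shares.items(), key=lambda kv: (-kv[1], kv[0]))


def union_proportion(
    cohort: MutationCohort, genes: Iterable[str], S_prime: IncidenceVector
) -> float:
    """Weighted probability of a mutation in ANY listed gene.

    Computed from patient sets (a patient mutated in several listed genes
    counts once), which is why this needs the cohort: co-mutation makes the
    union smaller than the sum of single-gene proportions, and C alone
    cannot express that.
    """
    genes = list(genes)
    if not genes:
        raise EstimatorError("union over an empty gene set")
    if not S_prime.normalized:
        raise EstimatorError("S' must be normalized")
    cats_with_patients = {c for c in cohort.categories() if cohort.n(c) > 0}
    if cats_with_patients != S_prime.categories():
        missing = cats_with_patients ^ S_prime.categories()
        raise EstimatorError(f"category lists of cohort and S' differ: {sorted(missing)}")
    total = 0.0
    for cat, share in S_prime.values.items():
        u = len(cohort.patients_mutated_in_any(genes, cat)) / cohort.n(cat)
        total += u * share
    return total


def subclass_estimates(
    C: ConditionalMatrix, S: IncidenceVector, subclass_tag: str, cmap: CategoryMap
) -> pd.Series:
    """Weighted proportions restricted to one histological subclass.

    The incidence vector is filtered to categories carrying the tag, then to
    those with sequencing data, and renormalized; genes are then weighted
    within the subclass only.
    """
    sub = subclass_vector(S, subclass_tag, cmap)
    sequenced = set(C.category_list) & sub.categories()
    if not sequenced:
        raise EstimatorError(f"subclass {subclass_tag!r} has no sequenced categories")
    sub_prime = restrict_and_normalize(sub, sequenced)
    sub_C = ConditionalMatrix(
        values=C.values[sorted(sequenced)],
        m=C.m[sorted(sequenced)],
        n=C.n[sorted(sequenced)],
    )
    return weighted_proportions(sub_C, sub_prime)


def compare_unweighted(C: ConditionalMatrix, G: pd.Series) -> pd.DataFrame:
    """Contrast the incidence-weighted estimate with the naive pooled rate.

    The pooled rate sum_h m_gh / sum_h n_h treats the concatenated cohorts
    as if they sampled cancer diagnoses representatively; the difference
    column quantifies the bias cohort composition introduces.
    """
    pooled = C.m.sum(axis=1) / float(C.n.sum())
    df = pd.DataFrame(
        {"pooled": pooled, "weighted": G.reindex(pooled.index)}
    )
    df["difference"] = df["pooled"] - df["weighted"]
    return df


def gene_set_view(
    G: pd.Series, gene_list: Sequence[str], top_n: int | None = None
) -> pd.DataFrame:
    """Rank a gene set by weighted proportion (absent genes report 0)."""
    sub = G.reindex(gene_list).fillna(0.0)
    sub = sub.iloc[np.lexsort((sub.index, -sub.to_numpy()))]
    if top_n is not None:
        sub = sub.iloc[:top_n]
    return pd.DataFrame({"gene": sub.index, "proportion": sub.to_numpy()}).reset_index(drop=True)


def pooled_frequencies(C: ConditionalMatrix) -> pd.Series:
    """Sample-pooled per-gene fraction, ignoring incidence weights."""
    return C.m.sum(axis=1) / float(C.n.sum())
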