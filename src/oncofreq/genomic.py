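"""Mutation-call ingestion and aggregation.

Takes MAF-style per-mutation tables from many sequencing studies and turns
them into the per-category conditional mutation matrix C, whose entry
c_gh = m_gh / n_h is the fraction of sequenced patients in category h with
at least one qualifying mutation in gene g.

Qualifying means the variant class is in a fixed whitelist of missense,
nonsense, small in-frame and frameshift indel, and nonstop calls; splice-site
and fusion calls are excluded.  Patients sampled repeatedly contribute only
their first sample; patients shared between studies contribute only from the
most recently dated study.  Gene symbols are standardized through a synonym
map before tallying, and multiplicity within a gene collapses to
presence/absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import UNMAPPED, CategoryMap

logger = logging.getLogger(__name__)

#: Variant classes counted as qualifying mutations (case-insensitive,
#: space/underscore-insensitive).  Everything else — splice site, fusion,
#: silent, UTR, intronic — is dropped.
QUALIFYING_CLASSES = frozenset(
    {
        "nonsense_mutation",
        "frame_shift_del",
        "frame_shift",
        "frame_shift_ins",
        "missense_mutation",
        "missense",
        "nonsense",
        "in_frame_del",
        "in_frame_ins",
        "nonstop_mutation",
    }
)


class GenomicError(ValueError):
    pass


def normalize_variant_class(token: str) -> str:
    return token.strip().lower().replace(" ", "_")


@dataclass(frozen=True)
class MutationRecord:
    """One mutation call row, tagged with enough identity to deduplicate."""

    study_id: str
    patient_id: str
    sample_id: str
    gene_symbol: str
    variant_classification: str
    sample_order_hint: int = 0
    study_date: str = ""


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample from a study roster (mutated or not).

    The roster defines the denominator: a patient with zero qualifying
    mutation rows still counts as sequenced.
    """

    study_id: str
    patient_id: str
    sample_id: str
    sample_order_hint: int = 0
    study_date: str = ""
    metadata: tuple[tuple[str, str], ...] = ()

    def metadata_dict(self) -> dict[str, str]:
        return dict(self.metadata)


@dataclass
class ManifestEntry:
    study_id: str
    study_date: str
    maf_path: str = ""
    samples_path: str = ""


# -- file readers -------------------------------------------------------------

_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


def parse_maf(
    path: str | Path,
    study_id: str,
    study_date: str = "",
    patient_column: str | None = "Patient_ID",
    barcode_prefix_len: int | None = None,
    sample_order_column: str = "Sample_Order",
) -> list[MutationRecord]:
    """Read a MAF-style TSV into mutation records.

    Comment lines starting with ``#`` (e.g. ``#version``) are skipped.
    Patient identity comes from ``patient_column`` when present, otherwise
    from the first ``barcode_prefix_len`` characters of the sample barcode,
    otherwise the barcode itself.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise GenomicError(f"{path}: missing mandatory MAF column(s) {missing}")
    barcodes = df["Tumor_Sample_Barcode"].astype(str)
    if patient_column is not None and patient_column in df.columns:
        patients = df[patient_column].astype(str)
    elif barcode_prefix_len is not None:
        patients = barcodes.str[:barcode_prefix_len]
    else:
        patients = barcodes
    if sample_order_column in df.columns:
        orders = pd.to_numeric(df[sample_order_column], errors="coerce").fillna(0).astype(int)
    else:
        orders = pd.Series(0, index=df.index)
    return [
        MutationRecord(
            study_id=study_id,
            patient_id=p,
            sample_id=b,
            gene_symbol=g.strip(),
            variant_classification=v,
            sample_order_hint=int(o),
            study_date=study_date,
        )
        for p, b, g, v, o in zip(
            patients, barcodes, df["Hugo_Symbol"], df["Variant_Classification"], orders
        )
    ]


def read_sample_table(
    path: str | Path, study_id: str, study_date: str = ""
) -> list[SampleInfo]:
    """Read a per-study roster TSV (sample_id, patient_id[, sample_order, metadata...])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "patient_id"):
        if col not in df.columns:
            raise GenomicError(f"{path}: roster needs a {col} column")
    meta_cols = [c for c in df.columns if c not in ("sample_id", "patient_id", "sample_order")]
    roster = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        order = int(d.get("sample_order", 0) or 0)
        roster.append(
            SampleInfo(
                study_id=study_id,
                patient_id=str(d["patient_id"]),
                sample_id=str(d["sample_id"]),
                sample_order_hint=order,
                study_date=study_date,
                metadata=tuple((c, str(d[c])) for c in meta_cols),
            )
        )
    return roster


def load_manifest(path: str | Path) -> dict[str, ManifestEntry]:
    """Read the study manifest TSV: study_id, date[, maf, samples]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("study_id", "date"):
        if col not in df.columns:
            raise GenomicError(f"{path}: manifest needs a {col} column")
    out: dict[str, ManifestEntry] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = str(d["study_id"])
        if sid in out:
            raise GenomicError(f"{path}: duplicate manifest row for study {sid!r}")
        out[sid] = ManifestEntry(
            study_id=sid,
            study_date=str(d["date"]),
            maf_path=str(d.get("maf", "")),
            samples_path=str(d.get("samples", "")),
        )
    return out


def load_synonym_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("alias", "canonical"):
        if col not in df.columns:
            raise GenomicError(f"{path}: synonym map needs an {col} column")
    return dict(zip(df["alias"].str.strip(), df["canonical"].str.strip()))


# -- record-stream transforms -------------------------------------------------


def filter_mutation_classes(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Keep exactly the records whose variant class is in the whitelist."""
    return [
        r for r in records if normalize_variant_class(r.variant_classification) in QUALIFYING_CLASSES
    ]


def _study_key(item) -> tuple[str, str]:
    # Lexicographic study_id breaks date ties deterministically.
    return (item.study_date, item.study_id)


def choose_primary_samples(items: Iterable) -> dict[str, tuple[str, str]]:
    """Per patient, pick (study_id, sample_id) of the record that counts.

    The study with the latest date wins (ties: lexicographically greatest
    study id); within that study the sample with the smallest order hint
    wins (ties: lexicographically smallest sample id).
    """
    best_study: dict[str, tuple[str, str]] = {}
    for it in items:
        key = _study_key(it)
        cur = best_study.get(it.patient_id)
        if cur is None or key > cur:
            best_study[it.patient_id] = key
    best_sample: dict[str, tuple[int, str]] = {}
    for it in items:
        if _study_key(it) != best_study[it.patient_id]:
            continue
        key = (it.sample_order_hint, it.sample_id)
        cur = best_sample.get(it.patient_id)
        if cur is None or key < cur:
            best_sample[it.patient_id] = key
    return {
        p: (best_study[p][1], best_sample[p][1]) for p in best_study if p in best_sample
    }


def dedup_samples(
    records: Iterable[MutationRecord], roster: Sequence[SampleInfo] | None = None
) -> list[MutationRecord]:
    """Drop records from longitudinal follow-up samples and superseded studies.

    When a roster is supplied the winning (study, sample) per patient is
    chosen from it — this matters for patients whose first sample carries no
    mutation rows at all; otherwise the choice is made from the records
    themselves.
    """
    records = list(records)
    chosen = choose_primary_samples(roster if roster is not None else records)
    return [
        r
        for r in records
        if chosen.get(r.patient_id) == (r.study_id, r.sample_id)
    ]


def dedup_roster(roster: Iterable[SampleInfo]) -> list[SampleInfo]:
    roster = list(roster)
    chosen = choose_primary_samples(roster)
    return [s for s in roster if chosen.get(s.patient_id) == (s.study_id, s.sample_id)]


def standardize_gene_names(
    records: Iterable[MutationRecord], synonym_map: Mapping[str, str]
) -> list[MutationRecord]:
    """Replace each gene symbol by its canonical name.

    Symbols absent from the map pass through unchanged; the distinct
    pass-through symbols are logged once.
    """
    out = []
    unknown: set[str] = set()
    for r in records:
        canonical = synonym_map.get(r.gene_symbol)
        if canonical is None:
            unknown.add(r.gene_symbol)
            out.append(r)
        else:
            out.append(
                MutationRecord(
                    study_id=r.study_id,
                    patient_id=r.patient_id,
                    sample_id=r.sample_id,
                    gene_symbol=canonical,
                    variant_classification=r.variant_classification,
                    sample_order_hint=r.sample_order_hint,
                    study_date=r.study_date,
                )
            )
    if unknown:
        logger.info("standardize_gene_names: %d symbols not in map (pass-through)", len(unknown))
    return out


# -- cohort tally -------------------------------------------------------------


@dataclass
class MutationCohort:
    """Deduplicated patient sets per category: denominators and per-gene numerators."""

    patients: dict[str, set[str]] = field(default_factory=dict)
    mutated: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def categories(self) -> list[str]:
        return sorted(self.patients)

    def genes(self) -> list[str]:
        return sorted(self.mutated)

    def n(self, category: str) -> int:
        return len(self.patients.get(category, ()))

    def m(self, gene: str, category: str) -> int:
        return len(self.mutated.get(gene, {}).get(category, ()))

    def patients_mutated_in_any(self, genes: Iterable[str], category: str) -> set[str]:
        hit: set[str] = set()
        for g in genes:
            hit |= self.mutated.get(g, {}).get(category, set())
        return hit


def assign_patients(roster: Iterable[SampleInfo], cmap: CategoryMap) -> dict[str, str]:
    """Classify each rostered sample and return patient → category.

    A patient whose samples classify into two different categories violates
    the one-category invariant and raises.  UNMAPPED patients stay in the
    result (tagged UNMAPPED) so callers can report the excluded mass.
    """
    out: dict[str, str] = {}
    for s in roster:
        cat = cmap.classify_genomic_sample(s.study_id, s.sample_id, s.metadata_dict())
        prev = out.get(s.patient_id)
        if prev is not None and prev != cat:
            raise GenomicError(
                f"patient {s.patient_id!r} assigned to both {prev!r} and {cat!r}"
            )
        out[s.patient_id] = cat
    return out


def tally_cohort(
    records: Iterable[MutationRecord], assignments: Mapping[str, str]
) -> MutationCohort:
    """Count patients per category (n_h) and mutated patients per gene (m_gh).

    A patient with one or many qualifying rows in the same gene counts once.
    Patients assigned UNMAPPED are excluded (and their exclusion is the
    caller's to report); records for patients absent from the assignment
    table raise, because the denominator would be undefined.
    """
    cohort = MutationCohort()
    for patient, category in assignments.items():
        if category == UNMAPPED:
            continue
        cohort.patients.setdefault(category, set()).add(patient)
    dropped_unmapped = 0
    for r in records:
        category = assignments.get(r.patient_id)
        if category is None:
            raise GenomicError(f"record for unrostered patient {r.patient_id!r}")
        if category == UNMAPPED:
            dropped_unmapped += 1
            continue
        cohort.mutated.setdefault(r.gene_symbol, {}).setdefault(category, set()).add(r.patient_id)
    if dropped_unmapped:
        logger.info("tally_cohort: %d records from UNMAPPED patients excluded", dropped_unmapped)
    return cohort


@dataclass
class ConditionalMatrix:
    """c_gh = m_gh / n_h with the counts it came from.

    ``values``/``m`` are genes × categories frames; ``n`` is the per-category
    patient count.  Only categories with n_h > 0 appear.
    """

    values: pd.DataFrame
    m: pd.DataFrame
    n: pd.Series

    @property
    def gene_list(self) -> list[str]:
        return list(self.values.index)

    @property
    def category_list(self) -> list[str]:
        return list(self.values.columns)


def conditional_matrix(
    cohort: MutationCohort, gene_universe: Sequence[str] | None = None
) -> ConditionalMatrix:
    """Build C from a tallied cohort.

    The gene universe defaults to the observed canonical symbols; an explicit
    list extends it with zero rows so genes of interest that were never
    observed get an estimate of 0 rather than going missing.
    """
    categories = [c for c in cohort.categories() if cohort.n(c) > 0]
    genes = sorted(set(cohort.genes()) | set(gene_universe or ()))
    n = pd.Series({c: cohort.n(c) for c in categories}, dtype=float)
    m = pd.DataFrame(
        np.zeros((len(genes), len(categories))), index=genes, columns=categories
    )
    for g in cohort.genes():
        for c, pats in cohort.mutated[g].items():
            if c in m.columns:
                m.loc[g, c] = len(pats)
    values = m.divide(n, axis=1)
    return ConditionalMatrix(values=values, m=m, n=n)
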