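"""Common cancer taxonomy and the maps onto it.

Registry records are keyed by ICD-O-3 morphology (histology/behaviour) and
topography (site) codes; sequencing studies are keyed by study id plus
per-sample metadata.  A :class:`CategoryMap` carries both maps onto one set
of analysis categories so incidence counts and mutation calls can be joined.

Categories may carry a subclass tag (adenocarcinoma, squamous cell
carcinoma, ...) so subclass-restricted analyses are a filter over the map,
not a second map.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Sentinel category for records the map does not cover.  Never silently
#: dropped: downstream stages keep and report UNMAPPED mass.
UNMAPPED = "UNMAPPED"

#: Wildcard site code: the morphology maps to the category at any site.
WILDCARD_SITE = "*"

SUBCLASS_TAGS = frozenset(
    {
        "adenocarcinoma",
        "squamous_cell_carcinoma",
        "malignant_melanoma",
        "transitional_cell_carcinoma",
        "other",
    }
)


class CategoryMapError(ValueError):
    """Raised for malformed or self-contradictory map files."""


def normalize_morphology(code: str) -> str:
    """Normalize an ICD-O-3 histology/behaviour code to ``dddd/d`` form.

    Registry exports write the same code either as ``8140/3`` or ``81403``;
    both normalize to ``8140/3``.  Codes in neither dialect pass through
    stripped but otherwise unchanged.
    """
    code = code.strip()
    if re.fullmatch(r"\d{4}/\d", code):
        return code
    if re.fullmatch(r"\d{5}", code):
        return f"{code[:4]}/{code[4]}"
    return code


def normalize_site(code: str) -> str:
    return code.strip().upper() if code.strip() != WILDCARD_SITE else WILDCARD_SITE


@dataclass
class StudyAssignment:
    """How samples of one sequencing study map onto categories.

    Precedence when classifying a sample (most to least specific):
    explicit per-sample assignment, metadata predicate (``field == value``),
    study-level default.
    """

    study_id: str
    default_category: str | None = None
    sample_overrides: dict[str, str] = field(default_factory=dict)
    predicates: list[tuple[str, str, str]] = field(default_factory=list)

    def referenced_categories(self) -> set[str]:
        cats = set(self.sample_overrides.values())
        cats.update(cat for _, _, cat in self.predicates)
        if self.default_category is not None:
            cats.add(self.default_category)
        return cats


@dataclass
class CategoryMap:
    """The taxonomy plus the registry-code and study maps onto it.

    ``entries`` maps a normalized ``(morphology, site)`` pair to exactly one
    category (the map is a function); a site of ``"*"`` matches any site but
    never shadows an exact pair.  ``categories`` maps each category id to an
    optional subclass tag.
    """

    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    categories: dict[str, str | None] = field(default_factory=dict)
    studies: dict[str, StudyAssignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (morph, site), cat in self.entries.items():
            self.categories.setdefault(cat, None)
        self.validate()

    # -- construction helpers -------------------------------------------------

    def add_entry(self, morphology: str, site: str, category: str) -> None:
        key = (normalize_morphology(morphology), normalize_site(site))
        existing = self.entries.get(key)
        if existing is not None and existing != category:
            raise CategoryMapError(
                f"conflicting category for {key}: {existing!r} vs {category!r}"
            )
        self.entries[key] = category
        self.categories.setdefault(category, None)

    def validate(self) -> None:
        for sid, sa in self.studies.items():
            missing = sa.referenced_categories() - set(self.categories)
            if missing:
                raise CategoryMapError(
                    f"study {sid!r} references unknown categories: {sorted(missing)}"
                )
        bad = {c: t for c, t in self.categories.items() if t is not None and t not in SUBCLASS_TAGS}
        if bad:
            raise CategoryMapError(f"unknown subclass tags: {bad}")

    # -- classification -------------------------------------------------------

    def classify_epi_record(self, morphology: str, site: str) -> str:
        """Map a registry (morphology, site) pair to a category.

        Exact (morphology, site) match wins over the (morphology, "*")
        wildcard; returns :data:`UNMAPPED` when neither exists.
        """
        morph = normalize_morphology(morphology)
        site = normalize_site(site)
        hit = self.entries.get((morph, site))
        if hit is not None:
            return hit
        return self.entries.get((morph, WILDCARD_SITE), UNMAPPED)

    def classify_genomic_sample(
        self,
        study_id: str,
        sample_id: str | None = None,
        metadata: Mapping[str, str] | None = None,
    ) -> str:
        """Map one sequenced sample to a category.

        Precedence: explicit per-sample assignment > metadata predicate >
        study default > :data:`UNMAPPED`.  A study may fan out to several
        categories through its predicates.
        """
        sa = self.studies.get(study_id)
        if sa is None:
            return UNMAPPED
        if sample_id is not None and sample_id in sa.sample_overrides:
            return sa.sample_overrides[sample_id]
        if metadata:
            for fld, value, cat in sa.predicates:
                if str(metadata.get(fld, "")).strip().lower() == value.strip().lower():
                    return cat
        return sa.default_category if sa.default_category is not None else UNMAPPED

    # -- subclass queries ------------------------------------------------------

    def subclass_members(self, tag: str) -> set[str]:
        if tag not in SUBCLASS_TAGS:
            raise CategoryMapError(f"unknown subclass tag {tag!r}")
        return {c for c, t in self.categories.items() if t == tag}

    # -- serialization ---------------------------------------------------------

    def save(self, map_path: str | Path, studies_path: str | Path | None = None) -> None:
        rows = [
            {"morphology_code": m, "site_code": s, "category_id": c,
             "subclass": self.categories.get(c) or ""}
            for (m, s), c in sorted(self.entries.items())
        ]
        # Categories reachable only from study assignments get
        # declaration-only rows ("-" morphology) so they survive a round trip.
        entry_cats = set(self.entries.values())
        rows.extend(
            {"morphology_code": "-", "site_code": "-", "category_id": c,
             "subclass": self.categories.get(c) or ""}
            for c in sorted(set(self.categories) - entry_cats)
        )
        pd.DataFrame(rows, columns=["morphology_code", "site_code", "category_id", "subclass"]).to_csv(
            map_path, sep="\t", index=False
        )
        if studies_path is not None:
            srows = []
            for sid in sorted(self.studies):
                sa = self.studies[sid]
                if sa.default_category is not None:
                    srows.append((sid, "default", "", sa.default_category))
                for fld, value, cat in sa.predicates:
                    srows.append((sid, "metadata", f"{fld}={value}", cat))
                for sample, cat in sorted(sa.sample_overrides.items()):
                    srows.append((sid, "sample", sample, cat))
            pd.DataFrame(
                srows, columns=["study_id", "selector_type", "selector_value", "category_id"]
            ).to_csv(studies_path, sep="\t", index=False)


def load_category_map(path: str | Path, studies_path: str | Path | None = None) -> CategoryMap:
    """Read a category map TSV (morphology_code, site_code, category_id[, subclass]).

    Duplicate keys with conflicting categories are rejected with the
    offending key and line number.  An empty file yields an empty map.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logging.getLogger(__name__).warning("%s: empty category map file", path)
        return CategoryMap()
    required = {"morphology_code", "site_code", "category_id"}
    missing = required - set(df.columns)
    if missing:
        raise CategoryMapError(f"{path}: missing columns {sorted(missing)}")
    cmap = CategoryMap()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        morph = str(row.morphology_code).strip()
        site = str(row.site_code).strip()
        cat = str(row.category_id).strip()
        if not morph or not site or not cat:
            raise CategoryMapError(f"{path}: line {i}: empty field in row {tuple(row)}")
        if morph == "-":
            # Declaration-only row: registers a category (for genomics-only
            # categories) without a registry-code entry.
            cmap.categories.setdefault(cat, None)
        else:
            try:
                cmap.add_entry(morph, site, cat)
            except CategoryMapError as exc:
                raise CategoryMapError(f"{path}: line {i}: {exc}") from exc
        if "subclass" in df.columns:
            tag = str(row.subclass).strip() or None
            prev = cmap.categories.get(cat)
            if tag is not None and prev is not None and prev != tag:
                raise CategoryMapError(
                    f"{path}: line {i}: category {cat!r} tagged both {prev!r} and {tag!r}"
                )
            if tag is not None:
                cmap.categories[cat] = tag
    cmap.validate()
    if studies_path is not None:
        load_study_assignments(studies_path, cmap)
    return cmap


def load_study_assignments(path: str | Path, cmap: CategoryMap) -> CategoryMap:
    """Attach study→category assignments from a TSV to an existing map.

    Columns: study_id, selector_type (default|metadata|sample),
    selector_value ("" for default, "field=value" for metadata, sample id
    for sample), category_id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"study_id", "selector_type", "selector_value", "category_id"}
    missing = required - set(df.columns)
    if missing:
        raise CategoryMapError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.study_id).strip()
        sa = cmap.studies.setdefault(sid, StudyAssignment(study_id=sid))
        sel = str(row.selector_type).strip().lower()
        cat = str(row.category_id).strip()
        if sel == "default":
            if sa.default_category is not None and sa.default_category != cat:
                raise CategoryMapError(f"{path}: line {i}: study {sid!r} has two defaults")
            sa.default_category = cat
        elif sel == "metadata":
            if "=" not in row.selector_value:
                raise CategoryMapError(f"{path}: line {i}: metadata selector needs field=value")
            fld, value = str(row.selector_value).split("=", 1)
            sa.predicates.append((fld.strip(), value.strip(), cat))
        elif sel == "sample":
            sample = str(row.selector_value).strip()
            if sa.sample_overrides.get(sample, cat) != cat:
                raise CategoryMapError(
                    f"{path}: line {i}: sample {sample!r} assigned to two categories"
                )
            sa.sample_overrides[sample] = cat
        else:
            raise CategoryMapError(f"{path}: line {i}: unknown selector_type {sel!r}")
    cmap.validate()
    return cmap


def unmapped_summary(assignments: Iterable[str]) -> dict[str, int]:
    """Count mapped vs unmapped outcomes from a stream of classifications."""
    total = mapped = 0
    for cat in assignments:
        total += 1
        mapped += cat != UNMAPPED
    return {"total": total, "mapped": mapped, "unmapped": total - mapped}
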