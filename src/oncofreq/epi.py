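"""Registry incidence processing: from raw (morphology, site, count) records
to the per-category incidence vector S, its sequenced restriction S', subclass
vectors and coverage statistics.

Counts are conserved exactly through reclassification: records the map does
not cover are accumulated under the UNMAPPED sentinel, never dropped, so the
table total always equals the input total (the conservation QC).
Internally shares are fractions summing to 1; percentages appear only in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .categories import UNMAPPED, CategoryMap

#: Reserved site row for records without a mapped category.
UNMAPPED_SITE = "UNMAPPED"

_NORM_TOL = 1e-9


class EpiError(ValueError):
    pass


@dataclass
class IncidenceTable:
    """Diagnosis counts indexed by (site_code, category_id)."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, site: str, category: str, count: int) -> None:
        if count < 0:
            raise EpiError(f"negative count {count} for ({site}, {category})")
        key = (site, category)
        self.counts[key] = self.counts.get(key, 0) + count

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"site_code": s, "category_id": c, "count": n}
            for (s, c), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["site_code", "category_id", "count"])


@dataclass
class IncidenceVector:
    """Per-category incidence mass: raw counts (S) or normalized shares (S')."""

    values: dict[str, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise EpiError("negative incidence value")
        if self.normalized:
            total = sum(self.values.values())
            if abs(total - 1.0) > _NORM_TOL:
                raise EpiError(f"normalized vector sums to {total}, not 1")

    @property
    def k(self) -> int:
        return len(self.values)

    @property
    def total(self) -> float:
        return sum(self.values.values())

    def categories(self) -> set[str]:
        return set(self.values)

    def normalize(self) -> "IncidenceVector":
        total = self.total
        if total <= 0:
            raise EpiError("cannot normalize an all-zero incidence vector")
        return IncidenceVector({c: v / total for c, v in self.values.items()}, normalized=True)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float).sort_index()


def build_incidence_table(
    records: Iterable[tuple[str, str, int]], cmap: CategoryMap
) -> IncidenceTable:
    """Accumulate (morphology, site, count) records into a (site, category) table.

    Unmapped records land in the reserved (UNMAPPED, UNMAPPED) cell so the
    output total equals the input total exactly.
    """
    table = IncidenceTable()
    for morph, site, count in records:
        count = int(count)
        if count < 0:
            raise EpiError(f"negative count {count} for ({morph}, {site})")
        if count == 0:
            continue
        category = cmap.classify_epi_record(morph, site)
        if category == UNMAPPED:
            table.add(UNMAPPED_SITE, UNMAPPED, count)
        else:
            table.add(site.strip().upper(), category, count)
    return table


def incidence_vector(table: IncidenceTable, include_unmapped: bool = False) -> IncidenceVector:
    """Marginalize the table over sites into the per-category count vector S."""
    values: dict[str, float] = {}
    for (_site, category), count in table.counts.items():
        if category == UNMAPPED and not include_unmapped:
            continue
        values[category] = values.get(category, 0.0) + count
    return IncidenceVector(values, normalized=False)


def restrict_and_normalize(S: IncidenceVector, sequenced_ids: set[str]) -> IncidenceVector:
    """Restrict S to sequenced categories and renormalize to sum 1 (S')."""
    kept = {c: v for c, v in S.values.items() if c in sequenced_ids}
    if not kept:
        raise EpiError("no sequenced category has incidence mass; no estimate possible")
    return IncidenceVector(kept, normalized=False).normalize()


def coverage_fraction(S: IncidenceVector, sequenced_ids: set[str]) -> float:
    """Share of total incidence in categories with representative sequencing."""
    total = S.total
    if total <= 0:
        return 0.0
    return sum(v for c, v in S.values.items() if c in sequenced_ids) / total


def top_categories_share(S: IncidenceVector, n: int) -> float:
    """Combined normalized share of the n most abundant categories.

    Ties are broken lexicographically on category id, so the result is
    deterministic.
    """
    if n <= 0:
        return 0.0
    total = S.total
    if total <= 0:
        return 0.0
    ranked = sorted(S.values.items(), key=lambda kv: (-kv[1], kv[0]))
    return sum(v for _, v in ranked[:n]) / total


def subclass_vector(S: IncidenceVector, subclass_tag: str, cmap: CategoryMap) -> IncidenceVector:
    """Restrict S to categories carrying a subclass tag, renormalized."""
    members = cmap.subclass_members(subclass_tag)
    kept = {c: v for c, v in S.values.items() if c in members}
    if not kept or sum(kept.values()) <= 0:
        raise EpiError(f"no incidence mass in subclass {subclass_tag!r}")
    return IncidenceVector(kept).normalize()


# -- registry file IO ---------------------------------------------------------


def read_registry(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a registry export as (morphology, site, count) records.

    Two dialects are auto-detected from the header: long format with columns
    ``morphology_code, site_code, count``, and wide format with one
    ``morphology_code`` column and one column per site code holding integer
    cells.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "morphology_code" not in df.columns:
        raise EpiError(f"{path}: registry file needs a morphology_code column")
    records: list[tuple[str, str, int]] = []
    if {"site_code", "count"} <= set(df.columns):
        for row in df.itertuples(index=False):
            records.append((str(row.morphology_code), str(row.site_code), int(row.count)))
    else:
        site_cols = [c for c in df.columns if c != "morphology_code"]
        if not site_cols:
            raise EpiError(f"{path}: wide registry file has no site columns")
        for row in df.itertuples(index=False):
            morph = str(row[0])
            for site, cell in zip(site_cols, row[1:]):
                if str(cell).strip() in ("", "0"):
                    continue
                records.append((morph, site, int(cell)))
    return records


def write_incidence_vector(S: IncidenceVector, path: str | Path) -> None:
    total = S.total
    rows = [
        {"category_id": c, "count": v, "share": (v / total if total else 0.0)}
        for c, v in sorted(S.values.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    pd.DataFrame(rows, columns=["category_id", "count", "share"]).to_csv(path, sep="\t", index=False)
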