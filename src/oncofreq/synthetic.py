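"""Synthetic registries and multi-study mutation cohorts with known truth.

The generator emulates the statistical structure the estimator assumes:
diagnoses fall on categories multinomially; within a category each sequenced
patient carries a mutation in gene g with a fixed Bernoulli probability; a
mutation event is written as 1–3 MAF rows.  On top of that it injects the
messiness the pipeline must survive: cohort sizes unrelated to incidence,
patients re-published by a later study, longitudinal follow-up samples,
synonym gene symbols, and mutation events whose calls are of non-qualifying
classes (splice/fusion) and must vanish in filtering.

Every quantity the pipeline should recover is recorded as ground truth, so
end-to-end tests are parameter-recovery tests, not snapshot tests.  All
randomness flows from one seed through per-purpose substreams: adding rows
to one stage does not shift draws in another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .categories import CategoryMap, StudyAssignment
from .epi import IncidenceTable, IncidenceVector, build_incidence_table
from .genomic import MutationRecord, SampleInfo

#: Mixed-dialect spellings of qualifying classes, to exercise normalization.
_QUALIFYING_SPELLINGS = (
    "Missense_Mutation",
    "missense",
    "Nonsense_Mutation",
    "nonsense",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "frame_shift",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Nonstop_Mutation",
)
_EXCLUDED_SPELLINGS = ("Splice_Site", "Fusion", "Silent", "3'UTR", "Intron")

LONGITUDINAL_SENTINEL = "TIMEPOINT2_MARKER"


@dataclass
class StudySpec:
    """One synthetic sequencing study: which categories it samples, and when."""

    study_id: str
    date: str
    categories: list[str]


@dataclass
class GroundTruth:
    """Complete description of a synthetic scenario.

    ``shares`` covers all categories (including unsequenced ones) and sums
    to 1; ``p`` holds the per-category Bernoulli probability of a mutation
    event per gene.  ``excluded_class_rate`` is the probability that an
    event is called only with non-qualifying classes, so the probability of
    a *qualifying* mutation is p·(1−excluded_class_rate) — that product is
    what the pipeline should recover.
    """

    categories: list[str]
    shares: dict[str, float]
    subclass: dict[str, str | None]
    sites: dict[str, str]
    morphologies: dict[str, list[str]]
    genes: list[str]
    p: pd.DataFrame
    studies: list[StudySpec]
    patients_per_category: dict[str, int]
    overlap_fraction: float = 0.0
    longitudinal_rate: float = 0.0
    alias_rate: float = 0.0
    excluded_class_rate: float = 0.0
    synonyms: dict[str, str] = field(default_factory=dict)
    registry_total: int = 7_167_808

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category shares sum to {total}, not 1")
        if ((self.p < 0) | (self.p > 1)).any().any():
            raise ValueError("mutation probabilities must be in [0, 1]")
        for rate in (self.overlap_fraction, self.longitudinal_rate,
                     self.alias_rate, self.excluded_class_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate {rate} outside [0, 1]")

    # -- derived truth --------------------------------------------------------

    def sequenced_categories(self) -> list[str]:
        return list(self.categories)

    def shares_prime(self) -> dict[str, float]:
        """True incidence shares renormalized over sequenced categories."""
        mass = sum(self.shares[c] for c in self.categories)
        return {c: self.shares[c] / mass for c in self.categories}

    def coverage(self) -> float:
        return sum(self.shares[c] for c in self.categories)

    def qualifying_p(self) -> pd.DataFrame:
        return self.p * (1.0 - self.excluded_class_rate)

    def expected_G(self) -> pd.Series:
        """True weighted proportion of qualifying mutations per gene."""
        sp = pd.Series(self.shares_prime()).reindex(self.p.columns)
        return pd.Series(
            self.qualifying_p().to_numpy() @ sp.to_numpy(), index=self.genes, name="true_G"
        )

    def recovery_se(self) -> pd.Series:
        """Binomial standard error of the weighted estimate per gene."""
        sp = pd.Series(self.shares_prime()).reindex(self.p.columns).to_numpy()
        n = np.array([self.patients_per_category[c] for c in self.p.columns], dtype=float)
        q = self.qualifying_p().to_numpy()
        var = (sp**2 * q * (1 - q) / n).sum(axis=1)
        return pd.Series(np.sqrt(var), index=self.genes, name="se")

    def category_map(self) -> CategoryMap:
        """The taxonomy map this scenario implies.

        Each category gets one exact-site morphology entry and one wildcard
        entry; single-category studies map by default, multi-category
        studies fan out on the roster's histology metadata.
        """
        cmap = CategoryMap()
        all_cats = list(self.shares)
        for cat in all_cats:
            for i, morph in enumerate(self.morphologies[cat]):
                site = self.sites[cat] if i == 0 else "*"
                cmap.add_entry(morph, site, cat)
            cmap.categories[cat] = self.subclass.get(cat)
        for spec in self.studies:
            if len(spec.categories) == 1:
                cmap.studies[spec.study_id] = StudyAssignment(
                    study_id=spec.study_id, default_category=spec.categories[0]
                )
            else:
                cmap.studies[spec.study_id] = StudyAssignment(
                    study_id=spec.study_id,
                    predicates=[("histology", c, c) for c in spec.categories],
                )
        cmap.validate()
        return cmap


def default_truth(
    seed: int = 20170,
    n_genes: int = 40,
    patients_per_category: int | dict[str, int] | None = None,
    overlap_fraction: float = 0.05,
    longitudinal_rate: float = 0.05,
    alias_rate: float = 0.10,
    excluded_class_rate: float = 0.10,
) -> GroundTruth:
    """The default scenario: six sequenced categories plus a small
    unsequenced remainder, 40 genes, three partially overlapping studies.

    Sequenced categories carry 93% of incidence; cohort sizes (300–2,000
    per category) are deliberately unrelated to incidence shares, like real
    sequencing cohorts.  Mutation probabilities are drawn once from the
    seed and become part of the recorded truth.
    """
    cats = [
        ("breast_carcinoma", 0.25, None, "C50"),
        ("colorectal_ac", 0.20, "adenocarcinoma", "C18"),
        ("lung_ac", 0.16, "adenocarcinoma", "C34"),
        ("melanoma", 0.12, "malignant_melanoma", "C44"),
        ("lung_scc", 0.11, "squamous_cell_carcinoma", "C34"),
        ("urothelial_tcc", 0.09, "transitional_cell_carcinoma", "C67"),
        ("rare_unsequenced", 0.07, None, "C80"),
    ]
    sequenced = [c[0] for c in cats[:-1]]
    shares = {c[0]: c[1] for c in cats}
    subclass = {c[0]: c[2] for c in cats}
    sites = {c[0]: c[3] for c in cats}
    morphologies = {
        c[0]: [f"8{100 + i:03d}/3", f"9{500 + i:03d}/3"] for i, c in enumerate(cats)
    }
    genes = [f"GENE{i:03d}" for i in range(1, n_genes + 1)]
    rng = np.random.default_rng(seed)
    base = 10 ** rng.uniform(-2.0, -0.7, size=n_genes)          # 0.01 .. 0.2
    mult = rng.lognormal(mean=0.0, sigma=0.5, size=(n_genes, len(sequenced)))
    p = pd.DataFrame(
        np.clip(base[:, None] * mult, 0.001, 0.5), index=genes, columns=sequenced
    )
    if patients_per_category is None:
        sizes = dict(zip(sequenced, [2000, 1500, 1000, 800, 500, 300]))
    elif isinstance(patients_per_category, int):
        sizes = {c: patients_per_category for c in sequenced}
    else:
        sizes = dict(patients_per_category)
    studies = [
        StudySpec("study_alpha", "2015-06-01", sequenced[0:4]),
        StudySpec("study_beta", "2017-03-15", sequenced[2:6]),
        StudySpec("study_gamma", "2019-11-20", sequenced[5:6]),
    ]
    synonyms = {f"{g}_ALIAS": g for g in genes[::3]}
    return GroundTruth(
        categories=sequenced,
        shares=shares,
        subclass=subclass,
        sites=sites,
        morphologies=morphologies,
        genes=genes,
        p=p,
        studies=studies,
        patients_per_category=sizes,
        overlap_fraction=overlap_fraction,
        longitudinal_rate=longitudinal_rate,
        alias_rate=alias_rate,
        excluded_class_rate=excluded_class_rate,
        synonyms=synonyms,
    )


def oversampled_scenario(seed: int = 20170) -> GroundTruth:
    """A deliberate cohort/incidence mismatch.

    A rare cancer (10% of diagnoses) contributes five times more sequenced
    patients than the common cancer, and carries a marker gene at high rate:
    pooling samples then overstates the marker's population frequency, while
    incidence weighting does not.
    """
    genes = ["MARKER1"] + [f"GENE{i:03d}" for i in range(1, 10)]
    rng = np.random.default_rng(seed)
    p = pd.DataFrame(
        rng.uniform(0.02, 0.15, size=(len(genes), 2)),
        index=genes,
        columns=["common_cancer", "rare_cancer"],
    )
    p.loc["MARKER1"] = [0.02, 0.50]
    return GroundTruth(
        categories=["common_cancer", "rare_cancer"],
        shares={"common_cancer": 0.9, "rare_cancer": 0.1},
        subclass={"common_cancer": None, "rare_cancer": None},
        sites={"common_cancer": "C18", "rare_cancer": "C37"},
        morphologies={"common_cancer": ["8140/3", "9500/3"], "rare_cancer": ["8580/3", "9501/3"]},
        genes=genes,
        p=p,
        studies=[
            StudySpec("study_common", "2016-01-01", ["common_cancer"]),
            StudySpec("study_rare", "2018-01-01", ["rare_cancer"]),
        ],
        patients_per_category={"common_cancer": 300, "rare_cancer": 1500},
    )


# -- registry generation ------------------------------------------------------


def generate_registry(
    truth: GroundTruth,
    total_count: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, int]], IncidenceTable]:
    """Multinomial draw of diagnoses over (morphology, site) cells.

    Each category's mass splits 70/30 over its two morphology codes; the
    second code is mapped by site wildcard, so registry records for it carry
    the category's site yet resolve through the wildcard path.  Returns the
    long-format records and the reclassified table (whose total equals
    ``total_count`` exactly).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if total_count is None:
        total_count = truth.registry_total
    cells: list[tuple[str, str]] = []
    probs: list[float] = []
    for cat, share in truth.shares.items():
        morphs = truth.morphologies[cat]
        site = truth.sites[cat]
        for morph, frac in zip(morphs, (0.7, 0.3)):
            cells.append((morph, site))
            probs.append(share * frac)
    counts = rng.multinomial(total_count, np.asarray(probs) / sum(probs))
    records = [
        (morph, site, int(n)) for (morph, site), n in zip(cells, counts) if n > 0
    ]
    table = build_incidence_table(records, truth.category_map())
    return records, table


def write_registry(records: list[tuple[str, str, int]], long_path: str | Path,
                   wide_path: str | Path | None = None) -> None:
    df = pd.DataFrame(records, columns=["morphology_code", "site_code", "count"])
    df.to_csv(long_path, sep="\t", index=False)
    if wide_path is not None:
        wide = (
            df.pivot_table(index="morphology_code", columns="site_code",
                           values="count", aggfunc="sum", fill_value=0)
            .astype(int)
            .reset_index()
        )
        wide.to_csv(wide_path, sep="\t", index=False)


# -- cohort generation --------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Everything the genomic pipeline needs, plus the truth to check against."""

    truth: GroundTruth
    roster: list[SampleInfo]
    records: list[MutationRecord]
    truth_m: pd.DataFrame            # qualifying-mutation presence counts, genes × categories
    truth_n: dict[str, int]          # distinct patients per category
    patient_categories: dict[str, str]

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Dump per-study MAF + roster TSVs, manifest, maps and truth JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        manifest_rows = []
        for spec in self.truth.studies:
            maf_rows = [
                {
                    "Hugo_Symbol": r.gene_symbol,
                    "Variant_Classification": r.variant_classification,
                    "Tumor_Sample_Barcode": r.sample_id,
                    "Patient_ID": r.patient_id,
                    "Sample_Order": r.sample_order_hint,
                }
                for r in self.records
                if r.study_id == spec.study_id
            ]
            maf = directory / f"{spec.study_id}.maf.tsv"
            pd.DataFrame(
                maf_rows,
                columns=["Hugo_Symbol", "Variant_Classification",
                         "Tumor_Sample_Barcode", "Patient_ID", "Sample_Order"],
            ).to_csv(maf, sep="\t", index=False)
            roster_rows = [
                {"sample_id": s.sample_id, "patient_id": s.patient_id,
                 "sample_order": s.sample_order_hint, **s.metadata_dict()}
                for s in self.roster
                if s.study_id == spec.study_id
            ]
            samples = directory / f"{spec.study_id}.samples.tsv"
            pd.DataFrame(roster_rows).to_csv(samples, sep="\t", index=False)
            manifest_rows.append(
                {"study_id": spec.study_id, "date": spec.date,
                 "maf": maf.name, "samples": samples.name}
            )
            paths[f"maf:{spec.study_id}"] = maf
            paths[f"samples:{spec.study_id}"] = samples
        manifest = directory / "manifest.tsv"
        pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)
        paths["manifest"] = manifest
        cmap = self.truth.category_map()
        paths["category_map"] = directory / "category_map.tsv"
        paths["study_assignments"] = directory / "study_assignments.tsv"
        cmap.save(paths["category_map"], paths["study_assignments"])
        paths["synonyms"] = directory / "synonyms.tsv"
        pd.DataFrame(
            sorted(self.truth.synonyms.items()), columns=["alias", "canonical"]
        ).to_csv(paths["synonyms"], sep="\t", index=False)
        paths["truth"] = directory / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "expected_G": self.truth.expected_G().round(10).to_dict(),
                    "truth_m": {g: self.truth_m.loc[g].to_dict() for g in self.truth_m.index},
                    "truth_n": self.truth_n,
                    "coverage": self.truth.coverage(),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        return paths


def generate_cohorts(truth: GroundTruth, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Draw the multi-study cohort implied by the ground truth.

    Per category, patients are dealt round-robin to the studies covering it;
    each patient/gene mutation event is Bernoulli(p_gh) and expands to 1–3
    MAF rows.  Events hit by the excluded-class rate are written only with
    non-qualifying classes (and excluded from the recorded truth counts);
    aliased rows use synonym symbols; longitudinal patients get a second,
    later sample carrying a sentinel gene; overlap patients are re-published
    by the latest-dated study covering their category.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    # Independent substreams per concern, so rates can change independently.
    streams = {
        name: np.random.default_rng(rng.integers(0, 2**31 - 1))
        for name in ("presence", "rows", "alias", "longitudinal", "overlap", "excluded")
    }
    cover: dict[str, list[StudySpec]] = {c: [] for c in truth.categories}
    for spec in truth.studies:
        for c in spec.categories:
            cover[c].append(spec)
    roster: list[SampleInfo] = []
    records: list[MutationRecord] = []
    truth_m = pd.DataFrame(
        0, index=truth.genes, columns=truth.categories, dtype=int
    )
    truth_n: dict[str, int] = {}
    patient_categories: dict[str, str] = {}
    gene_arr = np.array(truth.genes)
    has_alias = {g: f"{g}_ALIAS" in truth.synonyms for g in truth.genes}
    alias_of = {g: f"{g}_ALIAS" for g in truth.genes}

    for cat in truth.categories:
        specs = sorted(cover[cat], key=lambda s: (s.date, s.study_id))
        if not specs:
            raise ValueError(f"category {cat!r} has no covering study")
        latest = specs[-1]
        n_pat = truth.patients_per_category[cat]
        truth_n[cat] = n_pat
        p_vec = truth.p[cat].to_numpy()
        presence = streams["presence"].random((n_pat, len(gene_arr))) < p_vec
        excluded = streams["excluded"].random((n_pat, len(gene_arr))) < truth.excluded_class_rate
        qualifying = presence & ~excluded
        truth_m[cat] += qualifying.sum(axis=0)
        long_flags = streams["longitudinal"].random(n_pat) < truth.longitudinal_rate
        overlap_flags = streams["overlap"].random(n_pat) < truth.overlap_fraction
        for i in range(n_pat):
            patient = f"{cat}-P{i:05d}"
            patient_categories[patient] = cat
            home = specs[i % len(specs)]
            sample = f"{patient}-S1"
            meta = (("histology", cat),)
            roster.append(
                SampleInfo(home.study_id, patient, sample, 1, home.date, meta)
            )
            pat_rows: list[tuple[str, str]] = []   # (symbol-as-written, class)
            for j in np.nonzero(presence[i])[0]:
                gene = gene_arr[j]
                n_rows = int(streams["rows"].integers(1, 4))
                if excluded[i, j]:
                    classes = streams["rows"].choice(_EXCLUDED_SPELLINGS, size=n_rows)
                else:
                    classes = streams["rows"].choice(_QUALIFYING_SPELLINGS, size=n_rows)
                for cls in classes:
                    symbol = gene
                    if has_alias[gene] and streams["alias"].random() < truth.alias_rate:
                        symbol = alias_of[gene]
                    pat_rows.append((symbol, str(cls)))
            records.extend(
                MutationRecord(home.study_id, patient, sample, sym, cls, 1, home.date)
                for sym, cls in pat_rows
            )
            if long_flags[i]:
                # Follow-up sample in the same study; its sentinel gene must
                # vanish under the first-sample rule.
                s2 = f"{patient}-S2"
                roster.append(
                    SampleInfo(home.study_id, patient, s2, 2, home.date, meta)
                )
                records.append(
                    MutationRecord(
                        home.study_id, patient, s2,
                        LONGITUDINAL_SENTINEL, "Missense_Mutation", 2, home.date,
                    )
                )
            if overlap_flags[i] and home.study_id != latest.study_id:
                # Re-publication by the latest-dated study: same patient,
                # same qualifying profile, new sample barcode.
                dup = f"{patient}-DUP"
                roster.append(
                    SampleInfo(latest.study_id, patient, dup, 1, latest.date, meta)
                )
                records.extend(
                    MutationRecord(latest.study_id, patient, dup, sym, cls, 1, latest.date)
                    for sym, cls in pat_rows
                )
    return SyntheticCohort(
        truth=truth,
        roster=roster,
        records=records,
        truth_m=truth_m,
        truth_n=truth_n,
        patient_categories=patient_categories,
    )


# -- YAML scenario loading ----------------------------------------------------


def truth_from_yaml(path: str | Path) -> GroundTruth:
    """Build a scenario from a YAML file.

    Expected layout::

        categories:
          - {id: colorectal_ac, share: 0.5, site: C18, subclass: adenocarcinoma,
             patients: 500, morphologies: ["8140/3", "9510/3"]}
          - {id: rare_unseq, share: 0.1, site: C80, sequenced: false}
        genes: {GENE1: {colorectal_ac: 0.3, ...}, ...}
        studies:
          - {id: study_a, date: "2016-01-01", categories: [colorectal_ac]}
        rates: {overlap: 0.0, longitudinal: 0.0, alias: 0.0, excluded_class: 0.0}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    sequenced, shares, subclass, sites, morphs, sizes = [], {}, {}, {}, {}, {}
    for i, c in enumerate(cfg["categories"]):
        cid = c["id"]
        shares[cid] = float(c["share"])
        subclass[cid] = c.get("subclass")
        sites[cid] = c.get("site", f"C{10 + i}")
        morphs[cid] = list(c.get("morphologies", [f"8{100 + i:03d}/3", f"9{500 + i:03d}/3"]))
        if c.get("sequenced", True):
            sequenced.append(cid)
            sizes[cid] = int(c.get("patients", 500))
    p = pd.DataFrame(cfg["genes"]).T.reindex(columns=sequenced).astype(float)
    studies = [
        StudySpec(s["id"], str(s["date"]), list(s["categories"])) for s in cfg["studies"]
    ]
    rates = cfg.get("rates", {})
    genes = list(p.index)
    return GroundTruth(
        categories=sequenced,
        shares=shares,
        subclass=subclass,
        sites=sites,
        morphologies=morphs,
        genes=genes,
        p=p,
        studies=studies,
        patients_per_category=sizes,
        overlap_fraction=float(rates.get("overlap", 0.0)),
        longitudinal_rate=float(rates.get("longitudinal", 0.0)),
        alias_rate=float(rates.get("alias", 0.0)),
        excluded_class_rate=float(rates.get("excluded_class", 0.0)),
        synonyms={f"{g}_ALIAS": g for g in genes[::3]},
        registry_total=int(cfg.get("registry_total", 1_000_000)),
    )
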