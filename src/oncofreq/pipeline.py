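"""End-to-end orchestration: map → incidence → cohorts → estimates → CIs.

Each stage logs a QC checkpoint (record and patient totals), mirroring the
conservation checks a registry analysis needs: totals may only drop where a
documented filter applies, and the drop is recorded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .categories import UNMAPPED, load_category_map
from .epi import (
    IncidenceVector,
    build_incidence_table,
    coverage_fraction,
    incidence_vector,
    read_registry,
    restrict_and_normalize,
    top_categories_share,
    write_incidence_vector,
)
from .estimator import (
    compare_unweighted,
    contribution_breakdown,
    subclass_estimates,
    union_proportion,
    weighted_proportions,
)
from .genomic import (
    assign_patients,
    conditional_matrix,
    dedup_roster,
    dedup_samples,
    filter_mutation_classes,
    load_manifest,
    load_synonym_map,
    parse_maf,
    read_sample_table,
    standardize_gene_names,
    tally_cohort,
)
from .uncertainty import estimate_with_ci

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    registry: Path
    category_map: Path
    study_assignments: Path
    manifest: Path
    synonyms: Path | None = None
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    union_gene_lists: dict[str, list[str]] = field(default_factory=dict)
    subclasses: list[str] = field(default_factory=list)
    n_reps: int = 2000
    seed: int | None = None
    ci_level: float = 0.95
    top_n: int = 50
    out_dir: Path = Path("oncofreq_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        base = Path(path).parent
        def _p(key: str, optional: bool = False) -> Path | None:
            if key not in cfg or cfg[key] is None:
                if optional:
                    return None
                raise ConfigError(f"config missing required path {key!r}")
            return base / cfg[key]
        rc = cls(
            registry=_p("registry"),
            category_map=_p("category_map"),
            study_assignments=_p("study_assignments"),
            manifest=_p("manifest"),
            synonyms=_p("synonyms", optional=True),
            gene_sets={k: list(v) for k, v in cfg.get("gene_sets", {}).items()},
            union_gene_lists={k: list(v) for k, v in cfg.get("unions", {}).items()},
            subclasses=list(cfg.get("subclasses", [])),
            n_reps=int(cfg.get("n_reps", 2000)),
            seed=cfg.get("seed"),
            ci_level=float(cfg.get("ci_level", 0.95)),
            top_n=int(cfg.get("top_n", 50)),
            out_dir=base / cfg.get("out_dir", "oncofreq_out"),
        )
        rc.validate()
        return rc

    def validate(self) -> None:
        for name in ("registry", "category_map", "study_assignments", "manifest"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if self.synonyms is not None and not Path(self.synonyms).exists():
            raise ConfigError(f"synonyms path does not exist: {self.synonyms}")
        if self.n_reps >= 2 and self.seed is None:
            raise ConfigError("a seed is mandatory when confidence intervals are requested")


def build_cohort_matrix(roster, records, cmap, synonyms=None, gene_universe=None):
    """In-memory genomic stage: filter → dedup → standardize → tally → C.

    Returns ``(cohort, C)``.  ``run_pipeline`` is the file-based wrapper
    around this same sequence.
    """
    kept = filter_mutation_classes(records)
    kept = dedup_samples(kept, roster=roster)
    if synonyms:
        kept = standardize_gene_names(kept, synonyms)
    assignments = assign_patients(dedup_roster(roster), cmap)
    cohort = tally_cohort(kept, assignments)
    return cohort, conditional_matrix(cohort, gene_universe=gene_universe)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the JSON-serializable report; writes estimates, contributions,
    comparison, incidence and count TSVs plus ``report.json`` to
    ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc: list[dict] = []

    cmap = load_category_map(config.category_map, config.study_assignments)

    # Epidemiology: registry -> S -> S'.
    records_epi = read_registry(config.registry)
    input_total = sum(c for _, _, c in records_epi)
    table = build_incidence_table(records_epi, cmap)
    if table.total != input_total:
        raise ConfigError(
            f"conservation violated: registry total {input_total} != table total {table.total}"
        )
    qc.append({"stage": "registry", "total": input_total, "conserved": True})
    S_all = incidence_vector(table, include_unmapped=True)
    S = incidence_vector(table, include_unmapped=False)
    unmapped_mass = S_all.total - S.total
    qc.append({"stage": "incidence_vector", "mapped": S.total, "unmapped": unmapped_mass})

    # Genomics: rosters + MAFs -> deduped, filtered, standardized cohort.
    manifest = load_manifest(config.manifest)
    base = Path(config.manifest).parent
    roster, records = [], []
    for entry in manifest.values():
        roster.extend(
            read_sample_table(base / entry.samples_path, entry.study_id, entry.study_date)
        )
        records.extend(
            parse_maf(base / entry.maf_path, entry.study_id, entry.study_date)
        )
    qc.append({"stage": "ingest", "samples": len(roster), "mutation_rows": len(records)})

    kept = filter_mutation_classes(records)
    qc.append({"stage": "class_filter", "rows_in": len(records), "rows_kept": len(kept)})
    roster_primary = dedup_roster(roster)
    kept = dedup_samples(kept, roster=roster)
    qc.append({"stage": "dedup", "samples_kept": len(roster_primary), "rows_kept": len(kept)})
    if config.synonyms is not None:
        kept = standardize_gene_names(kept, load_synonym_map(config.synonyms))

    assignments = assign_patients(roster_primary, cmap)
    n_unmapped = sum(1 for c in assignments.values() if c == UNMAPPED)
    qc.append({"stage": "classify_samples", "patients": len(assignments),
               "unmapped_patients": n_unmapped})

    extra_genes = sorted(
        {g for gl in config.gene_sets.values() for g in gl}
        | {g for gl in config.union_gene_lists.values() for g in gl}
    )
    cohort = tally_cohort(kept, assignments)
    C = conditional_matrix(cohort, gene_universe=extra_genes)

    sequenced = set(C.category_list)
    coverage = coverage_fraction(S, sequenced)
    S_prime = restrict_and_normalize(S, sequenced)
    qc.append({"stage": "restrict", "sequenced_categories": len(sequenced),
               "coverage_fraction": coverage})

    if config.seed is not None:
        est = estimate_with_ci(
            C, S_prime, n_reps=config.n_reps, seed=config.seed,
            level=config.ci_level, coverage=coverage,
        )
        G = est.estimates
        est_frame = est.to_frame()
    else:
        G = weighted_proportions(C, S_prime)
        est_frame = pd.DataFrame({"proportion": G}).sort_values(
            "proportion", ascending=False, kind="mergesort"
        )

    est_frame.index.name = "gene"
    est_frame.to_csv(out / "estimates.tsv", sep="\t")
    write_incidence_vector(S, out / "incidence.tsv")
    counts = C.m.stack().rename("m").to_frame()
    counts["n"] = [C.n[cat] for _, cat in counts.index]
    counts.index.names = ["gene", "category_id"]
    counts.reset_index().to_csv(out / "counts.tsv", sep="\t", index=False)

    top_genes = est_frame.head(config.top_n).index
    contrib_rows = [
        {"gene": g, "category_id": cat, "share": share}
        for g in top_genes
        for cat, share in contribution_breakdown(g, C, S_prime)
    ]
    pd.DataFrame(contrib_rows, columns=["gene", "category_id", "share"]).to_csv(
        out / "contributions.tsv", sep="\t", index=False
    )
    comparison = compare_unweighted(C, G)
    comparison.index.name = "gene"
    comparison.to_csv(out / "comparison.tsv", sep="\t")

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_reps": config.n_reps if config.seed is not None else None,
        "coverage_fraction": coverage,
        "top10_incidence_share": top_categories_share(S, 10),
        "n_genes": len(C.gene_list),
        "n_categories": len(C.category_list),
        "n_patients": int(C.n.sum()),
        "qc": qc,
        "gene_sets": {},
        "unions": {},
        "subclasses": {},
    }
    for name, gene_list in config.gene_sets.items():
        view = G.reindex(gene_list).fillna(0.0).sort_values(ascending=False)
        report["gene_sets"][name] = view.head(config.top_n).round(6).to_dict()
    for name, gene_list in config.union_gene_lists.items():
        report["unions"][name] = union_proportion(cohort, gene_list, S_prime)
    for tag in config.subclasses:
        sub = subclass_estimates(C, S, tag, cmap)
        report["subclasses"][tag] = sub.sort_values(ascending=False).head(
            config.top_n
        ).round(6).to_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d genes, %d categories, coverage %.3f",
                len(C.gene_list), len(C.category_list), coverage)
    return report
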