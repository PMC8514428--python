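"""Reclassify registry-style incidence records onto analysis categories.

Builds a tiny taxonomy map, pushes a handful of (morphology, site, count)
records through it, and prints the incidence vector S with coverage numbers.
"""

from oncofreq import (
    CategoryMap,
    build_incidence_table,
    coverage_fraction,
    incidence_vector,
    restrict_and_normalize,
    top_categories_share,
)

cmap = CategoryMap()
cmap.add_entry("8140/3", "C18", "colorectal_ac")   # exact morphology+site
cmap.add_entry("8070/3", "C34", "lung_scc")
cmap.add_entry("8720/3", "*", "melanoma")          # wildcard: any site

records = [
    ("8140/3", "C18", 600),   # colorectal adenocarcinoma
    ("81403", "C18", 100),    # same code, registry dialect without the slash
    ("8070/3", "C34", 250),   # lung squamous cell carcinoma
    ("8720/3", "C44", 120),   # melanoma of skin, matched via wildcard
    ("9999/3", "C80", 30),    # unknown morphology: retained as UNMAPPED
]

table = build_incidence_table(records, cmap)
S = incidence_vector(table)
print(f"input total {sum(c for *_, c in records)}, table total {table.total} (conserved)")
print("incidence vector S:", dict(sorted(S.values.items())))

sequenced = {"colorectal_ac", "melanoma"}
print(f"coverage of sequenced categories: {coverage_fraction(S, sequenced):.3f}")
S_prime = restrict_and_normalize(S, sequenced)
print("S' (restricted, renormalized):",
      {c: round(v, 4) for c, v in sorted(S_prime.values.items())})
print(f"top-2 category share: {top_categories_share(S, 2):.3f}")
# The S' shares are the weights the estimator uses; the coverage fraction
# says how much of total incidence those weights actually represent.
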