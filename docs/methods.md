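# Methods

## Model

Let *h* index cancer categories on a common taxonomy and *g* index genes.
The quantity of interest is the population mutation proportion

    G_g = Σ_h c_gh · s′_h,

the probability that a newly diagnosed cancer carries at least one
qualifying mutation in gene *g*. `c_gh = m_gh / n_h` is estimated from
sequencing cohorts (m_gh = deduplicated patients of category *h* mutated in
*g*; n_h = all deduplicated sequenced patients of *h*, including those with
no qualifying mutation anywhere — the denominator is "sequenced", not
"mutated somewhere"). `s′_h` is the category's share of registry incidence
after restriction to sequenced categories and renormalization to 1.

The estimate over the sequenced coverage is reported as an estimate for all
cancers. That is an assumption, not a theorem: it holds insofar as the
unsequenced remainder resembles the sequenced majority. The coverage
fraction is therefore computed and carried with every estimate rather than
buried.

Contribution breakdowns decompose `G_g` as `w_gh = c_gh·s′_h / G_g`
(undefined and reported empty when `G_g = 0`). Multi-gene union proportions
are computed at patient level per category (`u_h = |patients mutated in any
listed gene| / n_h`) and then weighted — never as a sum of per-gene G
values, which overcounts co-mutated patients.

## Data cleaning rules

* **Variant-class whitelist** (case- and space/underscore-insensitive):
  nonsense_mutation, frame_shift_del, frame_shift, frame_shift_ins,
  missense_mutation, missense, nonsense, in_frame_del, in_frame_ins,
  nonstop_mutation. Splice-site, fusion, silent, UTR and intronic calls are
  dropped.
* **Longitudinal samples**: only a patient's first sample (smallest order
  hint; ties by sample id) within a study counts.
* **Cross-study overlap**: a patient appearing in several studies counts
  only in the study with the latest date; date ties resolve to the
  lexicographically greatest study id. The choice of winning sample is made
  from the study *roster*, not from the mutation rows, so a patient whose
  first sample happens to carry no calls is still handled correctly.
* **Gene symbols** are mapped through an alias→canonical synonym table;
  unknown symbols pass through and are logged. Multiplicity within a gene
  collapses to presence/absence after standardization.
* **Conservation**: registry reclassification never drops records; mass the
  map does not cover is an explicit UNMAPPED row, and the pipeline checks
  input total == table total at the QC checkpoint.

Classification precedence is a fixed contract: for registry records, exact
(morphology, site) beats the morphology wildcard; for sequenced samples,
explicit per-sample assignment beats a metadata predicate beats the study
default. Both are deterministic and tested with constructed collisions.

## Uncertainty

Sequencing cohorts (10³–10⁴ patients) are the dominant noise source next to
registry counts (~7×10⁶ diagnoses), so S′ is held fixed. Each replicate
draws `m*_gh ~ Poisson(m_gh)` independently per (gene, category), forms
proportions `min(m*_gh / n_h, 1)` and reweights. 2,000 replicates per
estimate; 95% CI = 2.5th/97.5th percentile with linear interpolation. Two
numerical choices deserve note: the Poisson perturbs the *numerator count*
(a rate-parameter reading of "central value"; proportion-space Poisson is
not well-defined), and proportions are clipped at 1, which matters only
when m_gh ≈ n_h. The Poisson variance m slightly exceeds the binomial
variance m(1−m/n), so intervals are mildly conservative for large c_gh;
empirical coverage on synthetic cohorts with c ≤ 0.2 is ~95–96%.

## Synthetic scenarios

The default scenario: six sequenced categories (breast, colorectal AC, lung
AC, melanoma, lung SCC, urothelial TCC) holding 93% of incidence plus an
unsequenced rare remainder at 7%; 40 genes with per-category qualifying
rates ~0.001–0.5 (drawn once from the scenario seed and recorded as truth);
three studies dated 2015/2017/2019 with overlapping category coverage;
cohort sizes 300–2,000 per category, deliberately unrelated to incidence;
registry total 7,167,808 diagnoses. Default nuisance rates: 5% cross-study
patient overlap, 5% longitudinal follow-up sampling, 10% alias symbols, 10%
excluded-class events.

`excluded_class_rate` is the probability that a mutation event is written
*only* with non-qualifying classes, so the truth the pipeline should
recover is `p_gh·(1−rate)`; at rate 1 every tallied count must be exactly 0.
Overlap duplicates re-publish a patient's qualifying profile under the
latest-dated covering study; longitudinal follow-ups carry a sentinel gene
that must never survive the first-sample rule. All randomness flows from
one seed through independent substreams per concern, so changing one rate
does not shift unrelated draws.

What the generator does *not* emulate: mutational signatures or positional
models (only presence/absence matters to the estimator), within-category
heterogeneity of mutation rates across studies, sample-quality artifacts,
and correlated co-mutation (genes are independent Bernoulli by default).
Passing tests therefore demonstrate estimator and pipeline correctness
under the assumed sampling model, not robustness to biological confounding
in real cohorts.

## Test and verification sizes

Unit and property tests run scenarios of 40–150 patients per category
(seconds). Parameter recovery is checked at 2,000 patients per category
across all 40 genes against a 3-standard-error band, with the binomial SE
`sqrt(Σ_h s′²_h p_gh(1−p_gh)/n_h)` computed from the recorded truth. CI
calibration regenerates 600 cohorts (10 genes × 3 categories, n=500,
qualifying rates 0.016–0.18) and checks pooled empirical coverage of the
2,000-replicate interval against 95% ± 3%; rates are capped at 0.2 because
the Poisson model is a small-rate approximation to the binomial sampling
that generates cohorts, and larger rates make the interval conservative by
construction. Estimator exactness is checked against a brute-force category
loop on 1,000 random instances at 1e-12.

## Known limitations

* The real-world taxonomy (hundreds of categories curated from ICD-O-3 and
  study metadata) is input data; this package ships only machinery plus
  small illustrative maps.
* Copy-number, fusion, splice-site and methylation alterations are out of
  scope, as are mortality- or prevalence-weighted variants of the estimate.
* No driver/passenger discrimination: counts include passengers.
* Denominator convention (all sequenced patients) is a documented choice;
  cohorts reporting only mutated samples would inflate c_gh and must be
  excluded upstream.
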