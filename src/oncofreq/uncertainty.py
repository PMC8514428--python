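"""Monte-Carlo confidence intervals for the weighted proportions.

Sampling noise is attributed to the sequencing cohorts: they are orders of
magnitude smaller than the registry counts, so the incidence shares are held
fixed.  For every (gene, category) pair the observed mutated-patient count
m_gh is the mean of a Poisson law; each replicate redraws all counts,
converts them to proportions against the fixed denominators n_h (clipped at
1, since a Poisson draw can exceed n_h when m_gh approaches it), and pushes
the replicate matrix through the same weighting as the point estimate.  The
95% interval is the 2.5th–97.5th percentile of the replicate G values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epi import IncidenceVector
from .estimator import ProportionEstimate, _aligned_shares, weighted_proportions
from .genomic import ConditionalMatrix

DEFAULT_N_REPS = 2000


class UncertaintyError(ValueError):
    pass


@dataclass
class ReplicateSet:
    """Replicate counts and the weighted proportions they induce."""

    counts: np.ndarray          # (n_reps, n_genes, n_categories) integer draws
    g_values: np.ndarray        # (n_reps, n_genes)
    gene_list: list[str]
    category_list: list[str]
    seed: int
    n_reps: int


def simulate_replicates(
    C: ConditionalMatrix,
    S_prime: IncidenceVector,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Draw Poisson replicates of the count matrix and reweight each one.

    ``seed`` (or an explicit generator) is mandatory: replicate sets are part
    of reported results and must be reproducible.  Same seed, same bits.
    """
    if n_reps < 2:
        raise UncertaintyError(f"n_reps must be >= 2, got {n_reps}")
    if rng is None:
        if seed is None:
            raise UncertaintyError("a seed (or generator) is required for replicates")
        rng = np.random.default_rng(seed)
    shares = _aligned_shares(C, S_prime).to_numpy()
    m = C.m.to_numpy()
    n = C.n.to_numpy()
    counts = rng.poisson(lam=m, size=(n_reps, *m.shape))
    proportions = np.clip(counts / n, 0.0, 1.0)
    g_values = proportions @ shares
    return ReplicateSet(
        counts=counts,
        g_values=g_values,
        gene_list=C.gene_list,
        category_list=C.category_list,
        seed=int(seed) if seed is not None else -1,
        n_reps=n_reps,
    )


def percentile_ci(replicates: ReplicateSet, level: float = 0.95) -> pd.DataFrame:
    """Per-gene equal-tailed percentile interval of the replicate G values."""
    if not 0 < level <= 1:
        raise UncertaintyError(f"level must be in (0, 1], got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(replicates.g_values, [100 * alpha, 100 * (1 - alpha)], axis=0)
    return pd.DataFrame(
        {"ci_low": lo, "ci_high": hi}, index=pd.Index(replicates.gene_list, name="gene")
    )


def estimate_with_ci(
    C: ConditionalMatrix,
    S_prime: IncidenceVector,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    level: float = 0.95,
    coverage: float | None = None,
) -> ProportionEstimate:
    """Point estimate G = C·S' plus its percentile CI in one call."""
    G = weighted_proportions(C, S_prime)
    reps = simulate_replicates(C, S_prime, n_reps=n_reps, seed=seed)
    ci = percentile_ci(reps, level=level)
    return ProportionEstimate(estimates=G, ci=ci, coverage=coverage, seed=seed)
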