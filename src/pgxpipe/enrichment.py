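"""Permutation test for pharmacogene over-representation in selection-scan
gene sets, plus the normal-approximation empirical p-value.

The null resamples the signature: each permutation draws ``signature_size``
gene ids uniformly without replacement from a universe of ``universe_size``
genes and records how many land in the pharmacogene set. The permutation
p-value is the inclusive upper tail, (# null overlaps >= observed) /
n_permutations; the empirical p-value standardises the observed overlap
against the permutation null and takes the upper standard-normal tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np
from scipy.stats import norm


class DegenerateNullError(ValueError):
    """The permutation null has zero spread; z-scores are undefined."""


@dataclass
class EnrichmentResult:
    statistic_name: str
    observed_overlap: int
    n_permutations: int
    null_overlaps: np.ndarray
    p_permutation: float
    p_empirical_normal: float
    null_mean: float
    null_sd: float

    def formatted_p(self) -> str:
        """Permutation p for display; a zero count reports '< 1/n'."""
        if self.p_permutation == 0.0:
            return f"< {1 / self.n_permutations:g}"
        return f"{self.p_permutation:g}"


def observed_overlap(
    signature_set: Collection[str], pharmacogene_set: Collection[str]
) -> int:
    """Number of signature genes that are pharmacogenes."""
    return len(set(signature_set) & set(pharmacogene_set))


def _null_overlap_draws(
    universe_size: int,
    n_pharmacogenes: int,
    signature_size: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised uniform subset draws.

    Assigning each gene a random key and keeping the ``signature_size``
    smallest keys is a uniform draw without replacement; by exchangeability
    the pharmacogenes can sit at indices < n_pharmacogenes. Chunked to bound
    memory at large universe sizes.
    """
    out = np.empty(n_permutations, dtype=np.int64)
    chunk = max(1, int(2e7) // max(universe_size, 1))
    kth = signature_size - 1
    for i in range(0, n_permutations, chunk):
        m = min(chunk, n_permutations - i)
        keys = rng.random((m, universe_size))
        if signature_size == universe_size:
            idx = np.broadcast_to(np.arange(universe_size), (m, universe_size))
        else:
            idx = np.argpartition(keys, kth, axis=1)[:, :signature_size]
        out[i : i + m] = (idx < n_pharmacogenes).sum(axis=1)
    return out


def empirical_p_normal(observed: float, null_mean: float, null_sd: float) -> float:
    """Upper-tail standard-normal probability of the standardised overlap."""
    if null_sd < 0:
        raise ValueError("null_sd must be non-negative")
    if null_sd == 0:
        raise DegenerateNullError("null standard deviation is zero; cannot standardize")
    return float(norm.sf((observed - null_mean) / null_sd))


def permutation_enrichment(
    universe_size: int,
    pharmacogene_set: Collection[str],
    signature_size: int,
    observed: int,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    statistic_name: str = "statistic",
) -> EnrichmentResult:
    """Permutation test of pharmacogene enrichment in one signature set.

    ``pharmacogene_set`` contributes only its cardinality to the uniform
    null; ``observed`` is the actual overlap (see :func:`observed_overlap`).
    """
    if signature_size > universe_size:
        raise ValueError(
            f"signature_size {signature_size} exceeds universe_size {universe_size}"
        )
    if signature_size < 0 or universe_size < 1:
        raise ValueError("universe_size must be >= 1 and signature_size >= 0")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n_pgx = len(set(pharmacogene_set))
    if n_pgx > universe_size:
        raise ValueError("more pharmacogenes than genes in the universe")
    if observed < 0 or observed > min(signature_size, n_pgx):
        raise ValueError("observed overlap outside its feasible range")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nulls = _null_overlap_draws(universe_size, n_pgx, signature_size, n_permutations, rng)
    p_perm = float((nulls >= observed).sum() / n_permutations)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1)) if n_permutations > 1 else 0.0
    if null_sd > 0:
        p_norm = empirical_p_normal(observed, null_mean, null_sd)
    else:
        p_norm = float("nan")
    return EnrichmentResult(
        statistic_name=statistic_name,
        observed_overlap=int(observed),
        n_permutations=int(n_permutations),
        null_overlaps=nulls,
        p_permutation=p_perm,
        p_empirical_normal=p_norm,
        null_mean=null_mean,
        null_sd=null_sd,
    )


def enrich_signatures(
    universe_size: int,
    pharmacogene_set: Collection[str],
    signatures: dict[str, Collection[str]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Run the permutation test for each named signature set."""
    rng = np.random.default_rng(seed)
    results = []
    for name, members in signatures.items():
        obs = observed_overlap(members, pharmacogene_set)
        results.append(
            permutation_enrichment(
                universe_size,
                pharmacogene_set,
                signature_size=len(set(members)),
                observed=obs,
                n_permutations=n_permutations,
                seed=rng,
                statistic_name=name,
            )
        )
    return results


def results_to_frame(results: list[EnrichmentResult]):
    """TSV-ready summary: one row per statistic."""
    import pandas as pd

    return pd.DataFrame(
        {
            "statistic": [r.statistic_name for r in results],
            "observed": [r.observed_overlap for r in results],
            "n_permutations": [r.n_permutations for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "p_permutation": [r.p_permutation for r in results],
            "p_permutation_display": [r.formatted_p() for r in results],
            "p_empirical_normal": [r.p_empirical_normal for r in results],
        }
    )
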