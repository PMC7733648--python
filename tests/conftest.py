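"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from codkin import SimConfig, simulate_dataset


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never call the implementation path
# they are used to check)
# ---------------------------------------------------------------------------

def gamete(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete (0/1 allele per locus) from a diploid allele-count vector."""
    return (rng.random(parent.shape) < parent / 2.0).astype(float)


def make_families(p: np.ndarray, sizes: list[int], rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes for full-sib families of the given sizes under HWE parents.

    Returns (calls, family_labels)."""
    rows, labels = [], []
    for fam, size in enumerate(sizes):
        dam = rng.binomial(2, p).astype(float)
        sire = rng.binomial(2, p).astype(float)
        for _ in range(size):
            rows.append(gamete(dam, rng) + gamete(sire, rng))
            labels.append(fam)
    return np.vstack(rows), np.asarray(labels)


def allele_sharing_r(g1: np.ndarray, g2: np.ndarray, p: np.ndarray) -> float:
    """Pedigree-free relatedness oracle: mean standardized genotype product.

    E[(g1 − 2p)(g2 − 2p)] = 2 p (1 − p) r for a dyad with relatedness r, so
    averaging the normalized cross-product over loci estimates r directly.
    """
    num = (g1 - 2 * p) * (g2 - 2 * p)
    den = 2 * p * (1 - p)
    return float(np.mean(num / den))


def grid_ml(A: np.ndarray, step: float = 0.001) -> tuple[np.ndarray, float]:
    """Brute-force ML over the (k0,k1,k2) simplex at the given grid step.

    A: (3, L) per-locus likelihoods for each IBD mode.  Returns the best k
    and its log-likelihood."""
    k0 = np.arange(0.0, 1.0 + step / 2, step)
    grid = []
    for a in k0:
        k1 = np.arange(0.0, 1.0 - a + step / 2, step)
        ks = np.column_stack([np.full_like(k1, a), k1, 1.0 - a - k1])
        grid.append(ks)
    ks = np.vstack(grid)
    with np.errstate(divide="ignore"):
        ll = np.log(np.clip(ks @ A, 1e-300, None)).sum(axis=1)
    i = int(np.argmax(ll))
    return ks[i], float(ll[i])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated study: 2 cohort years, one planted
    repeat pair, a few percent stocked outbreds."""
    cfg = SimConfig(n_loci=400, n_adult_pairs=20, n_years=2, multi_year_pairs=1,
                    nests_per_year=4, larvae_per_nest_range=(3, 4),
                    outbred_fraction=0.06, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free single-purpose dataset: no genotyping error, no missingness,
    no outbreds, exact otolith ageing."""
    cfg = SimConfig(n_loci=300, n_adult_pairs=16, n_years=2, multi_year_pairs=0,
                    nests_per_year=4, larvae_per_nest_range=(3, 4),
                    genotyping_error_rate=0.0, missing_rate=0.0,
                    outbred_fraction=0.0, otolith_noise_sd_mm=0.0,
                    age_reading_noise_sd_days=0.0, seed=7)
    return simulate_dataset(cfg)
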