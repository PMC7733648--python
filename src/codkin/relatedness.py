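"""Pairwise relatedness and individual inbreeding from SNP genotypes.

Two estimators of the relatedness coefficient r are provided, both operating
on biallelic allele-count genotypes with population allele frequencies
estimated from the sample:

* ``qg`` — the Queller–Goodnight moment estimator, symmetrized by averaging
  the two directional estimates after summing numerators and denominators
  across loci.  Unbiased, unbounded (can go negative), fast.
* ``dyadml`` — dyadic maximum likelihood over the non-inbred IBD-mode simplex
  (k0, k1, k2): the per-locus likelihood is a 3-component mixture of the
  joint genotype probabilities given 0, 1 or 2 alleles shared identical by
  descent, with a symmetric per-allele genotyping-error rate folded into the
  emission probabilities.  The mixture log-likelihood is concave in k, so EM
  from an interior start converges to the global maximum; r = k2 + k1/2.

Per-individual inbreeding F is the method-of-moments excess-homozygosity
statistic; strongly negative F (excess heterozygosity) flags outbred,
hatchery-origin individuals which are screened out before sibship analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "DyadEstimate",
    "InbreedingEstimate",
    "estimate_allele_frequencies",
    "queller_goodnight_r",
    "dyadic_ml_r",
    "pairwise_relatedness",
    "inbreeding_coefficient",
    "inbreeding_coefficients",
    "screen_outbreds",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_JOINT_LOCI = 100
DEFAULT_ERROR_RATE = 0.01
OUTBRED_F_THRESHOLD = -0.4


@dataclass
class AlleleFrequencies:
    """Sample allele frequencies with a retained-locus mask.

    ``values[l]`` is the frequency of the scored allele at locus ``l`` and is
    NaN for excluded loci (all-missing, non-polymorphic, or above the
    missingness ceiling).
    """

    values: np.ndarray
    retained: np.ndarray
    n_excluded: int

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class DyadEstimate:
    """Relatedness estimate for one unordered pair of individuals."""

    id_a: str
    id_b: str
    estimator: str
    r: float
    k0: float
    k1: float
    k2: float
    loci_used: int
    flag: str = ""  # "" = usable; otherwise reason the dyad is unusable


@dataclass
class InbreedingEstimate:
    larva_id: str
    F: float
    loci_used: int
    flag: str = ""


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def estimate_allele_frequencies(g: GenotypeMatrix,
                                max_missing: float = 0.5) -> AlleleFrequencies:
    """Per-locus scored-allele frequency f = mean allele count / 2.

    Loci that are all-missing, non-polymorphic (f outside (0,1)) or missing in
    more than ``max_missing`` of samples are excluded (frequency set to NaN).
    """
    calls = g.calls
    n_obs = (~np.isnan(calls)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nanmean(calls, axis=0) / 2.0
    miss_frac = 1.0 - n_obs / g.n_samples
    retained = (n_obs > 0) & (f > 0.0) & (f < 1.0) & (miss_frac <= max_missing)
    n_excluded = int((~retained).sum())
    if n_excluded:
        logger.info("excluded %d of %d loci (all-missing, non-polymorphic or "
                    "missingness > %.2f)", n_excluded, g.n_loci, max_missing)
    values = np.where(retained, f, np.nan)
    return AlleleFrequencies(values=values, retained=retained, n_excluded=n_excluded)


def _freq_values(g: GenotypeMatrix, freqs) -> np.ndarray:
    if freqs is None:
        freqs = estimate_allele_frequencies(g)
    if isinstance(freqs, AlleleFrequencies):
        return freqs.values
    return np.asarray(freqs, dtype=float)


# ---------------------------------------------------------------------------
# Queller–Goodnight moment estimator (batched core)
# ---------------------------------------------------------------------------

def _qg_batch(G1: np.ndarray, G2: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized Queller–Goodnight r for D dyads.

    G1, G2: (D, L) allele counts with NaN missing; p: (L,) frequencies with
    NaN for excluded loci.  Returns (r, loci_used); r is NaN where the summed
    denominator vanishes.
    """
    G1 = np.atleast_2d(G1)
    G2 = np.atleast_2d(G2)
    m = ~np.isnan(G1) & ~np.isnan(G2) & ~np.isnan(p)
    g1 = np.where(m, G1, 0.0)
    g2 = np.where(m, G2, 0.0)
    pp = np.where(np.isnan(p), 0.5, p)

    sim = np.where((g1 == 1) & (g2 == 1), 1.0, 2.0 - np.abs(g1 - g2))
    two_p_minus_1 = 2.0 * pp - 1.0
    psum1 = 1.0 + (g1 - 1.0) * two_p_minus_1
    psum2 = 1.0 + (g2 - 1.0) * two_p_minus_1
    num1 = np.where(m, sim - psum1, 0.0)
    num2 = np.where(m, sim - psum2, 0.0)
    den1 = np.where(m, 1.0 + (g1 != 1.0) - psum1, 0.0)
    den2 = np.where(m, 1.0 + (g2 != 1.0) - psum2, 0.0)

    s_n1, s_d1 = num1.sum(axis=1), den1.sum(axis=1)
    s_n2, s_d2 = num2.sum(axis=1), den2.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 0.5 * (s_n1 / s_d1 + s_n2 / s_d2)
    r = np.where((s_d1 == 0) | (s_d2 == 0), np.nan, r)
    return r, m.sum(axis=1)


# ---------------------------------------------------------------------------
# dyadic ML (batched EM core)
# ---------------------------------------------------------------------------

def _emission_matrix(error_rate: float) -> np.ndarray:
    """3×3 matrix E[true, observed] for symmetric per-allele flips."""
    e = error_rate
    return np.array([
        [(1 - e) ** 2, 2 * e * (1 - e), e ** 2],
        [e * (1 - e), (1 - e) ** 2 + e ** 2, e * (1 - e)],
        [e ** 2, 2 * e * (1 - e), (1 - e) ** 2],
    ])


def _joint_mode_tensors(p: np.ndarray, error_rate: float) -> np.ndarray:
    """Observed joint genotype probabilities O[mode, locus, g1, g2].

    mode m ∈ {0,1,2} = number of alleles shared IBD at the locus; p is the
    frequency of the scored allele per locus (NaN loci get placeholder 0.5 —
    they must be masked out by the caller).
    """
    pp = np.where(np.isnan(p), 0.5, np.asarray(p, dtype=float))
    q = 1.0 - pp
    L = pp.size
    P0 = np.stack([q ** 2, 2 * pp * q, pp ** 2], axis=-1)          # (L, 3)

    J = np.zeros((3, L, 3, 3))
    J[0] = P0[:, :, None] * P0[:, None, :]
    # one shared IBD allele
    J[1, :, 0, 0] = q ** 3
    J[1, :, 0, 1] = J[1, :, 1, 0] = pp * q ** 2
    J[1, :, 1, 1] = pp * q
    J[1, :, 1, 2] = J[1, :, 2, 1] = pp ** 2 * q
    J[1, :, 2, 2] = pp ** 3
    # two shared IBD alleles: identical genotypes
    idx = np.arange(3)
    J[2, :, idx, idx] = P0.T

    E = _emission_matrix(error_rate)
    # O[m, l, a, b] = sum_ij E[i,a] E[j,b] J[m, l, i, j]
    return np.einsum("ia,jb,mlij->mlab", E, E, J, optimize=True)


def _mode_likelihoods(O: np.ndarray, G1: np.ndarray, G2: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus mode likelihoods A[d, m, l] and joint-call mask for D dyads."""
    G1 = np.atleast_2d(G1)
    G2 = np.atleast_2d(G2)
    m = ~np.isnan(G1) & ~np.isnan(G2)
    g1 = np.where(m, G1, 0.0).astype(int)
    g2 = np.where(m, G2, 0.0).astype(int)
    lidx = np.arange(G1.shape[1])[None, :]
    A = O[:, lidx, g1, g2]           # (3, D, L)
    A = np.moveaxis(A, 0, 1)         # (D, 3, L)
    return A, m


def _em_step(k: np.ndarray, A: np.ndarray, w: np.ndarray,
             n_used: np.ndarray) -> np.ndarray:
    T = np.einsum("dm,dml->dl", k, A)
    T = np.where(T > 0, T, 1.0)
    resp = (k[:, :, None] * A / T[:, None, :]) * w[:, None, :]
    k_new = resp.sum(axis=2) / n_used[:, None]
    return k_new / k_new.sum(axis=1, keepdims=True)


def _loglik(k: np.ndarray, A: np.ndarray, w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        T = np.einsum("dm,dml->dl", k, A)
        return np.where(w > 0, np.log(np.where(T > 0, T, 1.0)), 0.0).sum(axis=1)


def _em_dyad_ml(A: np.ndarray, mask: np.ndarray, max_iter: int = 100,
                tol: float = 1e-8, start: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accelerated EM (SQUAREM) for mixture weights k over IBD modes, batched.

    A: (D, 3, L) per-locus mode likelihoods; mask: (D, L) usable loci.
    Each cycle takes two EM steps, extrapolates with the squared step-length
    rule, and falls back to the plain EM iterate whenever the extrapolation
    lowers the likelihood (the log-likelihood is concave, so monotone ascent
    to the global optimum is preserved).  Returns (k, loglik, converged).
    ``max_iter`` counts acceleration cycles (~3 EM steps each).
    """
    D, _, L = A.shape
    w = mask.astype(float)
    k = np.full((D, 3), 1.0 / 3.0) if start is None else np.array(start, dtype=float)
    converged = np.zeros(D, dtype=bool)
    # active set: dyads are frozen once their k stops moving
    active = np.arange(D)
    Aa, wa, ka = A, w, k.copy()
    na = np.maximum(wa.sum(axis=1), 1.0)
    for _ in range(max_iter):
        k1 = _em_step(ka, Aa, wa, na)
        k2 = _em_step(k1, Aa, wa, na)
        rstep = k1 - ka
        vstep = (k2 - k1) - rstep
        rn = np.linalg.norm(rstep, axis=1)
        vn = np.linalg.norm(vstep, axis=1)
        alpha = -np.where(vn > 0, rn / np.where(vn > 0, vn, 1.0), 1.0)
        alpha = np.minimum(alpha, -1.0)[:, None]
        k_acc = ka - 2.0 * alpha * rstep + alpha ** 2 * vstep
        k_acc = np.clip(k_acc, 1e-12, None)
        k_acc /= k_acc.sum(axis=1, keepdims=True)
        k_prop = _em_step(k_acc, Aa, wa, na)
        worse = _loglik(k_prop, Aa, wa) < _loglik(k2, Aa, wa)
        k_prop[worse] = k2[worse]
        delta = np.abs(k_prop - ka).max(axis=1)
        ka = k_prop
        done = delta < tol
        if done.any():
            k[active[done]] = ka[done]
            converged[active[done]] = True
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            Aa, wa, ka, na = Aa[keep], wa[keep], ka[keep], na[keep]
    if active.size:
        k[active] = ka
    return k, _loglik(k, A, w), converged


def _corner_logliks(A: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Log-likelihood at each simplex corner (pure IBD mode), (D, 3)."""
    with np.errstate(divide="ignore"):
        logA = np.log(A)
    logA = np.where(mask[:, None, :], logA, 0.0)
    return logA.sum(axis=2)


def _ml_batch(G1: np.ndarray, G2: np.ndarray, p: np.ndarray, error_rate: float,
              max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Dyadic ML for D dyads. Returns (k (D,3), r, loci_used, flags)."""
    O = _joint_mode_tensors(p, error_rate)
    A, mask = _mode_likelihoods(O, G1, G2)
    mask = mask & ~np.isnan(p)[None, :]
    k, loglik, converged = _em_dyad_ml(A, mask, max_iter=max_iter)

    # the log-likelihood is concave, so an interior EM fixed point is the
    # global optimum; retry non-converged dyads from near-corner starts
    if (~converged).any():
        starts = np.array([[0.96, 0.02, 0.02], [0.02, 0.96, 0.02], [0.02, 0.02, 0.96]])
        for s in starts:
            idx = np.where(~converged)[0]
            ks = np.broadcast_to(s, (idx.size, 3)).copy()
            k2, ll2, _ = _em_dyad_ml(A[idx], mask[idx], max_iter=max_iter, start=ks)
            better = ll2 > loglik[idx]
            k[idx[better]] = k2[better]
            loglik[idx[better]] = ll2[better]

    # a boundary optimum can sit exactly on a corner that EM only approaches
    # asymptotically; take the argmax over {EM solution, corners}
    corners = _corner_logliks(A, mask)
    best_c = corners.max(axis=1)
    take = best_c > loglik
    if take.any():
        eye = np.eye(3)
        k[take] = eye[corners.argmax(axis=1)[take]]
        loglik[take] = best_c[take]

    r = k[:, 2] + 0.5 * k[:, 1]
    flags = np.where(np.isfinite(loglik), "", "degenerate")
    return k, r, mask.sum(axis=1), flags


# ---------------------------------------------------------------------------
# public per-pair and all-pairs interfaces
# ---------------------------------------------------------------------------

def queller_goodnight_r(g: GenotypeMatrix, pair: tuple[str, str], freqs=None,
                        min_joint_loci: int = DEFAULT_MIN_JOINT_LOCI) -> DyadEstimate:
    """Symmetrized Queller–Goodnight moment estimate of r for one dyad."""
    p = _freq_values(g, freqs)
    a, b = pair
    r, n = _qg_batch(g.row(a), g.row(b), p)
    flag = ""
    if n[0] < min_joint_loci:
        flag = f"too_few_joint_loci ({int(n[0])} < {min_joint_loci})"
    elif np.isnan(r[0]):
        flag = "zero_denominator"
    return DyadEstimate(id_a=a, id_b=b, estimator="qg", r=float(r[0]),
                        k0=np.nan, k1=np.nan, k2=np.nan,
                        loci_used=int(n[0]), flag=flag)


def dyadic_ml_r(g: GenotypeMatrix, pair: tuple[str, str], freqs=None,
                error_rate: float = DEFAULT_ERROR_RATE,
                min_joint_loci: int = DEFAULT_MIN_JOINT_LOCI) -> DyadEstimate:
    """Dyadic maximum-likelihood (k0,k1,k2) and r = k2 + k1/2 for one dyad."""
    p = _freq_values(g, freqs)
    a, b = pair
    k, r, n, flags = _ml_batch(g.row(a)[None, :], g.row(b)[None, :], p, error_rate)
    flag = flags[0]
    if n[0] < min_joint_loci:
        flag = f"too_few_joint_loci ({int(n[0])} < {min_joint_loci})"
    return DyadEstimate(id_a=a, id_b=b, estimator="dyadml", r=float(r[0]),
                        k0=float(k[0, 0]), k1=float(k[0, 1]), k2=float(k[0, 2]),
                        loci_used=int(n[0]), flag=flag)


def pairwise_relatedness(g: GenotypeMatrix, estimator: str = "dyadml", freqs=None,
                         error_rate: float = DEFAULT_ERROR_RATE,
                         min_joint_loci: int = DEFAULT_MIN_JOINT_LOCI,
                         pairs: list[tuple[str, str]] | None = None,
                         chunk_elems: float = 1.5e7) -> pd.DataFrame:
    """Relatedness for all (or listed) sample pairs, batched.

    Returns a DataFrame with columns
    ``id_a, id_b, estimator, r, k0, k1, k2, loci_used, flag``.
    """
    if estimator not in ("qg", "dyadml"):
        raise ValueError(f"unknown estimator {estimator!r}")
    p = _freq_values(g, freqs)
    if pairs is None:
        pairs = list(itertools.combinations([str(s) for s in g.ids], 2))
    if not pairs:
        return pd.DataFrame(columns=["id_a", "id_b", "estimator", "r",
                                     "k0", "k1", "k2", "loci_used", "flag"])
    ia = np.array([g._index[a] for a, _ in pairs])
    ib = np.array([g._index[b] for _, b in pairs])

    chunk = max(1, int(chunk_elems / max(3 * g.n_loci, 1)))
    frames = []
    for s in range(0, len(pairs), chunk):
        sl = slice(s, s + chunk)
        G1 = g.calls[ia[sl]]
        G2 = g.calls[ib[sl]]
        if estimator == "qg":
            r, n = _qg_batch(G1, G2, p)
            k0 = k1 = k2 = np.full(r.size, np.nan)
            flags = np.where(np.isnan(r), "zero_denominator", "")
        else:
            k, r, n, flags = _ml_batch(G1, G2, p, error_rate)
            k0, k1, k2 = k[:, 0], k[:, 1], k[:, 2]
        flags = np.asarray(flags, dtype=object)
        low = n < min_joint_loci
        flags[low] = "too_few_joint_loci"
        frames.append(pd.DataFrame({
            "id_a": [a for a, _ in pairs[sl]], "id_b": [b for _, b in pairs[sl]],
            "estimator": estimator, "r": r, "k0": k0, "k1": k1, "k2": k2,
            "loci_used": n.astype(int), "flag": flags,
        }))
    out = pd.concat(frames, ignore_index=True)
    n_bad = int((out["flag"] != "").sum())
    if n_bad:
        logger.warning("%d of %d dyads flagged unusable", n_bad, len(out))
    return out


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------

def inbreeding_coefficients(g: GenotypeMatrix, freqs=None,
                            min_loci: int = DEFAULT_MIN_JOINT_LOCI) -> pd.DataFrame:
    """Method-of-moments F = 1 − (observed het / expected het) per individual.

    Expected heterozygosity is Σ 2f(1−f) over the individual's non-missing
    retained loci; F is clamped to [−1, 1].  Negative F marks excess
    heterozygosity (outbred signal).
    """
    p = _freq_values(g, freqs)
    usable = ~np.isnan(g.calls) & ~np.isnan(p)[None, :]
    het = ((g.calls == 1.0) & usable).sum(axis=1)
    exp_het_locus = 2.0 * p * (1.0 - p)
    exp_het = np.where(usable, exp_het_locus[None, :], 0.0).sum(axis=1)
    n = usable.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = 1.0 - het / exp_het
    F = np.clip(F, -1.0, 1.0)
    flags = np.where(exp_het == 0, "undefined_expected_het",
                     np.where(n < min_loci, "too_few_loci", ""))
    F = np.where(exp_het == 0, np.nan, F)
    return pd.DataFrame({"larva_id": g.ids, "F": F, "loci_used": n.astype(int),
                         "flag": flags})


def inbreeding_coefficient(g: GenotypeMatrix, larva_id: str, freqs=None,
                           min_loci: int = DEFAULT_MIN_JOINT_LOCI) -> InbreedingEstimate:
    """F for a single individual (see :func:`inbreeding_coefficients`)."""
    df = inbreeding_coefficients(g.subset([larva_id]), freqs=_freq_values(g, freqs),
                                 min_loci=min_loci)
    row = df.iloc[0]
    return InbreedingEstimate(larva_id=larva_id, F=float(row["F"]),
                              loci_used=int(row["loci_used"]), flag=row["flag"])


def screen_outbreds(estimates: pd.DataFrame,
                    threshold: float = OUTBRED_F_THRESHOLD
                    ) -> tuple[list[str], pd.DataFrame]:
    """Partition individuals into retained / excluded by the F screen.

    Individuals with F strictly below ``threshold`` (default −0.4) are flagged
    as outbred (stocked origin) and excluded from sibship analysis.
    Returns (retained ids, excluded table with F values).
    """
    if not (-1.0 < threshold <= 0.0):
        raise ValueError("inbreeding threshold must be in (-1, 0]")
    excluded = estimates[estimates["F"] < threshold].copy()
    retained = [str(s) for s in estimates.loc[estimates["F"] >= threshold, "larva_id"]]
    if len(excluded):
        logger.info("excluded %d putative outbreds (F < %.2f): %s",
                    len(excluded), threshold,
                    ", ".join(f"{r.larva_id}={r.F:.2f}" for r in excluded.itertuples()))
    return retained, excluded
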