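"""Isotopic validation of genetic families as a permutation test.

Larvae inherit their δ13C/δ15N signature from maternal yolk provisioning, so
true full-sib families should be tight clusters in isotope space.  The family
cohesion statistic S is the mean (over families of size ≥ 2) of the mean
within-family pairwise Euclidean distance after per-axis standardization:
small S = cohesive families.  Significance comes from permuting family labels
among larvae (within cohort year by default, since baseline isotopes can
drift between years); the one-sided p-value is the fraction of permutations
at least as cohesive as observed, with the add-one correction
p = (1 + #{S_perm ≤ S_obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IsotopeTestResult", "family_cohesion_statistic", "permutation_test"]


@dataclass
class IsotopeTestResult:
    S_obs: float
    p_value: float
    n_perm: int
    seed: int
    null: np.ndarray
    stratified_by_year: bool

    def to_dict(self) -> dict:
        return {"S_obs": self.S_obs, "p": self.p_value,
                "n_perm": self.n_perm, "seed": self.seed,
                "stratify_by_year": self.stratified_by_year}


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def _cohesion(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean over families (size >= 2) of mean within-family pairwise distance."""
    means = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if idx.size < 2:
            continue
        sub = dist[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        means.append(sub[iu].mean())
    if not means:
        raise ValueError("no family of size >= 2; cohesion undefined")
    return float(np.mean(means))


def _prepare(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    required = {"d13C", "d15N", "family_id"}
    if not required.issubset(table.columns):
        raise ValueError(f"isotope table needs columns {sorted(required)}")
    vals = table[["d13C", "d15N"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("isotope values must be finite")
    z = _standardize(vals)
    diff = z[:, None, :] - z[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    labels = table["family_id"].to_numpy()
    years = (table["year"].to_numpy() if "year" in table.columns
             else np.zeros(len(table), dtype=int))
    return dist, labels, years


def family_cohesion_statistic(table: pd.DataFrame) -> float:
    """Observed family-cohesion statistic S (see module docstring)."""
    dist, labels, _ = _prepare(table)
    sizes = pd.Series(labels).value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 families of size >= 2")
    return _cohesion(dist, labels)


def permutation_test(table: pd.DataFrame, n_perm: int = 999, seed: int = 0,
                     stratify_by_year: bool = True) -> IsotopeTestResult:
    """One-sided permutation test of family isotopic cohesion.

    Family labels are shuffled among larvae (within year if stratified);
    the alternative is that observed families are more cohesive (smaller S)
    than random groupings of the same sizes.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful p-value")
    dist, labels, years = _prepare(table)
    sizes = pd.Series(labels).value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 families of size >= 2")
    s_obs = _cohesion(dist, labels)
    rng = np.random.default_rng(seed)
    strata = years if stratify_by_year else np.zeros(len(labels), dtype=int)
    null = np.empty(n_perm)
    perm = labels.copy()
    for b in range(n_perm):
        for stratum in np.unique(strata):
            idx = np.where(strata == stratum)[0]
            perm[idx] = perm[idx[rng.permutation(idx.size)]]
        null[b] = _cohesion(dist, perm)
    p = (1.0 + float(np.sum(null <= s_obs))) / (n_perm + 1.0)
    return IsotopeTestResult(S_obs=s_obs, p_value=p, n_perm=n_perm, seed=seed,
                             null=null, stratified_by_year=stratify_by_year)
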