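"""Full-sib classification and family-group assembly across cohort years.

The full-sib cutoff on the relatedness coefficient r is calibrated by
Monte-Carlo simulation: dyads of known relationship (full-sib, half-sib,
parent–offspring, unrelated) are generated by explicit gamete dropping from
the observed allele frequencies and the chosen estimator applied to each,
giving empirical r distributions per category.  Dyads with r above the cutoff
(fixed 0.4 by default, or chosen to minimize full-sib false negatives plus
half-sib false positives) are full-sib edges; families are the connected
components of the resulting network.  Because all larvae come from a ≤3-year
window and the species matures only after 4–5 years, above-cutoff dyads
cannot be parent–offspring.  A family whose members span two or more cohort
years implies the same mother–father pair re-mated in those years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import relatedness as rel

__all__ = [
    "CategoryDistributions",
    "CutoffReport",
    "FamilyAssignment",
    "simulate_category_r",
    "choose_cutoff",
    "classify_dyads",
    "build_families",
    "detect_multi_year_pairs",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("FS", "HS", "PO", "U")
DEFAULT_CUTOFF = 0.4


@dataclass
class CategoryDistributions:
    """Simulated r values per relationship category."""

    values: dict[str, np.ndarray]
    n_sim: int
    estimator: str
    seed: int

    def mean(self, category: str) -> float:
        return float(np.nanmean(self.values[category]))


@dataclass
class CutoffReport:
    cutoff: float
    mode: str
    fs_false_negative_rate: float
    hs_false_positive_rate: float
    warning: str = ""


@dataclass
class FamilyAssignment:
    """One putative family: a connected component of full-sib edges.

    The family id doubles as an arbitrary putative-mother label (it could as
    well be read as a putative-father label).
    """

    family_id: str
    members: tuple[str, ...]
    years: tuple[int, ...]
    edges: tuple[tuple[str, str], ...]
    is_clique: bool

    @property
    def multi_year(self) -> bool:
        return len(self.years) >= 2

    @property
    def sequential(self) -> bool:
        ys = sorted(self.years)
        return len(ys) >= 2 and ys == list(range(ys[0], ys[-1] + 1))


# ---------------------------------------------------------------------------
# Monte-Carlo calibration
# ---------------------------------------------------------------------------

def _drop_gamete(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(parent.shape) < parent / 2.0).astype(float)


def simulate_category_r(freqs, estimator: str = "qg", n_sim: int = 1000,
                        seed: int = 0, error_rate: float = 0.0,
                        chunk: int = 500) -> CategoryDistributions:
    """Empirical r distributions for FS/HS/PO/U dyads by gamete dropping.

    ``freqs`` is a per-locus allele-frequency vector (NaN loci are dropped).
    Genotypes are simulated error-free; ``error_rate`` is what the ML
    estimator assumes, mirroring calibration against idealized pedigrees.
    """
    p = np.asarray(freqs, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no usable allele frequencies")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {c: np.empty(n_sim) for c in CATEGORIES}
    for c in CATEGORIES:
        out = values[c]
        for s in range(0, n_sim, chunk):
            n = min(chunk, n_sim - s)
            shape = (n, p.size)
            if c == "FS":
                P1 = rng.binomial(2, p, size=shape).astype(float)
                P2 = rng.binomial(2, p, size=shape).astype(float)
                a = _drop_gamete(P1, rng) + _drop_gamete(P2, rng)
                b = _drop_gamete(P1, rng) + _drop_gamete(P2, rng)
            elif c == "HS":
                S = rng.binomial(2, p, size=shape).astype(float)
                O1 = rng.binomial(2, p, size=shape).astype(float)
                O2 = rng.binomial(2, p, size=shape).astype(float)
                a = _drop_gamete(S, rng) + _drop_gamete(O1, rng)
                b = _drop_gamete(S, rng) + _drop_gamete(O2, rng)
            elif c == "PO":
                a = rng.binomial(2, p, size=shape).astype(float)
                mate = rng.binomial(2, p, size=shape).astype(float)
                b = _drop_gamete(a, rng) + _drop_gamete(mate, rng)
            else:  # U
                a = rng.binomial(2, p, size=shape).astype(float)
                b = rng.binomial(2, p, size=shape).astype(float)
            if estimator == "qg":
                r, _ = rel._qg_batch(a, b, p)
            elif estimator == "dyadml":
                _, r, _, _ = rel._ml_batch(a, b, p, error_rate)
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            out[s:s + n] = r
    return CategoryDistributions(values=values, n_sim=n_sim, estimator=estimator,
                                 seed=seed)


def choose_cutoff(dists: CategoryDistributions, mode: str = "fixed",
                  fixed_value: float = DEFAULT_CUTOFF) -> CutoffReport:
    """Full-sib/half-sib cutoff with empirical misclassification rates.

    ``fixed`` returns ``fixed_value`` (default 0.4); ``auto`` picks the cutoff
    minimizing FS false-negative rate + HS false-positive rate, returned as
    the midpoint of the optimal gap between simulated values.
    """
    fs = np.asarray(dists.values["FS"])
    hs = np.asarray(dists.values["HS"])
    if fs.size == 0 or hs.size == 0:
        raise ValueError("FS and HS distributions must be non-empty")

    def rates(c: float) -> tuple[float, float]:
        return float(np.mean(fs <= c)), float(np.mean(hs > c))

    if mode == "fixed":
        fnr, fpr = rates(fixed_value)
        return CutoffReport(cutoff=fixed_value, mode=mode,
                            fs_false_negative_rate=fnr, hs_false_positive_rate=fpr)
    if mode != "auto":
        raise ValueError(f"unknown cutoff mode {mode!r}")

    candidates = np.unique(np.concatenate([fs, hs]))
    scores = np.array([sum(rates(c)) for c in candidates])
    i = int(np.argmin(scores))
    best = candidates[i]
    above = candidates[candidates > best]
    cutoff = float((best + above[0]) / 2.0) if above.size else float(best)
    fnr, fpr = rates(cutoff)
    warning = ""
    if fnr + fpr > 0.5:
        warning = ("FS and HS distributions overlap heavily; "
                   "misclassification rates near 0.5")
        logger.warning(warning)
    return CutoffReport(cutoff=cutoff, mode=mode, fs_false_negative_rate=fnr,
                        hs_false_positive_rate=fpr, warning=warning)


# ---------------------------------------------------------------------------
# classification and family assembly
# ---------------------------------------------------------------------------

def classify_dyads(dyads: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF,
                   sensitivity_band: float = 0.05) -> pd.DataFrame:
    """Keep full-sib edges: usable dyads with r strictly above the cutoff.

    Returns the edge table (id_a, id_b, r).  Dyads within ±``sensitivity_band``
    of the cutoff are counted and logged so borderline calls are visible.
    """
    if dyads.empty:
        return dyads.reindex(columns=["id_a", "id_b", "r"]).iloc[0:0]
    ok = dyads["flag"].fillna("").eq("") & dyads["r"].notna()
    near = ok & dyads["r"].between(cutoff - sensitivity_band, cutoff + sensitivity_band)
    if near.any():
        logger.info("%d dyads within ±%.2f of cutoff %.2f", int(near.sum()),
                    sensitivity_band, cutoff)
    keep = ok & (dyads["r"] > cutoff)
    return dyads.loc[keep, ["id_a", "id_b", "r"]].reset_index(drop=True)


def build_families(edges: pd.DataFrame, years: Mapping[str, int],
                   all_larvae: Sequence[str] | None = None
                   ) -> tuple[list[FamilyAssignment], list[str]]:
    """Families as connected components of the full-sib network.

    ``years`` maps larva id → cohort year.  Returns (families, singletons);
    singletons are larvae (from ``all_larvae`` or the year map) in no family.
    Non-clique components are flagged, not split.
    """
    G = nx.Graph()
    for row in edges.itertuples():
        if row.id_a not in years or row.id_b not in years:
            raise KeyError(f"edge ({row.id_a}, {row.id_b}) references unknown larva")
        G.add_edge(row.id_a, row.id_b, r=row.r)
    components = sorted(nx.connected_components(G), key=lambda c: min(c))
    families = []
    for i, comp in enumerate(components):
        members = tuple(sorted(comp))
        sub = G.subgraph(comp)
        n = len(members)
        is_clique = sub.number_of_edges() == n * (n - 1) // 2
        if not is_clique:
            logger.warning("family %s is not a clique (%d/%d edges present)",
                           f"M{i + 1:02d}", sub.number_of_edges(), n * (n - 1) // 2)
        families.append(FamilyAssignment(
            family_id=f"M{i + 1:02d}",
            members=members,
            years=tuple(sorted({int(years[m]) for m in members})),
            edges=tuple((a, b) if a < b else (b, a) for a, b in sub.edges()),
            is_clique=is_clique,
        ))
    universe = list(all_larvae) if all_larvae is not None else list(years)
    in_family = {m for f in families for m in f.members}
    singletons = [s for s in universe if s not in in_family]
    return families, singletons


def detect_multi_year_pairs(families: Sequence[FamilyAssignment]) -> pd.DataFrame:
    """Families spanning >= 2 cohort years, i.e. repeated mother–father pairings.

    Full siblings share both parents, so a cross-year full-sib family means
    the same male and female re-paired in every listed year.
    """
    rows = [{"family_id": f.family_id,
             "years": ",".join(str(y) for y in f.years),
             "n_years": len(f.years),
             "sequential": f.sequential,
             "n_members": len(f.members)}
            for f in families if f.multi_year]
    return pd.DataFrame(rows, columns=["family_id", "years", "n_years",
                                       "sequential", "n_members"])


def families_to_frame(families: Sequence[FamilyAssignment],
                      years: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Long-format (family_id, larva_id[, year]) membership table."""
    rows = []
    for f in families:
        for m in f.members:
            row = {"family_id": f.family_id, "larva_id": m}
            if years is not None:
                row["year"] = int(years[m])
            rows.append(row)
    cols = ["family_id", "larva_id"] + (["year"] if years is not None else [])
    return pd.DataFrame(rows, columns=cols)


def export_graphml(families: Sequence[FamilyAssignment], path) -> None:
    """Write the full-sib network (family-labelled) as GraphML."""
    G = nx.Graph()
    for f in families:
        for m in f.members:
            G.add_node(m, family=f.family_id)
        G.add_edges_from(f.edges)
    nx.write_graphml(G, path)
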