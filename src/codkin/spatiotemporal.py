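"""Back-calculation of spawning events and putative nest locations.

Larval age is calibrated per cohort year by a linear regression of
daily-increment age on mean sagittal otolith length.  From age and capture
metadata the chain of events is inverted:

    hatch DoY   = capture DoY − age
    spawn DoY   = hatch DoY − incubation(water temperature)
    incubation  = 20.67 − 0.667 · T(°C)
    dispersal   = max(age − brood care, 0)        [days]
    nest km     = capture km − v · dispersal      [v = 700 m/day by default]

Chainage increases downstream and larvae drift downstream only, so the
putative nest lies upstream of (at smaller chainage than) the capture site.
Larvae are clustered into putative nests by single-linkage grouping on hatch
date and nest chainage within a cohort year, and the resulting partition is
compared against the genetic families via the adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "AgeModel",
    "SpawnEvent",
    "TemperatureSeries",
    "fit_age_model",
    "incubation_duration",
    "back_calculate",
    "back_calculate_table",
    "cluster_nests",
    "compare_partitions",
    "sibling_pair_sites",
]

logger = logging.getLogger(__name__)

DEFAULT_DRIFT_VELOCITY_M_PER_DAY = 700.0
DEFAULT_BROOD_CARE_DAYS = 7.0
DEFAULT_HATCH_TOLERANCE_DAYS = 3.0
DEFAULT_CHAINAGE_TOLERANCE_KM = 1.0


@dataclass
class AgeModel:
    """Per-year linear age–otolith calibration: age = intercept + slope·length."""

    year: int
    slope: float
    intercept: float
    residual_sd: float
    n: int

    def predict(self, otolith_len) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(otolith_len, dtype=float)


@dataclass
class SpawnEvent:
    """Back-calculated spawning event for one larva."""

    larva_id: str
    year: int
    age_days: float
    capture_doy: float
    hatch_doy: float
    spawn_doy: float
    incubation_days: float
    dispersal_days: float
    capture_km: float
    nest_km: float
    clamped: bool = False


class TemperatureSeries:
    """Water temperature lookup: scalar, per-year scalars, or (year, doy) table."""

    def __init__(self, source: float | Mapping[int, float] | pd.DataFrame):
        self._scalar = None
        self._by_year = None
        self._table = None
        if isinstance(source, pd.DataFrame):
            required = {"year", "doy", "temp_c"}
            if not required.issubset(source.columns):
                raise ValueError(f"temperature table needs columns {sorted(required)}")
            self._table = source
        elif isinstance(source, Mapping):
            self._by_year = {int(k): float(v) for k, v in source.items()}
        else:
            self._scalar = float(source)

    def at(self, year: int, doy: float) -> float:
        """Temperature for a year at (nearest) day-of-year."""
        if self._scalar is not None:
            return self._scalar
        if self._by_year is not None:
            return self._by_year[int(year)]
        sub = self._table[self._table["year"] == int(year)]
        if sub.empty:
            raise KeyError(f"no temperature records for year {year}")
        i = (sub["doy"] - doy).abs().idxmin()
        return float(sub.loc[i, "temp_c"])


def fit_age_model(otolith_len: Sequence[float], age_days: Sequence[float],
                  year: int) -> AgeModel:
    """Least-squares linear fit of increment age on otolith length for one year."""
    x = np.asarray(otolith_len, dtype=float)
    y = np.asarray(age_days, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration pairs")
    if np.ptp(x) == 0:
        raise ValueError("all otolith lengths equal; singular design")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sd = float(np.sqrt(np.sum(resid ** 2) / max(x.size - 2, 1)))
    return AgeModel(year=int(year), slope=float(res.slope),
                    intercept=float(res.intercept), residual_sd=sd, n=int(x.size))


def incubation_duration(temp_c: float) -> float:
    """Temperature-dependent egg incubation time in days: 20.67 − 0.667·T."""
    d = 20.67 - 0.667 * float(temp_c)
    if d <= 0:
        raise ValueError(
            f"non-positive incubation ({d:.3f} d) at {temp_c} °C; "
            "formula is valid only below ~31 °C")
    return d


def back_calculate(larva_id: str, year: int, capture_doy: float, capture_km: float,
                   age_days: float, temp_c: float,
                   brood_care_days: float = DEFAULT_BROOD_CARE_DAYS,
                   drift_velocity_m_per_day: float = DEFAULT_DRIFT_VELOCITY_M_PER_DAY,
                   reach_origin_km: float = 0.0) -> SpawnEvent:
    """Back-calculate hatch/spawn day-of-year and putative nest chainage."""
    if age_days <= 0:
        raise ValueError(f"age must be positive, got {age_days}")
    hatch = capture_doy - age_days
    incubation = incubation_duration(temp_c)
    spawn = hatch - incubation
    dispersal = age_days - brood_care_days
    clamped = False
    if dispersal < 0:
        logger.warning("larva %s: age %.1f d < brood care %.1f d; dispersal clamped to 0",
                       larva_id, age_days, brood_care_days)
        dispersal = 0.0
        clamped = True
    nest = capture_km - drift_velocity_m_per_day * dispersal / 1000.0
    if nest < reach_origin_km:
        logger.warning("larva %s: putative nest %.2f km above reach origin; floored",
                       larva_id, nest)
        nest = reach_origin_km
        clamped = True
    return SpawnEvent(larva_id=larva_id, year=int(year), age_days=float(age_days),
                      capture_doy=float(capture_doy), hatch_doy=float(hatch),
                      spawn_doy=float(spawn), incubation_days=float(incubation),
                      dispersal_days=float(dispersal), capture_km=float(capture_km),
                      nest_km=float(nest), clamped=clamped)


def back_calculate_table(metadata: pd.DataFrame, age_models: Mapping[int, AgeModel],
                         temperature: TemperatureSeries,
                         brood_care_days: float = DEFAULT_BROOD_CARE_DAYS,
                         drift_velocity_m_per_day: float = DEFAULT_DRIFT_VELOCITY_M_PER_DAY,
                         ) -> pd.DataFrame:
    """Apply the age model and back-calculation to every larva in the metadata.

    Temperature for the incubation formula is looked up at the estimated
    hatch day-of-year (single lookup, no fixed-point iteration).
    """
    rows = []
    for rec in metadata.itertuples():
        year = int(rec.year)
        model = age_models[year]
        age = float(model.predict(rec.otolith_len_mm))
        if age <= 0:
            logger.warning("larva %s: non-positive predicted age %.2f; skipped",
                           rec.larva_id, age)
            continue
        hatch_guess = rec.capture_doy - age
        ev = back_calculate(
            larva_id=rec.larva_id, year=year, capture_doy=rec.capture_doy,
            capture_km=rec.capture_site_km, age_days=age,
            temp_c=temperature.at(year, hatch_guess),
            brood_care_days=brood_care_days,
            drift_velocity_m_per_day=drift_velocity_m_per_day)
        rows.append(vars(ev))
    return pd.DataFrame(rows)


def cluster_nests(events: pd.DataFrame,
                  hatch_tolerance_days: float = DEFAULT_HATCH_TOLERANCE_DAYS,
                  chainage_tolerance_km: float = DEFAULT_CHAINAGE_TOLERANCE_KM,
                  ) -> dict[str, str]:
    """Single-linkage putative-nest grouping within each cohort year.

    Two larvae join when |Δhatch| ≤ hatch tolerance AND |Δnest chainage| ≤
    chainage tolerance.  Returns larva id → nest-group label.
    """
    if hatch_tolerance_days <= 0 or chainage_tolerance_km <= 0:
        raise ValueError("tolerances must be positive")
    labels: dict[str, str] = {}
    group_no = 0
    for year, sub in events.groupby("year"):
        ids = sub["larva_id"].to_list()
        h = sub["hatch_doy"].to_numpy()
        c = sub["nest_km"].to_numpy()
        n = len(ids)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (abs(h[i] - h[j]) <= hatch_tolerance_days
                        and abs(c[i] - c[j]) <= chainage_tolerance_km):
                    parent[find(i)] = find(j)
        roots: dict[int, str] = {}
        for i in range(n):
            r = find(i)
            if r not in roots:
                group_no += 1
                roots[r] = f"nest{group_no:03d}"
            labels[ids[i]] = roots[r]
    return labels


def compare_partitions(groups_a: Mapping[str, object],
                       groups_b: Mapping[str, object]) -> float:
    """Adjusted Rand index between two partitions over their shared larvae."""
    shared = sorted(set(groups_a) & set(groups_b))
    if not shared:
        raise ValueError("partitions cover disjoint larva sets")
    la = [groups_a[s] for s in shared]
    lb = [groups_b[s] for s in shared]
    return float(adjusted_rand_score(la, lb))


def sibling_pair_sites(edges: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per full-sib pair: whether members share a capture site or sit at adjacent sites."""
    site_of = dict(zip(metadata["larva_id"], metadata["capture_site_km"]))
    site_order = {s: i for i, s in enumerate(sorted(set(site_of.values())))}
    rows = []
    for e in edges.itertuples():
        sa, sb = site_of[e.id_a], site_of[e.id_b]
        rows.append({
            "id_a": e.id_a, "id_b": e.id_b,
            "site_a_km": sa, "site_b_km": sb,
            "same_site": sa == sb,
            "adjacent_site": abs(site_order[sa] - site_order[sb]) == 1,
        })
    return pd.DataFrame(rows, columns=["id_a", "id_b", "site_a_km", "site_b_km",
                                       "same_site", "adjacent_site"])
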