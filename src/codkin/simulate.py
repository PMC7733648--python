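"""Synthetic pedigreed larval populations with known ground truth.

Emulates an outcrossed riverine fish population sampled as drifting larvae:
adults drawn under Hardy–Weinberg equilibrium, Mendelian inheritance with
per-allele genotyping error and missing calls, a configurable mating model
(monogamy / polygyny / polyandry, with parent pairs planted to re-mate across
years), nest positions and hatch dates along a one-dimensional river reach,
downstream larval drift to fixed capture sites, an admixed "stocked" outbred
contaminant subpopulation, and maternally transmitted carbon/nitrogen isotope
signatures.  Every larva carries full pedigree and spatio-temporal truth so
downstream inference can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimulatedDataset",
    "ConfigError",
    "draw_allele_frequencies",
    "simulate_pedigree_and_genotypes",
    "simulate_isotopes",
    "simulate_age_calibration",
    "simulate_dataset",
    "write_dataset",
]


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults reflect the study system: a ~65 km upland river reach sampled by
    six drift-net sites over three annual cohorts, mean larval drift velocity
    700 m/day, paternal brood care of 4–10 days (median 7 used), and a late
    spring spawning season (day-of-year ~300–335 in the southern hemisphere).
    """

    n_loci: int = 1000
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_adult_pairs: int = 30
    n_years: int = 3
    start_year: int = 2011
    multi_year_pairs: int = 0
    #: explicit year-index sets for each planted repeat pair; None = built-in
    #: pattern (first pair spans all years, the rest alternate 2-year sets)
    multi_year_year_sets: tuple[tuple[int, ...], ...] | None = None
    #: proportions (monogamy, polygyny, polyandry) used when forming each
    #: season's matings beyond the planted repeat pairs
    mating_strategy_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)
    nests_per_year: int | tuple[int, ...] = 7
    larvae_per_nest_range: tuple[int, int] = (4, 6)
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.02
    outbred_fraction: float = 0.0
    #: allele-frequency shift of the stocked gene pool away from the river
    #: pool (toward the opposite allele; a domesticated strain near fixation)
    outbred_freq_shift: float = 0.7
    river_length_km: float = 65.0
    capture_sites: tuple[float, ...] = (8.0, 18.0, 28.0, 38.0, 48.0, 58.0)
    water_temp_c: float | Mapping[int, float] = 17.0
    drift_velocity_m_per_day: float = 700.0
    drift_days_range: tuple[float, float] = (0.0, 6.0)
    brood_care_days: float = 7.0
    hatch_doy_range: tuple[int, int] = (300, 335)
    #: within-family isotope noise floor ≈ assay precision (‰)
    isotope_family_sd: float = 0.15
    isotope_between_sd: float = 1.0
    isotope_mean: tuple[float, float] = (-28.0, 10.0)  # (δ13C, δ15N) ‰
    otolith_len_at_hatch_mm: float = 0.15
    otolith_growth_mm_per_day: float = 0.045
    otolith_noise_sd_mm: float = 0.005
    age_reading_noise_sd_days: float = 0.5
    n_aged_per_year: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        if self.drift_velocity_m_per_day < 0:
            raise ConfigError("drift velocity must be >= 0")
        mix = self.mating_strategy_mix
        if len(mix) != 3 or any(p < 0 or p > 1 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigError("mating_strategy_mix must be 3 proportions summing to 1")
        if not (0.0 <= self.genotyping_error_rate <= 1.0):
            raise ConfigError("genotyping_error_rate must be a probability")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ConfigError("missing_rate must be a probability")
        if not (0.0 <= self.outbred_fraction < 1.0):
            raise ConfigError("outbred_fraction must be in [0, 1)")
        if self.multi_year_pairs > self.n_adult_pairs:
            raise ConfigError(
                f"multi_year_pairs ({self.multi_year_pairs}) exceeds "
                f"n_adult_pairs ({self.n_adult_pairs})"
            )
        if self.multi_year_pairs and self.n_years < 2:
            raise ConfigError("multi-year repeat pairs need n_years >= 2")
        a, b = self.larvae_per_nest_range
        if not (1 <= a <= b):
            raise ConfigError("larvae_per_nest_range must satisfy 1 <= lo <= hi")
        if not self.capture_sites or list(self.capture_sites) != sorted(self.capture_sites):
            raise ConfigError("capture_sites must be a non-empty increasing chainage list")
        if max(self.capture_sites) > self.river_length_km:
            raise ConfigError("capture sites must lie within the river reach")
        if self.isotope_family_sd < 0 or self.isotope_between_sd < 0:
            raise ConfigError("isotope standard deviations must be >= 0")

    # ------------------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return [self.start_year + i for i in range(self.n_years)]

    def nests_for_year(self, year_index: int) -> int:
        if isinstance(self.nests_per_year, (tuple, list)):
            return int(self.nests_per_year[year_index])
        return int(self.nests_per_year)

    def temp_for_year(self, year: int) -> float:
        if isinstance(self.water_temp_c, Mapping):
            return float(self.water_temp_c[year])
        return float(self.water_temp_c)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if isinstance(d["water_temp_c"], Mapping):
            d["water_temp_c"] = {int(k): float(v) for k, v in d["water_temp_c"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth: per-larva pedigree/space-time facts and per-pair-year matings."""

    larvae: pd.DataFrame      # larva_id, mother, father, nest_id, year, true_hatch_doy,
                              # true_spawn_doy, true_nest_km, true_age_days, drift_days, outbred
    pair_years: pd.DataFrame  # mother, father, year, nest_id
    #: error-free adult genotypes (never observed by the inference pipeline)
    adult_genotypes: GenotypeMatrix | None = None

    def parent_pair_of(self, larva_id: str) -> tuple[str, str] | None:
        row = self.larvae.set_index("larva_id").loc[larva_id]
        if row["outbred"]:
            return None
        return (row["mother"], row["father"])

    @property
    def multi_year_parent_pairs(self) -> pd.DataFrame:
        """Parent pairs observed mating in >= 2 distinct years."""
        g = self.pair_years.groupby(["mother", "father"])["year"].agg(
            years=lambda s: tuple(sorted(set(s))))
        g = g[g["years"].map(len) >= 2].reset_index()
        return g


@dataclass
class SimulatedDataset:
    """Bundle of everything the simulator produces for one configuration."""

    config: SimConfig
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    truth: TruthTable
    calibration: pd.DataFrame
    allele_freqs: np.ndarray


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def draw_allele_frequencies(config: SimConfig) -> np.ndarray:
    """Per-locus allele frequencies of the scored allele.

    Minor-allele frequencies are uniform over ``maf_range``; each locus is
    mirrored to 1 − f with probability 1/2 so the scored allele is not always
    the minor one.  Deterministic under a fixed config seed.
    """
    rng = _rng(config, 0)
    lo, hi = config.maf_range
    f = rng.uniform(lo, hi, size=config.n_loci)
    mirror = rng.random(config.n_loci) < 0.5
    return np.where(mirror, 1.0 - f, f)


def _default_year_sets(config: SimConfig) -> list[tuple[int, ...]]:
    """Year-index sets for planted repeat pairs, mimicking the observed mix:
    the first pair re-mates every year; later pairs re-mate for two years,
    one consecutive pair then non-consecutive pairs where the span allows."""
    sets: list[tuple[int, ...]] = []
    for i in range(config.multi_year_pairs):
        if i == 0:
            sets.append(tuple(range(config.n_years)))
        elif i == 1 or config.n_years < 3:
            sets.append((0, 1))
        else:
            sets.append((0, config.n_years - 1))
    return sets


def _mendelian_offspring(gm: np.ndarray, gf: np.ndarray, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """n offspring genotype rows from parental genotype vectors (gamete dropping)."""
    pm = np.broadcast_to(gm / 2.0, (n, gm.size))
    pf = np.broadcast_to(gf / 2.0, (n, gf.size))
    return (rng.random(pm.shape) < pm).astype(float) + (rng.random(pf.shape) < pf)


def _apply_genotyping_noise(calls: np.ndarray, error_rate: float, missing_rate: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Symmetric per-allele flips then missingness."""
    out = calls.astype(float)
    if error_rate > 0:
        down = rng.binomial(out.astype(int), error_rate)
        up = rng.binomial((2 - out).astype(int), error_rate)
        out = out - down + up
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = np.nan
    return out


def simulate_pedigree_and_genotypes(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthTable]:
    """Simulate the pedigree, larval genotypes and capture metadata.

    Returns ``(genotypes, metadata, truth)``.  Metadata columns:
    ``larva_id, year, capture_doy, capture_site_km, otolith_len_mm``.

    Larval drift: a drawn drift-day value places a provisional downstream
    position ``nest + v·d`` which is snapped to the nearest capture site at or
    below that position on the downstream side; the realized drift duration is
    the travel time ``(site − nest)/v`` to that site, so capture day-of-year is
    exactly ``hatch + brood_care + travel time`` and back-calculation is
    invertible in the noise-free limit.
    """
    freqs = draw_allele_frequencies(config)
    rng = _rng(config, 1)

    males = [f"SIRE{i:03d}" for i in range(config.n_adult_pairs)]
    females = [f"DAM{i:03d}" for i in range(config.n_adult_pairs)]
    g_m = rng.binomial(2, freqs, size=(config.n_adult_pairs, config.n_loci)).astype(float)
    g_f = rng.binomial(2, freqs, size=(config.n_adult_pairs, config.n_loci)).astype(float)

    year_sets = (list(config.multi_year_year_sets)
                 if config.multi_year_year_sets is not None
                 else _default_year_sets(config))
    if len(year_sets) != config.multi_year_pairs:
        raise ConfigError("multi_year_year_sets length must equal multi_year_pairs")
    for ys in year_sets:
        if len(set(ys)) < 2 or min(ys) < 0 or max(ys) >= config.n_years:
            raise ConfigError(f"invalid multi-year year set {ys}")

    # matings per year: planted repeat pairs first, then fresh (or strategy-
    # dependent) pairings from the remaining adult pool
    matings: list[tuple[int, int, int]] = []  # (year_index, male_idx, female_idx)
    fresh_male = fresh_female = config.multi_year_pairs
    for yi in range(config.n_years):
        planted = [i for i, ys in enumerate(year_sets) if yi in ys]
        year_matings = [(yi, i, i) for i in planted]
        n_extra = config.nests_for_year(yi) - len(planted)
        if n_extra < 0:
            raise ConfigError(
                f"nests_per_year[{yi}] smaller than planted repeat pairs active that year")
        for _ in range(n_extra):
            strategy = rng.choice(3, p=np.asarray(config.mating_strategy_mix))
            used_m = [m for _, m, _ in year_matings]
            used_f = [f for _, _, f in year_matings]
            if strategy == 1 and used_m:            # polygyny: reuse a male
                m = used_m[rng.integers(len(used_m))]
                f = fresh_female; fresh_female += 1
            elif strategy == 2 and used_f:          # polyandry: reuse a female
                f = used_f[rng.integers(len(used_f))]
                m = fresh_male; fresh_male += 1
            else:                                   # monogamy: fresh pair
                m = fresh_male; fresh_male += 1
                f = fresh_female; fresh_female += 1
            if m >= config.n_adult_pairs or f >= config.n_adult_pairs:
                raise ConfigError("adult pool exhausted; raise n_adult_pairs")
            year_matings.append((yi, m, f))
        matings.extend(year_matings)

    sites = np.asarray(config.capture_sites, dtype=float)
    v_km = config.drift_velocity_m_per_day / 1000.0
    lo_d, hi_d = config.drift_days_range

    larva_rows: list[dict] = []
    geno_rows: list[np.ndarray] = []
    pair_rows: list[dict] = []
    counter = 0
    for nest_no, (yi, mi, fi) in enumerate(matings):
        year = config.years[yi]
        nest_id = f"N{nest_no:03d}"
        nest_km = rng.uniform(0.0, sites[-1])
        hatch = float(rng.integers(config.hatch_doy_range[0], config.hatch_doy_range[1] + 1))
        incubation = 20.67 - 0.667 * config.temp_for_year(year)
        n_larvae = int(rng.integers(config.larvae_per_nest_range[0],
                                    config.larvae_per_nest_range[1] + 1))
        pair_rows.append({"mother": females[fi], "father": males[mi],
                          "year": year, "nest_id": nest_id})
        kids = _mendelian_offspring(g_m[mi], g_f[fi], n_larvae, rng)
        d_draw = rng.uniform(lo_d, hi_d, size=n_larvae)
        for j in range(n_larvae):
            pos = nest_km + v_km * d_draw[j]
            downstream = sites[sites >= pos - 1e-9]
            site = float(downstream[0]) if downstream.size else float(sites[-1])
            travel = max(site - nest_km, 0.0) / v_km if v_km > 0 else 0.0
            age = config.brood_care_days + travel
            larva_rows.append({
                "larva_id": f"L{counter:04d}",
                "mother": females[fi], "father": males[mi],
                "nest_id": nest_id, "year": year,
                "true_hatch_doy": hatch,
                "true_spawn_doy": hatch - incubation,
                "true_nest_km": nest_km,
                "true_age_days": age,
                "drift_days": travel,
                "capture_doy": hatch + age,
                "capture_site_km": site,
                "outbred": False,
            })
            geno_rows.append(kids[j])
            counter += 1

    # stocked outbred contaminants: F1 crosses between the river pool and a
    # frequency-shifted hatchery pool -> excess heterozygosity (negative F)
    n_family = counter
    n_out = int(round(config.outbred_fraction / (1.0 - config.outbred_fraction) * n_family))
    if n_out > 0:
        shift = np.where(freqs < 0.5, config.outbred_freq_shift, -config.outbred_freq_shift)
        f_stocked = np.clip(freqs + shift, 0.02, 0.98)
        for j in range(n_out):
            g = ((rng.random(config.n_loci) < freqs).astype(float)
                 + (rng.random(config.n_loci) < f_stocked))
            year = config.years[int(rng.integers(config.n_years))]
            hatch = float(rng.integers(config.hatch_doy_range[0],
                                       config.hatch_doy_range[1] + 1))
            age = config.brood_care_days + rng.uniform(lo_d, hi_d)
            site = float(sites[rng.integers(sites.size)])
            larva_rows.append({
                "larva_id": f"L{counter:04d}",
                "mother": None, "father": None, "nest_id": None, "year": year,
                "true_hatch_doy": hatch, "true_spawn_doy": np.nan,
                "true_nest_km": np.nan, "true_age_days": age,
                "drift_days": np.nan, "capture_doy": hatch + age,
                "capture_site_km": site, "outbred": True,
            })
            geno_rows.append(g)
            counter += 1

    truth_df = pd.DataFrame(larva_rows)
    calls = _apply_genotyping_noise(np.vstack(geno_rows), config.genotyping_error_rate,
                                    config.missing_rate, rng)
    genotypes = GenotypeMatrix(
        ids=truth_df["larva_id"].to_numpy(dtype=object),
        loci=np.asarray([f"SNP{i:05d}" for i in range(config.n_loci)], dtype=object),
        calls=calls,
    )

    oto = (config.otolith_len_at_hatch_mm
           + config.otolith_growth_mm_per_day * truth_df["true_age_days"].to_numpy()
           + rng.normal(0.0, config.otolith_noise_sd_mm, size=len(truth_df)))
    metadata = pd.DataFrame({
        "larva_id": truth_df["larva_id"],
        "year": truth_df["year"],
        "capture_doy": truth_df["capture_doy"],
        "capture_site_km": truth_df["capture_site_km"],
        "otolith_len_mm": oto,
    })
    adults = GenotypeMatrix(
        ids=np.asarray(males + females, dtype=object),
        loci=genotypes.loci.copy(),
        calls=np.vstack([g_m, g_f]),
    )
    truth = TruthTable(
        larvae=truth_df.drop(columns=["capture_doy", "capture_site_km"]),
        pair_years=pd.DataFrame(pair_rows),
        adult_genotypes=adults,
    )
    return genotypes, metadata, truth


def simulate_isotopes(truth: TruthTable, config: SimConfig) -> pd.DataFrame:
    """Maternally transmitted (δ13C, δ15N) signatures.

    Each mother draws a signature around the population mean with the
    between-family sd; her offspring inherit it plus within-family noise.
    Outbred larvae each carry an independent (unknown-mother) signature.
    """
    rng = _rng(config, 2)
    mean = np.asarray(config.isotope_mean, dtype=float)
    mothers = sorted({m for m in truth.larvae["mother"] if m is not None})
    sig = {m: mean + rng.normal(0.0, config.isotope_between_sd, size=2) for m in mothers}
    rows = []
    for _, r in truth.larvae.iterrows():
        base = (sig[r["mother"]] if r["mother"] is not None
                else mean + rng.normal(0.0, config.isotope_between_sd, size=2))
        val = base + rng.normal(0.0, config.isotope_family_sd, size=2)
        rows.append({"larva_id": r["larva_id"], "d13C": val[0], "d15N": val[1]})
    return pd.DataFrame(rows)


def simulate_age_calibration(truth: TruthTable, metadata: pd.DataFrame,
                             config: SimConfig) -> pd.DataFrame:
    """Aged subset emulating commercial daily-increment reads on ~30 larvae/year."""
    rng = _rng(config, 3)
    merged = truth.larvae.merge(metadata[["larva_id", "otolith_len_mm"]], on="larva_id")
    rows = []
    for year, grp in merged.groupby("year"):
        take = min(config.n_aged_per_year, len(grp))
        idx = rng.choice(len(grp), size=take, replace=False)
        sub = grp.iloc[np.sort(idx)]
        ages = sub["true_age_days"].to_numpy() + rng.normal(
            0.0, config.age_reading_noise_sd_days, size=take)
        for (_, r), a in zip(sub.iterrows(), ages):
            rows.append({"larva_id": r["larva_id"], "year": year,
                         "otolith_len_mm": r["otolith_len_mm"],
                         "increment_age_days": max(a, 0.5)})
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: genotypes + metadata (with isotopes) + truth + calibration."""
    genotypes, metadata, truth = simulate_pedigree_and_genotypes(config)
    iso = simulate_isotopes(truth, config)
    metadata = metadata.merge(iso, on="larva_id")
    calibration = simulate_age_calibration(truth, metadata, config)
    return SimulatedDataset(config=config, genotypes=genotypes, metadata=metadata,
                            truth=truth, calibration=calibration,
                            allele_freqs=draw_allele_frequencies(config))


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write genotype/metadata/truth/calibration CSVs plus the config YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.csv",
        "metadata": out / "metadata.csv",
        "truth_larvae": out / "truth_larvae.csv",
        "truth_pair_years": out / "truth_pair_years.csv",
        "calibration": out / "calibration.csv",
        "config": out / "config.yaml",
    }
    ds.genotypes.to_csv(paths["genotypes"])
    ds.metadata.to_csv(paths["metadata"], index=False)
    ds.truth.larvae.to_csv(paths["truth_larvae"], index=False)
    ds.truth.pair_years.to_csv(paths["truth_pair_years"], index=False)
    ds.calibration.to_csv(paths["calibration"], index=False)
    ds.config.to_yaml(paths["config"])
    return paths
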