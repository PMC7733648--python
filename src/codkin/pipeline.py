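"""End-to-end orchestration: screen → relatedness → cutoff calibration →
families → multi-year detection → spatio-temporal cross-check → isotope
validation → chance-pairing report.

The in-memory core is :func:`analyse`; :func:`run_pipeline` wraps it with
file IO, per-stage error reporting and a MANIFEST so partial output is never
mistaken for a complete run.  All randomness derives from one seed, forked
into an independent stream per stage, so any stage is individually
reproducible and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from . import relatedness as rel
from . import sibship
from . import spatiotemporal as st
from . import isotopes as iso
from . import pairing

__all__ = ["RunConfig", "PipelineResult", "PipelineError", "analyse", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (paths + thresholds + seed)."""

    genotype_csv: str
    metadata_csv: str
    outdir: str
    calibration_csv: str | None = None
    #: scalar °C, mapping year → °C, or path to a (year, doy, temp_c) CSV
    temperature: float | dict | str = 17.0
    estimator: str = "dyadml"
    cutoff_mode: str = "fixed"
    cutoff_value: float = sibship.DEFAULT_CUTOFF            # r > 0.4
    inbreeding_threshold: float = rel.OUTBRED_F_THRESHOLD   # F < −0.4
    genotyping_error_rate: float = rel.DEFAULT_ERROR_RATE
    min_joint_loci: int = rel.DEFAULT_MIN_JOINT_LOCI
    n_sim: int = 1000
    brood_care_days: float = st.DEFAULT_BROOD_CARE_DAYS     # 7 d
    drift_velocity_m_per_day: float = st.DEFAULT_DRIFT_VELOCITY_M_PER_DAY  # 700
    hatch_tolerance_days: float = st.DEFAULT_HATCH_TOLERANCE_DAYS
    chainage_tolerance_km: float = st.DEFAULT_CHAINAGE_TOLERANCE_KM
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    summary: dict
    inbreeding: pd.DataFrame
    excluded_outbreds: pd.DataFrame
    dyads: pd.DataFrame
    cutoff: sibship.CutoffReport
    edges: pd.DataFrame
    families: list
    singletons: list
    multi_year: pd.DataFrame
    spawn_events: pd.DataFrame
    nest_groups: dict
    sibling_sites: pd.DataFrame
    isotope_test: iso.IsotopeTestResult | None


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (kept below 2**31)."""
    s = np.random.SeedSequence(seed, spawn_key=(stage,)).generate_state(1)[0]
    return int(s & 0x7FFFFFFF)


def analyse(genotypes: GenotypeMatrix, metadata: pd.DataFrame,
            calibration: pd.DataFrame | None,
            temperature: st.TemperatureSeries,
            config: RunConfig) -> PipelineResult:
    """Run the full analysis in memory and return all stage outputs."""

    def stage(name):
        logger.info("stage: %s", name)

    # ---- outbred screen -------------------------------------------------
    stage("screen")
    freqs_all = rel.estimate_allele_frequencies(genotypes)
    inbreeding = rel.inbreeding_coefficients(genotypes, freqs=freqs_all,
                                             min_loci=config.min_joint_loci)
    retained_ids, excluded = rel.screen_outbreds(inbreeding,
                                                 threshold=config.inbreeding_threshold)
    if not retained_ids:
        raise ValueError("all larvae excluded by the inbreeding screen")
    g = genotypes.subset(retained_ids)
    meta = metadata[metadata["larva_id"].isin(retained_ids)].reset_index(drop=True)

    # ---- relatedness ----------------------------------------------------
    stage("relatedness")
    freqs = rel.estimate_allele_frequencies(g)
    dyads = rel.pairwise_relatedness(
        g, estimator=config.estimator, freqs=freqs,
        error_rate=config.genotyping_error_rate,
        min_joint_loci=config.min_joint_loci)

    # ---- cutoff calibration --------------------------------------------
    stage("calibrate")
    dists = sibship.simulate_category_r(
        freqs.values, estimator=config.estimator, n_sim=config.n_sim,
        seed=_stage_seed(config.seed, 1), error_rate=config.genotyping_error_rate)
    cutoff = sibship.choose_cutoff(dists, mode=config.cutoff_mode,
                                   fixed_value=config.cutoff_value)

    # ---- families and multi-year pairs ----------------------------------
    stage("families")
    edges = sibship.classify_dyads(dyads, cutoff=cutoff.cutoff)
    years = dict(zip(meta["larva_id"], meta["year"].astype(int)))
    families, singletons = sibship.build_families(edges, years,
                                                  all_larvae=retained_ids)
    multi_year = sibship.detect_multi_year_pairs(families)

    # ---- spatio-temporal cross-check ------------------------------------
    stage("spatiotemporal")
    spawn_events = pd.DataFrame()
    nest_groups: dict = {}
    ari = None
    sibling_sites = pd.DataFrame()
    if calibration is not None and len(calibration):
        age_models = {
            int(year): st.fit_age_model(sub["otolith_len_mm"], sub["increment_age_days"],
                                        year=int(year))
            for year, sub in calibration.groupby("year")}
        spawn_events = st.back_calculate_table(
            meta, age_models, temperature,
            brood_care_days=config.brood_care_days,
            drift_velocity_m_per_day=config.drift_velocity_m_per_day)
        nest_groups = st.cluster_nests(
            spawn_events, hatch_tolerance_days=config.hatch_tolerance_days,
            chainage_tolerance_km=config.chainage_tolerance_km)
        family_labels = {m: f.family_id for f in families for m in f.members}
        family_labels.update({s: f"single_{s}" for s in singletons})
        ari = st.compare_partitions(nest_groups, family_labels)
        sibling_sites = st.sibling_pair_sites(edges, meta)

    # ---- isotope validation ---------------------------------------------
    stage("isotopes")
    isotope_test = None
    if {"d13C", "d15N"}.issubset(meta.columns) and families:
        table = sibship.families_to_frame(families, years=years).merge(
            meta[["larva_id", "d13C", "d15N"]], on="larva_id")
        sizes = table["family_id"].value_counts()
        if (sizes >= 2).sum() >= 2:
            isotope_test = iso.permutation_test(
                table, n_perm=config.n_perm,
                seed=_stage_seed(config.seed, 2), stratify_by_year=True)

    # ---- chance-pairing probabilities -----------------------------------
    stage("pairing")
    n_pool = len(families) + len(singletons)
    pairing_rows = []
    if n_pool >= 2:
        for f in families:
            if f.multi_year:
                pairing_rows.append({
                    "family_id": f.family_id,
                    "years": ",".join(map(str, f.years)),
                    "y": len(f.years),
                    "p_chance": pairing.chance_pairing_probability(n_pool, len(f.years)),
                })
    joint_p = None
    if pairing_rows:
        joint_p = pairing.joint_repeat_probability(
            [pairing.PairingScenario(n=n_pool, y=row["y"], alpha=config.alpha)
             for row in pairing_rows])
    if not multi_year.empty:
        multi_year = multi_year.merge(
            pd.DataFrame(pairing_rows)[["family_id", "p_chance"]],
            on="family_id", how="left")

    summary = {
        "seed": config.seed,
        "estimator": config.estimator,
        "n_larvae": genotypes.n_samples,
        "n_retained": len(retained_ids),
        "n_excluded_outbreds": len(excluded),
        "n_loci": genotypes.n_loci,
        "n_loci_retained": freqs.n_retained,
        "n_dyads": len(dyads),
        "cutoff": cutoff.cutoff,
        "cutoff_mode": cutoff.mode,
        "cutoff_fs_false_negative_rate": cutoff.fs_false_negative_rate,
        "cutoff_hs_false_positive_rate": cutoff.hs_false_positive_rate,
        "n_fullsib_dyads": len(edges),
        "n_families": len(families),
        "n_singletons": len(singletons),
        "pairing_pool_n": n_pool,
        "multi_year_pairs": pairing_rows,
        "joint_chance_probability": joint_p,
        "ari_families_vs_nests": ari,
        "isotope": isotope_test.to_dict() if isotope_test is not None else None,
    }
    return PipelineResult(
        summary=summary, inbreeding=inbreeding, excluded_outbreds=excluded,
        dyads=dyads, cutoff=cutoff, edges=edges, families=families,
        singletons=singletons, multi_year=multi_year, spawn_events=spawn_events,
        nest_groups=nest_groups, sibling_sites=sibling_sites,
        isotope_test=isotope_test)


def _load_temperature(source: float | dict | str) -> st.TemperatureSeries:
    if isinstance(source, str):
        return st.TemperatureSeries(pd.read_csv(source))
    return st.TemperatureSeries(source)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs, run :func:`analyse`, write all stage outputs + MANIFEST."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "stages": [], "error": None}

    def finish_manifest():
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    current_stage = "load"
    try:
        genotypes = GenotypeMatrix.from_csv(config.genotype_csv)
        metadata = pd.read_csv(config.metadata_csv)
        calibration = (pd.read_csv(config.calibration_csv)
                       if config.calibration_csv else None)
        temperature = _load_temperature(config.temperature)
        manifest["stages"].append("load")

        current_stage = "analyse"
        result = analyse(genotypes, metadata, calibration, temperature, config)
        manifest["stages"].append("analyse")

        current_stage = "write"
        result.inbreeding.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
        result.excluded_outbreds.to_csv(out / "excluded_outbreds.tsv", sep="\t",
                                        index=False)
        result.dyads.to_csv(out / "dyads.tsv", sep="\t", index=False)
        result.edges.to_csv(out / "fullsib_edges.tsv", sep="\t", index=False)
        years = dict(zip(metadata["larva_id"], metadata["year"].astype(int)))
        sibship.families_to_frame(result.families, years=years).to_csv(
            out / "families.tsv", sep="\t", index=False)
        result.multi_year.to_csv(out / "multi_year_pairs.tsv", sep="\t", index=False)
        sibship.export_graphml(result.families, out / "fullsib_network.graphml")
        if len(result.spawn_events):
            result.spawn_events.to_csv(out / "spawn_events.tsv", sep="\t", index=False)
            pd.DataFrame(sorted(result.nest_groups.items()),
                         columns=["larva_id", "nest_group"]).to_csv(
                out / "nest_groups.tsv", sep="\t", index=False)
            result.sibling_sites.to_csv(out / "sibling_pair_sites.tsv", sep="\t",
                                        index=False)
        if result.isotope_test is not None:
            (out / "isotope_test.json").write_text(
                json.dumps(result.isotope_test.to_dict(), indent=2, sort_keys=True))
        (out / "summary.json").write_text(
            json.dumps(result.summary, indent=2, sort_keys=True, default=float))
        manifest["stages"].append("write")
        manifest["complete"] = True
        finish_manifest()
        return result
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["error"] = f"{current_stage}: {exc}"
        finish_manifest()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(current_stage, exc) from exc
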