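"""End-to-end orchestration of the ecoregion-stratified SDM study.

``run_pipeline`` composes the stages in study order — synthetic landscape
(or user rasters), occurrence preparation, embedded covariate selection,
four-family replicate modeling per variable arm, AUC/TSS evaluation,
permutation importance, and the ecoregion x threshold sensitivity analysis —
and writes every table as CSV plus a JSON manifest (inputs, seeds, row
counts, content hashes).  Each stage is also callable on its own (the CLI
exposes them file-to-file).

Reproducibility contract: every stochastic stage receives a seed derived
from the master seed by a scheme keyed on (stage name, species id), so
adding a species never perturbs another species' results, and rerunning
with an identical config is byte-identical.  A species failing any stage is
logged and skipped; failures never cascade.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, covsel, importance, metrics, models, prep, synthetic
from .landscape import (EcoregionMap, Landscape, load_ecoregions,
                        load_landscape, save_ecoregions, save_landscape)

log = logging.getLogger("ecosdm")

ARMS = ("climate_only", "soil_only", "climate_soil")


def derive_seed(master: int, stage: str, species: str = "") -> int:
    """Stable per-(stage, species) seed below 2**31."""
    tag = zlib.crc32(f"{stage}:{species}".encode())
    return int((master * 1_000_003 + tag) % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Study design knobs with the synthetic study's default conditions."""

    mode: str = "synthetic"                    # synthetic | user
    outdir: str = "ecosdm_out"
    seed: int = 0
    # landscape (synthetic mode)
    grid: tuple[int, int] = (64, 64)
    n_climate: int = 9
    n_soil: int = 8
    autocorr_range: float = 4.0
    cross_block_corr: float = 0.3              # climate-soil block correlation
    n_regions: int = 4
    area_fractions: tuple[float, ...] | None = None
    region_smoothing: float = 12.0
    region_env_strength: float = 2.0           # per-region shift of driver layers (SD units)
    # user mode raster paths
    landscape_dir: str | None = None
    ecoregion_path: str | None = None
    occurrences_csv: str | None = None
    # virtual flora (synthetic mode)
    n_specialists: int = 2
    n_generalists: int = 2
    driver_variables: tuple[str, ...] = ("bio1", "bio12")
    specialist_breadth: float = 0.4
    generalist_breadth: float = 1.2
    n_presence: int = 150
    flora_region_offset: int = 0       # rotates species' home ecoregions
    sampling_bias: float = 0.0                 # corner-bias strength; 0 = none
    # prep
    thresholds: tuple[float, ...] = prep.DEFAULT_THRESHOLDS
    min_records: int = prep.MIN_RECORDS_DEFAULT
    env_filter: bool = False
    n_bins: int = 8
    n_background: int = 10_000
    # covariate selection
    k_climate: int = 5
    k_soil: int = 5
    r_cut: float = covsel.R_CUT_DEFAULT
    vif_threshold: float | None = None         # whole-domain VIF pre-screen when set
    # modeling
    arms: tuple[str, ...] = ARMS
    families: tuple[str, ...] = models.FAMILIES
    n_replicates: int = 10
    test_fraction: float = 0.2
    hyperparams: dict = field(default_factory=dict)
    n_permutations: int = 5

    def validate(self) -> None:
        problems = []
        if self.mode not in ("synthetic", "user"):
            problems.append(f"mode must be synthetic|user, got {self.mode!r}")
        if not self.thresholds or not all(0 < t <= 1 for t in self.thresholds):
            problems.append("thresholds must be non-empty and lie in (0, 1]")
        if not self.arms or not set(self.arms) <= set(ARMS):
            problems.append(f"arms must be a non-empty subset of {ARMS}")
        if not self.families or not set(self.families) <= set(models.FAMILIES):
            problems.append(f"families must be a non-empty subset of {models.FAMILIES}")
        if not 0 < self.test_fraction < 1:
            problems.append("test_fraction must be in (0, 1)")
        if self.mode == "user" and not (self.landscape_dir and self.ecoregion_path
                                        and self.occurrences_csv):
            problems.append("user mode requires landscape_dir, ecoregion_path, occurrences_csv")
        if problems:
            raise ValueError("invalid config:\n- " + "\n- ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for f in ("grid", "thresholds", "arms", "families", "driver_variables"):
            v = getattr(cfg, f)
            if isinstance(v, list):
                setattr(cfg, f, tuple(v))
        if isinstance(cfg.area_fractions, list):
            cfg.area_fractions = tuple(cfg.area_fractions)
        return cfg


def _block_cross_corr(n_climate: int, n_soil: int, rho: float) -> np.ndarray:
    """Exchangeable climate-soil cross-block correlation: keeps soil layers
    informative about climate-driven niches without a degenerate target."""
    n = n_climate + n_soil
    C = np.eye(n)
    C[:n_climate, n_climate:] = rho
    C[n_climate:, :n_climate] = rho
    ev = np.linalg.eigvalsh(C)
    if ev[0] < 1e-8:  # guard PSD for large rho
        C = (C + (1e-8 - ev[0]) * np.eye(n)) / (1.0 + 1e-8 - ev[0])
    return C


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> tuple[Landscape, EcoregionMap, pd.DataFrame]:
    """Synthetic landscape, ecoregion mosaic and virtual-species occurrences."""
    landscape = synthetic.generate_env_layers(
        cfg.n_climate, cfg.n_soil, cfg.grid, cfg.autocorr_range,
        _block_cross_corr(cfg.n_climate, cfg.n_soil, cfg.cross_block_corr),
        seed=derive_seed(cfg.seed, "landscape"))
    eco = synthetic.generate_ecoregions(
        landscape, cfg.n_regions, cfg.region_smoothing, cfg.area_fractions,
        seed=derive_seed(cfg.seed, "ecoregions"))
    if cfg.region_env_strength > 0:
        synthetic.imprint_ecoregions(landscape, eco, cfg.driver_variables,
                                     cfg.region_env_strength)
    flora = synthetic.make_virtual_flora(
        landscape, eco, cfg.n_specialists, cfg.n_generalists,
        cfg.driver_variables, cfg.specialist_breadth, cfg.generalist_breadth,
        region_offset=cfg.flora_region_offset,
        seed=derive_seed(cfg.seed, "flora"))
    bias = (synthetic.corner_bias_surface(landscape.shape, strength=cfg.sampling_bias)
            if cfg.sampling_bias > 0 else None)
    occ_frames = []
    for sp in flora:
        suit = synthetic.suitability_surface(sp, landscape)
        occ_frames.append(synthetic.sample_occurrences(
            suit, landscape, cfg.n_presence, sp.species_id, bias_surface=bias,
            seed=derive_seed(cfg.seed, "occurrences", sp.species_id)))
    return landscape, eco, pd.concat(occ_frames, ignore_index=True)


def load_inputs(cfg: PipelineConfig) -> tuple[Landscape, EcoregionMap, pd.DataFrame]:
    landscape = load_landscape(cfg.landscape_dir)
    eco = load_ecoregions(cfg.ecoregion_path)
    occ = pd.read_csv(cfg.occurrences_csv)
    return landscape, eco, occ


def stage_prep(cfg: PipelineConfig, landscape: Landscape, eco: EcoregionMap,
               occ_raw: pd.DataFrame) -> dict:
    """Cleaning, geographic (and optional environmental) filtering, ecoregion
    assignment, richness summary and per-species background allocation."""
    occ_clean, dropped = prep.clean_coordinates(occ_raw, landscape)
    occ_geo = prep.geographic_filter(occ_clean, landscape)
    occ_geo = prep.min_records_gate(occ_geo, cfg.min_records)
    if occ_geo.empty:
        raise ValueError("no species survive cleaning and the minimum-record gate")
    assignments = prep.assign_to_ecoregions(occ_geo, landscape, eco, cfg.thresholds)
    richness = prep.richness_table(assignments, eco, cfg.thresholds)
    if cfg.env_filter:
        occ_geo = prep.environmental_filter(occ_geo, landscape, n_bins=cfg.n_bins,
                                            seed=derive_seed(cfg.seed, "envfilter"))
    backgrounds, skipped = {}, []
    for sp, sp_occ in occ_geo.groupby("species", sort=True):
        try:
            backgrounds[sp] = prep.kde_background(
                sp_occ, landscape, cfg.n_background,
                seed=derive_seed(cfg.seed, "background", sp))
        except Exception as exc:  # noqa: BLE001
            log.warning("species %s skipped at background stage: %s", sp, exc)
            skipped.append({"species": sp, "stage": "background", "reason": str(exc)})
    return {"occurrences": occ_geo, "dropped": dropped, "assignments": assignments,
            "richness": richness, "backgrounds": backgrounds, "skipped": skipped}


def stage_select(cfg: PipelineConfig, landscape: Landscape, occ: pd.DataFrame,
                 backgrounds: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, list[dict]]:
    """Embedded covariate selection per species; returns the rank/choice table."""
    variables = None
    if cfg.vif_threshold is not None:
        ok = ~landscape.nodata_mask
        domain = pd.DataFrame({v: landscape.layers[v][ok]
                               for v in landscape.variable_names()})
        variables = covsel.vif_prescreen(domain, cfg.vif_threshold)
    rows, skipped = [], []
    for sp, sp_occ in occ.groupby("species", sort=True):
        if sp not in backgrounds:
            continue
        try:
            design = covsel.build_design(sp_occ, backgrounds[sp], landscape,
                                         variables=variables, species_id=sp)
            selected = covsel.covsel_embed(
                design, cfg.k_climate, cfg.k_soil, cfg.r_cut,
                seed=derive_seed(cfg.seed, "covsel", sp),
                rrf_trees=cfg.hyperparams.get("rf_trees", 500))
            tab = selected.table.copy()
            tab.insert(0, "species", sp)
            rows.append(tab)
        except Exception as exc:  # noqa: BLE001
            log.warning("species %s skipped at selection stage: %s", sp, exc)
            skipped.append({"species": sp, "stage": "select", "reason": str(exc)})
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return table, skipped


def arm_variables(selection: pd.DataFrame, species: str) -> dict[str, list[str]]:
    sub = selection[(selection["species"] == species) & selection["chosen"]]
    climate = sub[sub["category"] == "climate"]["variable"].tolist()
    soil = sub[sub["category"] == "soil"]["variable"].tolist()
    return {"climate_only": climate, "soil_only": soil, "climate_soil": climate + soil}


def stage_model(cfg: PipelineConfig, landscape: Landscape, occ: pd.DataFrame,
                backgrounds: dict[str, pd.DataFrame], selection: pd.DataFrame
                ) -> tuple[pd.DataFrame, pd.DataFrame, list[dict], int]:
    """Replicate fits of every family per arm, held-out AUC/TSS, and
    permutation importance on the climate + soil arm."""
    metric_rows, importance_rows, skipped = [], [], []
    n_fits = 0
    for sp, sp_occ in occ.groupby("species", sort=True):
        if sp not in backgrounds or (selection.empty or
                                     sp not in set(selection["species"])):
            continue
        try:
            design_full = covsel.build_design(sp_occ, backgrounds[sp], landscape,
                                              species_id=sp)
            arms = arm_variables(selection, sp)
            for arm in cfg.arms:
                variables = arms[arm]
                if not variables:
                    raise ValueError(f"arm {arm!r} has no selected variables")
                design = design_full.subset(variables)
                splits = models.split_replicates(
                    design, cfg.n_replicates, cfg.test_fraction,
                    seed=derive_seed(cfg.seed, f"splits:{arm}", sp))
                bundle = models.fit_bundle(
                    design, splits, cfg.families, arm=arm,
                    hyperparams=cfg.hyperparams,
                    seed=derive_seed(cfg.seed, f"fit:{arm}", sp))
                n_fits += len(bundle.live_members())
                metric_rows.append(metrics.evaluate_bundle(bundle, splits, design))
                if arm == "climate_soil":
                    importance_rows.append(importance.bundle_importance(
                        bundle, design, cfg.n_permutations,
                        seed=derive_seed(cfg.seed, "importance", sp)))
        except Exception as exc:  # noqa: BLE001 - per-species isolation
            log.warning("species %s skipped at modeling stage: %s", sp, exc)
            skipped.append({"species": sp, "stage": "model", "reason": str(exc)})
    metric_table = pd.concat(metric_rows, ignore_index=True) if metric_rows else pd.DataFrame()
    imp_table = pd.concat(importance_rows, ignore_index=True) if importance_rows else pd.DataFrame()
    return metric_table, imp_table, skipped, n_fits


def stage_contributions(cfg: PipelineConfig, importance_table: pd.DataFrame,
                        assignments: pd.DataFrame, categories: dict[str, str]
                        ) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Per-species relative contributions and the ecoregion-mean tables."""
    if importance_table.empty:
        return pd.DataFrame(), {}
    contribs = pd.concat([importance.relative_contributions(rec)
                          for _, rec in importance_table.groupby("species")],
                         ignore_index=True)
    tables = {}
    for tau in cfg.thresholds:
        tab = importance.aggregate_contributions(contribs, assignments, tau, categories)
        if not tab.empty:
            tables[tau] = tab
    return contribs, tables


def stage_sensitivity(cfg: PipelineConfig, metric_table: pd.DataFrame,
                      assignments: pd.DataFrame) -> dict[str, analysis.SensitivityResult]:
    """Threshold x ecoregion two-way ANOVA + Tukey HSD on ensemble AUC/TSS."""
    out = {}
    sens_input = build_sensitivity_table(metric_table, assignments, cfg.thresholds)
    for response in ("auc", "tss"):
        try:
            out[response] = analysis.sensitivity_anova(sens_input, response)
        except Exception as exc:  # degenerate designs (one region or threshold)
            log.warning("sensitivity ANOVA on %s skipped: %s", response, exc)
    return out


def build_sensitivity_table(metric_table: pd.DataFrame, assignments: pd.DataFrame,
                            thresholds: tuple[float, ...],
                            family: str = "ENSEMBLE") -> pd.DataFrame:
    """Per-(species, threshold) replicate-mean AUC/TSS with the species'
    assigned ecoregion at that threshold: the unit of replication for the
    sensitivity ANOVA.  A species contributes a row at every threshold at
    which it is assigned."""
    if metric_table.empty:
        return pd.DataFrame(columns=["species", "threshold", "ecoregion", "auc", "tss"])
    means = (metric_table[metric_table["family"] == family]
             .groupby("species")[["auc", "tss"]].mean().reset_index())
    rows = []
    for tau in thresholds:
        col = f"assigned_{tau}"
        sub = assignments[["species", col]].dropna().rename(columns={col: "ecoregion"})
        merged = sub.merge(means, on="species")
        merged["threshold"] = tau
        rows.append(merged)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full study; returns the result tables and writes CSV
    outputs plus ``manifest.json`` under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "synthetic":
        landscape, eco, occ_raw = stage_simulate(cfg)
        save_landscape(landscape, outdir / "landscape", params={"seed": cfg.seed})
        save_ecoregions(eco, outdir / "ecoregions.asc")
    else:
        landscape, eco, occ_raw = load_inputs(cfg)

    prepped = stage_prep(cfg, landscape, eco, occ_raw)
    selection, skip_sel = stage_select(cfg, landscape, prepped["occurrences"],
                                       prepped["backgrounds"])
    metric_table, importance_table, skip_fit, n_fits = stage_model(
        cfg, landscape, prepped["occurrences"], prepped["backgrounds"], selection)
    categories = {v.name: v.category for v in landscape.catalog}
    contribs, contrib_tables = stage_contributions(cfg, importance_table,
                                                   prepped["assignments"], categories)
    sensitivity = stage_sensitivity(cfg, metric_table, prepped["assignments"])

    results = {
        "landscape": landscape, "ecoregions": eco,
        "occurrences": prepped["occurrences"], "dropped": prepped["dropped"],
        "assignments": prepped["assignments"], "richness": prepped["richness"],
        "backgrounds": prepped["backgrounds"],
        "selection": selection, "metrics": metric_table,
        "importance": importance_table, "contributions": contribs,
        "contribution_tables": contrib_tables, "sensitivity": sensitivity,
        "skipped": prepped["skipped"] + skip_sel + skip_fit,
    }
    _write_outputs(cfg, outdir, results, n_fits)
    return results


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(cfg: PipelineConfig, outdir: Path, results: dict, n_fits: int) -> None:
    files = {}

    def write_csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        files[name] = {"sha256": _sha256(path), "rows": len(df)}

    write_csv("occurrences_filtered.csv", results["occurrences"])
    write_csv("occurrences_dropped.csv", results["dropped"])
    write_csv("assignments.csv", results["assignments"])
    write_csv("richness.csv", results["richness"])
    for sp, bg in results["backgrounds"].items():
        write_csv(f"background_{sp}.csv", bg)
    write_csv("selection.csv", results["selection"])
    write_csv("metrics.csv", results["metrics"])
    write_csv("metrics_summary.csv", metrics.summarize_metrics(results["metrics"]))
    write_csv("importance.csv", results["importance"])
    write_csv("contributions.csv", results["contributions"])
    for tau, tab in results["contribution_tables"].items():
        write_csv(f"contribution_table_tau{tau}.csv", tab)
    for response, res in results["sensitivity"].items():
        write_csv(f"sensitivity_{response}_tukey.csv", res.tukey)
        write_csv(f"sensitivity_{response}_anova.csv",
                  res.anova.reset_index(names="term"))

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "master_seed": cfg.seed,
        "n_model_fits": n_fits,
        "skipped_species": results["skipped"],
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
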