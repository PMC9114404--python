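"""End-to-end orchestration: seascape/ingest -> terrain -> stratify ->
survey cleaning -> distribution models -> community maps -> statistics.

Every threshold and seed that affects results lives in
:class:`PipelineConfig`, which serialises losslessly to YAML next to the
run's outputs.  Stage seeds are derived deterministically from the
global seed and the stage name, so a run is a pure function of its
config.  Each stage writes its artifacts into the run directory and logs
one line with the counts that matter (images dropped, morphotypes
filtered, cells masked); a MANIFEST file lists every artifact with its
SHA-256 digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import community_maps, sdm, seascape, stats_compare, stratify, survey
from .grids import GridStack, read_grid, write_grid
from .sdm import RFConfig, derive_seed
from .seascape import SeascapeSpec, SurveyDesign


@dataclass
class PipelineConfig:
    """Every tunable of the full analysis, with the field's defaults."""

    seed: int = 0
    # synthetic inputs (used unless bathymetry_path is given)
    seascape: SeascapeSpec = field(default_factory=SeascapeSpec)
    design: SurveyDesign = field(default_factory=SurveyDesign)
    community_sizes: dict | None = None
    target_density_per_m2: float = 0.6
    # real inputs
    bathymetry_path: str | None = None
    annotations_path: str | None = None
    # stage parameters
    bpi_radii_m: tuple = (1000.0, 17000.0)
    stratify_k: int = 4
    stratify_algorithm: str = "k_means"
    prevalence_min_images: int = 10
    prevalence_inclusive: bool = True
    overlap_separation_factor: float = 1.0
    rf_n_trees: int = 500
    richness_threshold: float = 0.5
    assemblage_k_range: tuple = (2, 10)
    habitat_k: int | None = None
    depth_mask_m: float | None = None
    comparison_resolution_m: float = 715.0
    n_start: int = 25
    permanova_n_permutations: int = 999
    permanova_cells_per_group: int = 500

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "seascape" in raw and isinstance(raw["seascape"], dict):
            sea = dict(raw["seascape"])
            for key in ("plain_depth_range_m",):
                if key in sea and isinstance(sea[key], list):
                    sea[key] = tuple(sea[key])
            if "seamounts" in sea:
                sea["seamounts"] = tuple(tuple(s) for s in sea["seamounts"])
            raw["seascape"] = SeascapeSpec(**sea)
        if "design" in raw and isinstance(raw["design"], dict):
            raw["design"] = SurveyDesign(**raw["design"])
        for key in ("bpi_radii_m", "assemblage_k_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_csv(df: pd.DataFrame, path: str, **kw) -> None:
    df.to_csv(path, float_format="%.10g", lineterminator="\n", **kw)


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Run the whole analysis; returns a dict of the headline results.

    Writes rasters (.asc), tables (.csv), the serialized config, a stage
    log and a MANIFEST into ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    log: list = []
    results: dict = {}

    def stage_seed(name: str) -> int:
        return derive_seed(config.seed, f"stage:{name}")

    # -- inputs -----------------------------------------------------------
    if config.bathymetry_path is None:
        spec = dataclasses.replace(config.seascape,
                                   seed=stage_seed("seascape"))
        depth = seascape.generate_bathymetry(spec)
        env = seascape.generate_env_layers(depth, spec)
        niches = seascape.make_community(config.community_sizes,
                                         seed=stage_seed("community"))
        niches = seascape.calibrate_density(
            env, niches, config.target_density_per_m2,
            config.design.image_area_mean_m2)
        design = dataclasses.replace(config.design, seed=stage_seed("survey"))
        table, truth = seascape.simulate_survey(env, niches, design)
        write_grid(truth.zone_map, os.path.join(out_dir, "planted_zones.asc"))
        log.append(f"simulate: {len(table)} images, {len(niches)} morphotypes")
    else:
        depth = read_grid(config.bathymetry_path)
        env = GridStack({"depth": depth})
        table = pd.read_csv(config.annotations_path)
        truth = None
        log.append(f"ingest: {len(table)} images from {config.annotations_path}")
    write_grid(env["depth"], os.path.join(out_dir, "depth.asc"))

    # -- terrain ----------------------------------------------------------
    from .terrain import terrain_stack

    terrain = terrain_stack(env["depth"], config.bpi_radii_m)
    if "backscatter" in env:
        terrain.add("backscatter", env["backscatter"].copy())
    for name in terrain.names:
        if name != "depth":
            write_grid(terrain[name], os.path.join(out_dir, f"{name}.asc"))
    log.append(f"terrain: layers {terrain.names}")

    # -- survey cleaning --------------------------------------------------
    table, overlap_log = survey.remove_overlaps(
        table, min_separation_factor=config.overlap_separation_factor)
    log.append(f"overlaps: dropped {len(overlap_log.dropped_ids)} images")

    # -- stratification and subsampling -----------------------------------
    strata = stratify.cluster_strata(terrain, config.stratify_k,
                                     config.stratify_algorithm,
                                     seed=stage_seed("stratify"))
    coverage = stratify.coverage_fractions(strata)
    assignment = stratify.assign_strata(table, strata)
    available = {lab: int((assignment == lab).sum()) for lab in coverage}
    plan = stratify.allocate_subsample(available, coverage)
    subsample = stratify.draw_subsample(table, strata, plan,
                                        seed=stage_seed("subsample"))
    write_grid(strata.grid, os.path.join(out_dir, "strata.asc"))
    _write_csv(pd.DataFrame({
        "stratum": plan.strata,
        "coverage": [plan.coverage[s] for s in plan.strata],
        "available": [plan.available[s] for s in plan.strata],
        "allocated": [plan.allocated[s] for s in plan.strata],
    }), os.path.join(out_dir, "allocation.csv"), index=False)
    _write_csv(subsample, os.path.join(out_dir, "subsample.csv"), index=False)
    log.append(f"stratify: allocation {plan.allocated} (anchor {plan.anchor})")

    # -- presence-absence and prevalence filter ----------------------------
    matrix = survey.to_presence_absence(subsample)
    filtered, report = survey.prevalence_filter(
        matrix, config.prevalence_min_images, config.prevalence_inclusive,
        source_table=subsample)
    summary = survey.survey_summary(subsample)
    results["survey_summary"] = summary
    results["prevalence_report"] = report
    log.append(f"prevalence: retained {report.n_retained} of "
               f"{report.n_retained + report.n_excluded} morphotypes")

    # -- distribution models ----------------------------------------------
    predictor_stack = env
    predictors, dropped = sdm.build_predictor_table(subsample, predictor_stack)
    kept = subsample.loc[predictors.index]
    rf_config = RFConfig(n_trees=config.rf_n_trees, seed=stage_seed("sdm"))
    kept_matrix = survey.PresenceAbsenceMatrix(
        filtered.values.loc[kept["image_id"]])
    prob_stack, failures = sdm.fit_all(kept_matrix, predictors,
                                       predictor_stack, rf_config)
    _write_csv(prob_stack.registry(), os.path.join(out_dir, "models.csv"),
               index=False)
    log.append(f"sdm: fitted {len(prob_stack)} forests, "
               f"{len(failures)} skipped, {len(dropped)} images off-grid")
    results["n_models"] = len(prob_stack)
    if len(prob_stack) == 0:
        _finish(out_dir, config, log, results)
        return results

    # -- community maps ----------------------------------------------------
    richness = community_maps.richness_map(prob_stack,
                                           config.richness_threshold)
    write_grid(richness, os.path.join(out_dir, "richness.asc"))
    results["mean_richness"] = float(np.nanmean(richness.values))

    k_lo, k_hi = config.assemblage_k_range
    assemblages, cascade = community_maps.assemblage_map(
        prob_stack, range(k_lo, k_hi + 1), config.n_start,
        seed=stage_seed("assemblage"))
    write_grid(assemblages.grid, os.path.join(out_dir, "assemblages.asc"))
    _write_csv(pd.DataFrame({"k": list(cascade.scores),
                             "calinski_harabasz": list(cascade.scores.values())}),
               os.path.join(out_dir, "assemblage_cascade.csv"), index=False)
    results["assemblage_k"] = assemblages.k
    log.append(f"assemblages: best_k={assemblages.k}")

    habitats, hab_cascade = community_maps.habitat_map(
        prob_stack, env, k=config.habitat_k,
        k_range=range(k_lo, k_hi + 1), depth_mask_m=config.depth_mask_m,
        target_resolution_m=(config.comparison_resolution_m
                             if config.comparison_resolution_m
                             > env.reference.cell_size_m else None),
        n_start=config.n_start, seed=stage_seed("habitat"))
    write_grid(habitats.grid, os.path.join(out_dir, "habitats.asc"))
    results["habitat_k"] = habitats.k
    log.append(f"habitats: k={habitats.k}")

    # -- statistics ---------------------------------------------------------
    mask = prob_stack.grids.joint_valid_mask
    cell_labels = assemblages.grid.values[mask]
    X = np.column_stack([prob_stack[n].values[mask]
                         for n in prob_stack.names])
    rng = np.random.default_rng(stage_seed("permanova"))
    sel_idx = []
    for g in range(1, assemblages.k + 1):
        members = np.nonzero(cell_labels == g)[0]
        take = min(len(members), config.permanova_cells_per_group)
        sel_idx.append(rng.choice(members, size=take, replace=False))
    sel = np.concatenate(sel_idx)
    perm_results = stats_compare.pairwise_permanova(
        X[sel], cell_labels[sel],
        n_permutations=config.permanova_n_permutations,
        seed=stage_seed("permanova"))
    perm_table = stats_compare.permanova_table(perm_results)
    _write_csv(perm_table, os.path.join(out_dir, "permanova.csv"), index=False)
    results["permanova"] = perm_table
    log.append("permanova: adjusted p "
               + ", ".join(f"{r.pair}: {r.p_adjusted:.3f}" for r in perm_results))

    image_labels = assemblages.grid.sample(kept["x"].to_numpy(),
                                           kept["y"].to_numpy())
    ok = np.isfinite(image_labels)
    comp = stats_compare.composition_fractions(
        survey.PresenceAbsenceMatrix(kept_matrix.values.loc[kept["image_id"][ok]]),
        image_labels[ok].astype(int))
    _write_csv(comp, os.path.join(out_dir, "composition.csv"))
    summary_tbl = stats_compare.assemblage_summary(
        assemblages, kept.loc[ok], survey.to_presence_absence(kept.loc[ok]))
    _write_csv(summary_tbl, os.path.join(out_dir, "assemblage_summary.csv"),
               index=False)
    results["assemblage_summary"] = summary_tbl

    if truth is not None and truth.zone_map is not None:
        from sklearn.metrics import adjusted_rand_score

        zones = truth.zone_map.values[mask]
        both = np.isfinite(zones) & np.isfinite(cell_labels)
        results["zone_ari"] = float(adjusted_rand_score(
            zones[both].astype(int), cell_labels[both].astype(int)))
        log.append(f"recovery: ARI vs planted zones {results['zone_ari']:.3f}")

    _finish(out_dir, config, log, results)
    return results


def _finish(out_dir: str, config: PipelineConfig, log: list,
            results: dict) -> None:
    config.to_yaml(os.path.join(out_dir, "config.yaml"))
    with open(os.path.join(out_dir, "log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    manifest = {}
    for name in sorted(os.listdir(out_dir)):
        if name == "MANIFEST.json":
            continue
        path = os.path.join(out_dir, name)
        if os.path.isfile(path):
            with open(path, "rb") as fh:
                manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(out_dir, "MANIFEST.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
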