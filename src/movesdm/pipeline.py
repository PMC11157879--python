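"""Pipeline orchestration: staged runs, manifests, and the study driver.

Two entry surfaces:

* :func:`run_study` — the in-memory end-to-end driver used by the analysis
  scripts, the tests and the acceptance script: preprocess tracks, build
  the use-availability design, match covariates, fit/tune/evaluate one
  boosted model per region x behaviour, predict and threshold suitability,
  and validate it spatially.
* :func:`run_stage` — a file-based stage wrapper with an input/parameter
  hash manifest, so re-running an unchanged stage is a no-op and stale
  upstream artefacts are detected.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import env_matching as em
from . import habitat_model as hm
from . import spatial_validation as sv
from .io_formats import EnvLayer, RegionSet
from .pseudoabsence import generate_design, clip_to_extent
from .synthetic import Scenario, true_state_at
from .track_processing import SSMTrack, preprocess_tracks, ssm_tracks_to_frame

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Per-stage parameters with the defaults named across the modules."""

    seed: int = 0
    max_gap_days: float = 5.0
    g_threshold: float = 0.8
    n_pseudo_per_track: int = 5
    bias_weight: float = 0.25
    collinearity_cutoff: float = 0.6
    test_fraction: float = 0.25
    min_auc: float = 0.6
    min_accuracy: float = 0.4
    min_points_per_window: int = 20
    tuning_grid: list = field(default_factory=lambda: [
        hm.GBMConfig(d, t, 10, s, 0.75)
        for d in (2, 3) for t in (100, 300) for s in (0.05, 0.1)])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed below 2^31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def default_covariate_specs() -> list[em.CovariateSpec]:
    """The standard covariate set: static seafloor terrain plus composited
    dynamic fields, with the 14-day lagged, log-transformed chlorophyll."""
    return [
        em.CovariateSpec("bathymetry", "bathymetry", "static"),
        em.CovariateSpec("rugosity", "rugosity", "static"),
        em.CovariateSpec("dist_canyon", "dist_canyon", "static"),
        em.CovariateSpec("sst", "sst", "composite_5d"),
        em.CovariateSpec("sst_sd", "sst", "monthly_sd"),
        em.CovariateSpec("chl", "chl", "composite_8d", transform="log", lag_days=14),
        em.CovariateSpec("ssha", "ssha", "composite_5d"),
    ]


def derive_static_layers(stacks: dict, canyons) -> dict:
    """Add rugosity and distance-to-canyon derived from bathymetry."""
    out = dict(stacks)
    if "rugosity" not in out:
        out["rugosity"] = em.compute_rugosity(stacks["bathymetry"])
    if "dist_canyon" not in out and canyons is not None:
        out["dist_canyon"] = em.compute_distance_to(canyons, stacks["bathymetry"])
    return out


@dataclass
class RegionModelResult:
    region: str
    behaviour: str
    n_presence: int
    n_pseudo: int
    covariates_kept: list[str]
    dropped_collinear: list
    tuned_config: hm.GBMConfig
    model: hm.FittedModel
    metrics: dict
    threshold: float
    product: hm.SuitabilityProduct
    surface: sv.AccuracySurface | None
    variogram: sv.VariogramSummary | None
    kernel: sv.KernelGeometry | None
    geomorph_pct: dict
    validated_fraction: float
    audit: list


@dataclass
class StudyResult:
    ssm_tracks: list[SSMTrack]
    design: pd.DataFrame
    dataset: em.ModelDataset
    models: dict[tuple[str, str], RegionModelResult]
    behaviour_agreement_pct: float | None = None
    suitability_spearman: float | None = None


def select_and_fit(frame: pd.DataFrame, covariates: list[str],
                   config: PipelineConfig, seed: int):
    """Variable screening, tuning, simplification and the AUC-floor refit.

    The Pearson collinearity screen runs over the environmental fields only
    (month is the seasonality control, not a field, and always enters the
    candidate set); the tuned configuration is then simplified by backward
    elimination before the final fit. Returns
    (model, metrics, audit trail, dropped collinear pairs, tuned config).
    """
    pre = hm.fit(frame, covariates, hm.GBMConfig(2, 100, 10, 0.1, 0.75), seed)
    env_covs = [c for c in covariates if c != "month"]
    kept, dropped = em.collinearity_filter(
        frame, config.collinearity_cutoff, pre.relative_influence, env_covs)
    if "month" in covariates:
        kept = kept + ["month"]

    tuned, _tab = hm.tune(frame, kept, config.tuning_grid, seed=seed)
    kept, simplify_trail = hm.simplify_covariates(frame, kept, tuned, seed)
    model, metrics, audit = hm.iterative_variable_refit(
        frame, kept, tuned, config.min_auc, config.test_fraction, seed,
        min_covariates=min(2, len(kept)))
    audit = [{"simplify": simplify_trail}] + audit
    return model, metrics, audit, dropped, tuned


def predict_time_averaged(model: hm.FittedModel, stacks: dict,
                          specs: list[em.CovariateSpec],
                          period, region: str, region_poly,
                          covariate_ranges=None, window_days: int = 10):
    """Time-marginalized suitability: predict per composite window, then
    average the predictions.

    Predicting once on period-averaged covariates evaluates the trees at
    covariate combinations that were never realized (an off-manifold
    average); averaging the per-window predictions marginalizes the model
    over the realized conditions instead, and averages away the response
    to transient anomalies. Cells predicted in fewer than half the windows
    stay masked. Returns (continuous EnvLayer, reference PredictionGrid).
    """
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    used = [s for s in specs if s.name in model.covariates]
    surfaces = []
    grid = None
    day = start
    while day < end:
        w1 = min(day + pd.Timedelta(days=window_days), end)
        try:
            pg = em.build_prediction_grid(stacks, used, (day, w1),
                                          region, region_poly)
        except (em.MissingLayerError, em.ConfigurationError):
            day = w1
            continue
        surfaces.append(hm.predict_surface(model, pg, covariate_ranges).grid)
        grid = pg
        day = w1
    if not surfaces:
        raise em.MissingLayerError("no composite window inside the period")
    stack = np.stack(surfaces)
    with np.errstate(all="ignore"):
        avg = np.nanmean(stack, axis=0)
    avg[np.isfinite(stack).sum(axis=0) < 0.5 * len(surfaces)] = np.nan
    ref = next(iter(grid.layers.values()))
    continuous = EnvLayer("suitability", avg, grid.transform, crs=ref.crs,
                          time_window=(start, end), units="probability")
    return continuous, grid


def predict_products(model: hm.FittedModel, frame: pd.DataFrame, stacks: dict,
                     specs: list[em.CovariateSpec], region_poly, region: str):
    """Prevalence threshold, prediction grid, continuous and binary maps."""
    scores_all = model.predict(frame[model.covariates])
    labels_all = frame["label"].to_numpy().astype(int)
    threshold = hm.prevalence_threshold(scores_all, labels_all)
    period = (pd.Timestamp(frame["time"].min()), pd.Timestamp(frame["time"].max()))
    ranges = {c: (float(frame[c].min()), float(frame[c].max()))
              for c in model.covariates if c in frame}
    continuous, grid = predict_time_averaged(model, stacks, specs, period,
                                             region, region_poly, ranges)
    binary = hm.apply_threshold(continuous, threshold)
    return scores_all, labels_all, threshold, grid, continuous, binary


def validate_products(frame: pd.DataFrame, scores_all, labels_all, threshold,
                      grid, binary, config: PipelineConfig, region: str,
                      behaviour: str):
    """Variogram-driven spatial Kappa/AUC surfaces and the validated map."""
    variogram = kernel = surface = validated = None
    try:
        variogram = sv.empirical_variogram(
            frame["lon"].to_numpy(), frame["lat"].to_numpy(), labels_all,
            track_ids=frame["animal_id"].to_numpy(),
            seed=config.stage_seed(f"vgram:{region}:{behaviour}"))
        kernel = sv.kernel_rule(variogram)
        surface = sv.accuracy_surface(
            frame["lon"].to_numpy(), frame["lat"].to_numpy(), scores_all,
            labels_all, kernel, grid.transform, threshold,
            config.min_points_per_window)
        validated = sv.validate_map(binary, surface, config.min_accuracy)
    except ValueError as e:
        log.warning("%s/%s: spatial validation unavailable (%s)", region, behaviour, e)
    return variogram, kernel, surface, validated


def _run_one_model(frame: pd.DataFrame, covariates: list[str], stacks: dict,
                   specs: list[em.CovariateSpec], region_poly, region: str,
                   behaviour: str, config: PipelineConfig,
                   geomorph: EnvLayer | None) -> RegionModelResult:
    seed = config.stage_seed(f"fit:{region}:{behaviour}")
    model, metrics, audit, dropped, tuned = select_and_fit(
        frame, covariates, config, seed)
    scores_all, labels_all, threshold, grid, continuous, binary = \
        predict_products(model, frame, stacks, specs, region_poly, region)
    variogram, kernel, surface, validated = validate_products(
        frame, scores_all, labels_all, threshold, grid, binary, config,
        region, behaviour)
    product = hm.SuitabilityProduct(continuous, threshold, binary, validated,
                                    dict(metrics))
    geo_pct = {}
    if geomorph is not None:
        geo = em._resample(geomorph, grid.transform, categorical=True)
        geo_pct = em.geomorph_overlay(binary, geo,
                                      {1: "shelf", 2: "slope", 3: "basin"})
    if validated is not None:
        nb = float(np.nansum(binary.grid == 1))
        nv = float(np.nansum(validated.grid == 1))
        vfrac = nv / nb if nb > 0 else 0.0
    else:
        vfrac = np.nan
    return RegionModelResult(
        region, behaviour, int((labels_all == 1).sum()), int((labels_all == 0).sum()),
        list(model.covariates), dropped, tuned, model, metrics, threshold,
        product, surface, variogram, kernel, geo_pct, vfrac, audit)


def run_study(scenario: Scenario, config: PipelineConfig | None = None,
              specs: list[em.CovariateSpec] | None = None) -> StudyResult:
    """Full pipeline on one (synthetic or real) study."""
    config = config or PipelineConfig()
    specs = specs or default_covariate_specs()

    ssm = preprocess_tracks(scenario.tracks, scenario.regions,
                            config.max_gap_days, config.g_threshold)

    extents = {r.name: r.polygon for r in scenario.regions.regions}
    design = generate_design(ssm, extents, scenario.stacks.get("land"),
                             config.n_pseudo_per_track, config.bias_weight,
                             config.stage_seed("pseudoabsence"))
    clipped = []
    for region, g in design.groupby("region"):
        clipped.append(clip_to_extent(g, extents[region]))
    design = pd.concat(clipped, ignore_index=True)

    stacks = derive_static_layers(scenario.stacks, scenario.canyons)
    dataset = em.extract_covariates(design, specs, stacks)

    covariates = list(dataset.covariates) + ["month"]
    models = {}
    frame_all = dataset.complete_cases()
    for (region, behaviour), grp in frame_all.groupby(["region", "behaviour"]):
        if grp["label"].nunique() < 2 or len(grp) < 60:
            log.warning("%s/%s: too little data (%d rows), skipped",
                        region, behaviour, len(grp))
            continue
        models[(region, behaviour)] = _run_one_model(
            grp.reset_index(drop=True), covariates, stacks, specs,
            extents[region], region, behaviour, config,
            scenario.stacks.get("geomorph"))

    result = StudyResult(ssm, design, dataset, models)
    _score_against_truth(scenario, config, result)
    return result


def _score_against_truth(scenario: Scenario, config: PipelineConfig,
                         result: StudyResult) -> None:
    """Recovery metrics against recorded ground truth (synthetic runs)."""
    truth = getattr(scenario, "truth", None)
    if truth is None or not truth.true_tracks:
        return
    id2truth = {}
    for i, t in enumerate(truth.true_tracks):
        id2truth[f"whale_{i:02d}"] = t
    agree = tot = 0
    for tr in result.ssm_tracks:
        tt = id2truth.get(tr.animal_id)
        if tt is None:
            continue
        st = true_state_at(tt, [p.time for p in tr.locations])
        est = np.array([p.behaviour for p in tr.locations])
        agree += int((est == st["behaviour_true"].to_numpy()).sum())
        tot += len(est)
    if tot:
        result.behaviour_agreement_pct = 100.0 * agree / tot

    # rank agreement between the foraging model surface and true suitability
    from scipy.stats import spearmanr
    for (region, behaviour), rm in result.models.items():
        if behaviour != "foraging":
            continue
        pred = rm.product.continuous
        true_rs = em._resample(truth.true_suitability, pred.transform, False)
        ok = np.isfinite(pred.grid) & np.isfinite(true_rs.grid)
        if ok.sum() > 10:
            rho = float(spearmanr(pred.grid[ok], true_rs.grid[ok]).statistic)
            result.suitability_spearman = rho
        break


def report(result: StudyResult) -> dict:
    """Machine-readable study summary (one block per region x behaviour)."""
    out = {"n_ssm_tracks": len(result.ssm_tracks),
           "behaviour_agreement_pct": result.behaviour_agreement_pct,
           "suitability_spearman": result.suitability_spearman,
           "models": {}}
    for (region, behaviour), rm in result.models.items():
        out["models"][f"{region}/{behaviour}"] = {
            "n_presence": rm.n_presence,
            "n_pseudo_absence": rm.n_pseudo,
            "pseudo_ratio": rm.n_pseudo / max(rm.n_presence, 1),
            "covariates": rm.covariates_kept,
            "dropped_collinear": [(a, b, round(r, 3)) for a, b, r in rm.dropped_collinear],
            "tuned_config": vars(rm.tuned_config) if hasattr(rm.tuned_config, "__dict__")
                             else str(rm.tuned_config),
            "global_auc": rm.metrics["global_auc"],
            "global_kappa": rm.metrics["global_kappa"],
            "spearman": rm.metrics["spearman"],
            "threshold": rm.threshold,
            "geomorph_pct": {k: round(v, 1) for k, v in rm.geomorph_pct.items()},
            "validated_fraction_of_suitable": rm.validated_fraction,
            "n_refit_drops": sum(1 for a in rm.audit if "metrics" in a) - 1,
        }
    return out


def report_markdown(rep: dict) -> str:
    lines = ["| region/behaviour | n pres | n pseudo | AUC | Kappa | rho | thr | valid. frac |",
             "|---|---|---|---|---|---|---|---|"]
    for key, m in rep["models"].items():
        lines.append(
            f"| {key} | {m['n_presence']} | {m['n_pseudo_absence']} | "
            f"{m['global_auc']:.2f} | {m['global_kappa']:.2f} | {m['spearman']:.2f} | "
            f"{m['threshold']:.2f} | {m['validated_fraction_of_suitable']:.2f} |")
    return "\n".join(lines)


# ---------------------------------------------------------------- stages

def _hash_paths(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(map(Path, paths)):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def run_stage(name: str, func, inputs: list, params: dict, out_dir,
              manifest_path="manifest.json") -> dict:
    """Run ``func(out_dir)`` unless inputs+params are unchanged.

    The manifest records, per stage, the input hash, parameters and the
    produced files; a stage with a matching hash and existing outputs is
    skipped. Returns the manifest entry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mpath = out_dir / manifest_path
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    for p in inputs:
        if not Path(p).exists():
            raise FileNotFoundError(f"stage {name}: missing upstream input {p} "
                                    f"(re-run the producing stage)")
    digest = hashlib.sha256(
        (_hash_paths(inputs) + json.dumps(params, sort_keys=True, default=str))
        .encode()).hexdigest()
    entry = manifest.get(name)
    if entry and entry.get("hash") == digest and \
            all(Path(f).exists() for f in entry.get("outputs", [])):
        log.info("stage %s: up to date, skipped", name)
        entry["skipped"] = True
        return entry
    outputs = func(out_dir)
    entry = {"hash": digest, "params": {k: str(v) for k, v in params.items()},
             "outputs": [str(f) for f in (outputs or [])], "skipped": False}
    manifest[name] = entry
    mpath.write_text(json.dumps(manifest, indent=2))
    return entry
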