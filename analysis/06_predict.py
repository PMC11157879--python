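"""Stage 6 — gridded suitability predictions and binary habitat maps.

For each fitted model: average the dynamic covariates over the model's
data period, resample all layers to the coarsest resolution, clip to the
region, predict cellwise suitability (masking cells outside the training
covariate support), threshold at the prevalence-matched cut-off, and
overlay the binary map on the geomorphic classes. Writes
results/maps/*.nc and results/maps/summary.json.
"""

import json
from pathlib import Path

import joblib
import pandas as pd

import movesdm.env_matching as em
from movesdm.io_formats import read_regions_geojson, write_raster
from movesdm.pipeline import (default_covariate_specs, derive_static_layers,
                              predict_products, run_stage)
from movesdm.synthetic import ScenarioConfig, regenerate_env

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    study = RESULTS / "study"
    with open(study / "scenario_config.json") as fh:
        raw = json.load(fh)
    raw["duration_days_range"] = tuple(raw["duration_days_range"])
    cfg = ScenarioConfig(**raw)

    def stage(out_dir):
        frame = pd.read_csv(out_dir / "dataset.csv", parse_dates=["time"])
        frame = frame[~frame["missing_any"]].reset_index(drop=True)
        regions = read_regions_geojson(study / "regions.geojson")
        stacks, canyons, _ = regenerate_env(cfg)
        stacks = derive_static_layers(stacks, canyons)
        specs = default_covariate_specs()
        mdir = out_dir / "models"
        outdir = out_dir / "maps"
        outdir.mkdir(exist_ok=True)
        outputs = []
        summary = {}
        for path in sorted(mdir.glob("*.joblib")):
            region, behaviour = path.stem.split("__")
            model = joblib.load(path)
            grp = frame[(frame["region"] == region)
                        & (frame["behaviour"] == behaviour)].reset_index(drop=True)
            scores, labels, threshold, grid, cont, binary = predict_products(
                model, grp, stacks, specs, regions[region].polygon, region)
            write_raster(cont, outdir / f"{path.stem}_suitability.nc")
            write_raster(binary, outdir / f"{path.stem}_suitable.nc")
            geo = em._resample(stacks["geomorph"], grid.transform, categorical=True)
            pct = em.geomorph_overlay(binary, geo, {1: "shelf", 2: "slope", 3: "basin"})
            summary[path.stem] = {"threshold": threshold,
                                  "geomorph_pct": {k: round(v, 1)
                                                   for k, v in pct.items()}}
            print(f"{region}/{behaviour}: threshold {threshold:.2f}; "
                  f"suitable habitat by class {summary[path.stem]['geomorph_pct']}")
            outputs += [outdir / f"{path.stem}_suitability.nc",
                        outdir / f"{path.stem}_suitable.nc"]
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        return outputs + [outdir / "summary.json"]

    run_stage("predict", stage, inputs=[RESULTS / "dataset.csv",
                                        RESULTS / "models" / "metrics.json"],
              params={}, out_dir=RESULTS)


if __name__ == "__main__":
    main()
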