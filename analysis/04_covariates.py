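"""Stage 4 — derive and match environmental covariates.

Derives rugosity and distance-to-canyon from the bathymetry, regenerates
the dynamic fields from the recorded scenario config, composites them
(5/8-day means, monthly SDs, 14-day lagged log chlorophyll) and matches
one value per covariate to every presence/pseudo-absence row. Writes
results/dataset.csv.
"""

import json
from pathlib import Path

import pandas as pd

from movesdm.pipeline import default_covariate_specs, derive_static_layers, run_stage
from movesdm.synthetic import ScenarioConfig, regenerate_env
import movesdm.env_matching as em

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    study = RESULTS / "study"
    with open(study / "scenario_config.json") as fh:
        raw = json.load(fh)
    raw["duration_days_range"] = tuple(raw["duration_days_range"])
    cfg = ScenarioConfig(**raw)

    def stage(out_dir):
        design = pd.read_csv(out_dir / "design.csv", parse_dates=["time"])
        stacks, canyons, _period = regenerate_env(cfg)
        stacks = derive_static_layers(stacks, canyons)
        specs = default_covariate_specs()
        ds = em.extract_covariates(design, specs, stacks)
        ds.frame.to_csv(out_dir / "dataset.csv", index=False)
        n_miss = int(ds.frame["missing_any"].sum())
        print(f"matched {len(specs)} covariates to {len(ds.frame)} rows; "
              f"{n_miss} rows flagged with missing values")
        return [out_dir / "dataset.csv"]

    run_stage("covariates", stage, inputs=[RESULTS / "design.csv"],
              params={"specs": [s.name for s in default_covariate_specs()]},
              out_dir=RESULTS)


if __name__ == "__main__":
    main()
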