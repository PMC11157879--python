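"""Stage 3 — simulate the use-availability design's controls.

Five constrained pseudo tracks per smoothed segment: same start point and
timestamps, empirical step/turn distributions, endpoint orientation, a
randomised 180/300-degree turning offset, and rejection off land and
outside the regional extent. Writes results/design.csv with label 1
(presence) / 0 (pseudo-absence) rows at a 5:1 ratio.
"""

import json
from pathlib import Path

import pandas as pd

from movesdm.io_formats import read_env_layer, read_regions_geojson
from movesdm.pipeline import run_stage
from movesdm.pseudoabsence import clip_to_extent, generate_design
from movesdm.track_processing import ssm_tracks_from_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    study = RESULTS / "study"
    with open(study / "scenario_config.json") as fh:
        seed = json.load(fh)["seed"]

    def stage(out_dir):
        ssm = ssm_tracks_from_frame(pd.read_csv(out_dir / "ssm_tracks.csv"))
        regions = read_regions_geojson(study / "regions.geojson")
        land = read_env_layer(study / "rasters" / "land.nc", "land")
        extents = {r.name: r.polygon for r in regions.regions}
        design = generate_design(ssm, extents, land, n_per_track=5, seed=seed)
        design = pd.concat([clip_to_extent(g, extents[r])
                            for r, g in design.groupby("region")],
                           ignore_index=True)
        design.to_csv(out_dir / "design.csv", index=False)
        n1 = (design["label"] == 1).sum()
        n0 = (design["label"] == 0).sum()
        print(f"{n1} presence rows, {n0} pseudo-absence rows "
              f"(ratio {n0 / max(n1, 1):.2f}:1 after clipping)")
        return [out_dir / "design.csv"]

    run_stage("pseudoabsence", stage,
              inputs=[RESULTS / "ssm_tracks.csv", study / "regions.geojson"],
              params={"n_per_track": 5, "seed": seed}, out_dir=RESULTS)


if __name__ == "__main__":
    main()
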