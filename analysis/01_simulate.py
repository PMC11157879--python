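"""Stage 1 — generate the synthetic tracking study.

Materializes a ground-truthed study under results/study/: telemetry fixes
(tracks.csv), static rasters (bathymetry, land, geomorphic classes), the
modelling regions, and the recorded truth (true suitability raster, true
tracks with per-step persistence, planted effect sizes). Dynamic fields
(SST, chlorophyll-a, SSHA) are regenerated deterministically from the
recorded config by later stages, so no bulky daily rasters are stored.

Run:  python analysis/01_simulate.py [--seed 11] [--n-whales 38]
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from movesdm.pipeline import run_stage
from movesdm.synthetic import ScenarioConfig, make_scenario

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n-whales", type=int, default=38)
    args = ap.parse_args()

    cfg = ScenarioConfig(seed=args.seed, n_whales=args.n_whales)

    def stage(out_dir):
        study = out_dir / "study"
        scen = make_scenario(cfg, out_dir=study)
        with open(study / "scenario_config.json", "w") as fh:
            json.dump(asdict(cfg), fh, indent=2, default=list)
        n_fix = sum(len(t) for t in scen.tracks)
        durs = [t.duration_days for t in scen.tracks]
        durs.sort()
        print(f"simulated {len(scen.tracks)} tracks, {n_fix} fixes; "
              f"median duration {durs[len(durs) // 2]:.0f} d "
              f"(range {durs[0]:.0f}-{durs[-1]:.0f} d)")
        return [study / "tracks.csv", study / "scenario_config.json"]

    run_stage("simulate", stage, inputs=[], params=asdict(cfg), out_dir=RESULTS)


if __name__ == "__main__":
    main()
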