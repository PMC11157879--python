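"""Stage 8 — study report and ground-truth recovery scores.

Aggregates the per-model metrics, thresholds, geomorph overlays and
validation summaries into results/report.json (+ a markdown table), and —
because this study is synthetic — scores the pipeline against the recorded
truth: behaviour-classification agreement and the rank correlation between
the predicted and true suitability surfaces.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

import movesdm.env_matching as em
from movesdm.io_formats import read_env_layer
from movesdm.pipeline import run_stage
from movesdm.synthetic import true_state_at

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    study = RESULTS / "study"

    def stage(out_dir):
        report = {"models": {}}
        with open(out_dir / "models" / "metrics.json") as fh:
            metrics = json.load(fh)
        with open(out_dir / "maps" / "summary.json") as fh:
            maps = json.load(fh)
        kernels = {}
        kpath = out_dir / "validation" / "kernel.json"
        if kpath.exists():
            with open(kpath) as fh:
                kernels = json.load(fh)
        for key, m in metrics.items():
            report["models"][key] = {**{k: m[k] for k in
                                        ("covariates", "global_auc",
                                         "global_kappa", "spearman")},
                                     **maps.get(key, {}),
                                     **kernels.get(key, {})}

        # truth recovery: behaviour agreement
        ssm = pd.read_csv(out_dir / "ssm_tracks.csv", parse_dates=["time"])
        truth = pd.read_csv(study / "truth" / "true_tracks.csv",
                            parse_dates=["time"])
        agree = tot = 0
        for (aid,), g in ssm.groupby(["animal_id"]):
            widx = int(str(aid).split("_")[1])
            tt = truth[truth["whale"] == widx]
            if not len(tt):
                continue
            st = true_state_at(tt, g["time"])
            agree += int((g["behaviour"].to_numpy()
                          == st["behaviour_true"].to_numpy()).sum())
            tot += len(g)
        report["behaviour_agreement_pct"] = 100.0 * agree / max(tot, 1)

        # truth recovery: rank agreement of the foraging suitability map
        true_suit = read_env_layer(study / "truth" / "true_suitability.nc",
                                   "true_suitability")
        for key in report["models"]:
            if not key.endswith("__foraging"):
                continue
            pred = read_env_layer(out_dir / "maps" / f"{key}_suitability.nc",
                                  "suitability")
            tr = em._resample(true_suit, pred.transform, False)
            ok = np.isfinite(pred.grid) & np.isfinite(tr.grid)
            if ok.sum() > 10:
                report["suitability_spearman"] = float(
                    spearmanr(pred.grid[ok], tr.grid[ok]).statistic)
            break

        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        lines = ["| model | AUC | Kappa | rho | threshold | geomorph % |",
                 "|---|---|---|---|---|---|"]
        for key, m in report["models"].items():
            lines.append(f"| {key} | {m['global_auc']:.2f} | "
                         f"{m['global_kappa']:.2f} | {m['spearman']:.2f} | "
                         f"{m.get('threshold', float('nan')):.2f} | "
                         f"{m.get('geomorph_pct', {})} |")
        lines.append("")
        lines.append(f"Behaviour agreement vs truth: "
                     f"{report['behaviour_agreement_pct']:.1f}%")
        if "suitability_spearman" in report:
            lines.append(f"Spearman(predicted, true suitability): "
                         f"{report['suitability_spearman']:.3f}")
        (out_dir / "report.md").write_text("\n".join(lines))
        print("\n".join(lines))
        return [out_dir / "report.json", out_dir / "report.md"]

    run_stage("report", stage,
              inputs=[RESULTS / "models" / "metrics.json",
                      RESULTS / "maps" / "summary.json"],
              params={}, out_dir=RESULTS)


if __name__ == "__main__":
    main()
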