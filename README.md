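# movesdm

Satellite-tracking-to-habitat-suitability modelling for migratory marine
megafauna, built for the whale-scale problem: a few dozen Argos/GPS tracks
of very unequal length and quality, behaviours that alternate between
area-restricted foraging and directed migration, and managers who need to
know not just *where* habitat is predicted suitable but *where that
prediction can be trusted*.

The pipeline:

1. **Track regularization** — split tracks at >5-day transmission gaps and
   smooth each segment with a correlated-random-walk state-space model
   (class-specific Argos error, `sigma = err95/1.96`), at a time step
   matched to the tag's daily fix rate.
2. **Move persistence** — estimate `g in [0,1]` per location (logit
   random-walk MAP); `g >= 0.8` labels migration, lower values foraging
   (or foraging/reproduction north of 11.5 deg S), with separate habitat
   models per region x behaviour.
3. **Pseudo-absences** — five constrained random tracks per real track
   (same start, duration and timestamps; empirical step/turn
   distributions; endpoint orientation; 180/300-degree turning offset;
   rejection off land), giving the use–availability design its controls.
4. **Covariates** — depth, rugosity, distance to canyons, SST (5-day
   composites and monthly SDs), log chlorophyll-a lagged 14 days, SSHA,
   and month; Pearson screening at |r| > 0.6.
5. **Habitat model** — Bernoulli gradient-boosted trees, grid-tuned by
   cross-validated MSE, simplified by backward elimination, evaluated on a
   25% holdout (global AUC, Kappa, Spearman), predicted onto
   period-averaged covariate grids at the coarsest resolution, and
   thresholded where predicted prevalence equals observed prevalence.
6. **Spatial validation** — an empirical variogram of the data sets a
   moving-window kernel (slope >= 0.8: diameter 2x the mean range, spacing
   1x; else 0.5x and 0.25x); spatial Kappa and spatial AUC inside each
   window map where the model discriminates, and suitable habitat is
   *validated* only where both exceed 0.4.

Because the raw whale tracks cannot be shipped, the package carries a
first-class synthetic generator: a continental-margin world with a planted
logistic suitability surface (slope-band depth preference + warm-water
preference), whales whose foraging bouts follow that surface, and
telemetry observation with real Argos class error. Every pipeline stage
has a recovery test against this recorded truth.

## Worked example

```python
from movesdm.synthetic import ScenarioConfig, make_scenario
from movesdm.pipeline import PipelineConfig, run_study, report_markdown, report

scen = make_scenario(ScenarioConfig(seed=11, n_whales=8,
                                    duration_days_range=(20, 120)))
result = run_study(scen, PipelineConfig(seed=11))
print(report_markdown(report(result)))
print(f"behaviour agreement {result.behaviour_agreement_pct:.1f}%, "
      f"suitability rank correlation {result.suitability_spearman:.2f}")
```

prints (8-whale study, a couple of minutes on one core):

```
| region/behaviour | n pres | n pseudo | AUC | Kappa | rho | thr | valid. frac |
|---|---|---|---|---|---|---|---|
| study_foraging/foraging | 476 | 2385 | 0.97 | 0.76 | 0.60 | 0.44 | 1.00 |
| study_migration/migration | 1125 | 5685 | 0.86 | 0.54 | 0.47 | 0.26 | 0.93 |
behaviour agreement 78.6%, suitability rank correlation 0.59
```

Reading the table: each region x behaviour dataset holds the presence rows
and five pseudo-absence rows per presence (minus boundary clipping);
AUC/Kappa/rho are held-out global accuracy (AUC 0.97 = excellent
discrimination); `thr` is the prevalence-matched cut-off between suitable
and unsuitable habitat; and `valid. frac` is the share of predicted
suitable cells whose local spatial Kappa *and* spatial AUC exceed 0.4 —
the part of the map the validation actually supports. The last line scores
the run against the generator's recorded truth: 79% of smoothed locations
got the correct behaviour label, and the predicted foraging suitability
ranks cells in good agreement with the planted surface (Spearman 0.59 —
the depth-band structure is recovered cleanly; rank agreement over the
flat deep-basin cells, where the planted truth varies only through a
weakly identified thermal gradient, is the limiting term; see
`docs/methods.md`).

The staged version of the same analysis lives in `analysis/01_simulate.py`
… `analysis/08_report.py`; each script is idempotent (hash-checked
manifest) and writes its artefacts under `results/`.

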