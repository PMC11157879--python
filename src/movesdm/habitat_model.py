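"""Stage 4: gradient-boosted use-availability habitat model.

One Bernoulli (logistic-deviance) boosted-tree model per region x behaviour,
trained on presence (1) vs pseudo-absence (0) rows. The learner is
scikit-learn's GradientBoostingClassifier; this module owns the design
around it: stratified 75/25 splitting, grid tuning by cross-validated mean
squared error, global AUC / Kappa / Spearman evaluation, iterative dropping
of low-influence covariates until the model clears a global-AUC floor,
relative-influence normalisation, gridded prediction, prevalence-matched
thresholding, and partial-dependence curves.

The model output in [0, 1] is a relative probability of occurrence
(habitat suitability), not an absolute occupancy probability: the 5:1
pseudo-absence ratio fixes the base rate by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .env_matching import ModelDataset, PredictionGrid
from .io_formats import EnvLayer

log = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class GBMConfig:
    """Boosted-tree hyper-parameters (gbm-style naming)."""

    interaction_depth: int = 3
    n_trees: int = 500
    min_node: int = 10
    shrinkage: float = 0.1
    bag_fraction: float = 0.75

    def __post_init__(self):
        if min(self.interaction_depth, self.n_trees, self.min_node) <= 0:
            raise ValueError("all config fields must be positive")
        if not (0 < self.shrinkage <= 1 and 0 < self.bag_fraction <= 1):
            raise ValueError("shrinkage and bag_fraction must be in (0, 1]")

    def make_learner(self, seed: int) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            loss="log_loss", n_estimators=self.n_trees,
            max_depth=self.interaction_depth, min_samples_leaf=self.min_node,
            learning_rate=self.shrinkage, subsample=self.bag_fraction,
            random_state=seed)


#: default tuning grid (the full factorial is configurable by the caller)
DEFAULT_GRID = [GBMConfig(d, t, m, s, b)
                for d, t, m, s, b in product((2, 3, 5), (100, 500, 1000),
                                             (5, 10), (0.01, 0.1), (0.5, 0.75))]


@dataclass
class FittedModel:
    config: GBMConfig
    learner: GradientBoostingClassifier
    covariates: list[str]
    relative_influence: dict[str, float]
    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.learner.predict_proba(X)[:, 1]


def auc_score(scores, labels) -> float:
    """AUC as pairwise concordance via the rank (Mann-Whitney) formulation.

    Ties in score count 1/2. Equals the brute-force mean over all
    presence x absence pairs of 1[s_p > s_a] + 0.5 * 1[s_p == s_a].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise EvaluationError("AUC needs both classes")
    r = rankdata(scores)
    u = float(r[labels == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def kappa_score(scores, labels, threshold: float) -> float:
    """Cohen's Kappa of (score >= threshold) against the 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    n = len(labels)
    po = float(np.mean(pred == labels))
    p1, q1 = float(labels.mean()), float(pred.mean())
    pe = p1 * q1 + (1 - p1) * (1 - q1)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def prevalence_threshold(scores, labels) -> float:
    """Threshold at which predicted prevalence matches observed prevalence.

    Scans the attainable thresholds (the score values themselves) and
    returns the one minimising |mean(score >= t) - mean(label)|, preferring
    the larger (more conservative) threshold on ties. This is the
    (1 - prevalence)-quantile of the score distribution.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise EvaluationError("labels contain a single class")
    if np.ptp(scores) == 0:
        raise EvaluationError("constant predictions: threshold undefined")
    p_obs = labels.mean()
    cands = np.unique(scores)
    prev = (scores[None, :] >= cands[:, None]).mean(axis=1)
    err = np.abs(prev - p_obs)
    best = np.nonzero(err == err.min())[0].max()
    t = float(cands[best])
    return min(max(t, 1e-9), 1.0 - 1e-9)


def split_train_test(data: ModelDataset | pd.DataFrame, test_fraction: float = 0.25,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split into train/test row positions."""
    frame = data.complete_cases() if isinstance(data, ModelDataset) else data
    n = len(frame)
    if n < 20:
        raise EvaluationError("need >= 20 rows to split")
    if not (0 < test_fraction < 1):
        raise EvaluationError("test_fraction must be in (0, 1)")
    y = frame["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes required for a stratified split")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(y):
        pos = np.nonzero(y == cls)[0]
        k = int(round(test_fraction * len(pos)))
        k = min(max(k, 1), len(pos) - 1)
        test_idx.append(rng.choice(pos, size=k, replace=False))
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def tune(frame: pd.DataFrame, covariates: list[str],
         grid: list[GBMConfig] | None = None, cv_folds: int = 5,
         seed: int = 0, max_rows: int = 8000) -> tuple[GBMConfig, pd.DataFrame]:
    """Grid tuning by k-fold cross-validated MSE of predicted probability.

    Every configuration in the grid is evaluated; the argmin is returned
    with ties broken by fewer trees, then smaller depth. Also returns the
    full evaluation log. Datasets beyond ``max_rows`` are tuned on a
    stratified random subsample (the final fit still uses all rows).
    """
    if not grid:
        raise EvaluationError("empty tuning grid")
    if len(frame) > max_rows:
        rng = np.random.default_rng(seed)
        parts = [g.sample(n=max(1, int(round(max_rows * len(g) / len(frame)))),
                          random_state=int(rng.integers(2**31 - 1)))
                 for _, g in frame.groupby("label")]
        frame = pd.concat(parts)
    X = frame[covariates].to_numpy(dtype=float)
    y = frame["label"].to_numpy().astype(int)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + 1)
            folds = list(skf.split(X, y))
            for tr2, te2 in folds:
                if len(np.unique(y[tr2])) < 2 or len(np.unique(y[te2])) < 2:
                    raise EvaluationError("single-class CV fold after reshuffle")
            break
    records = []
    for cfg in grid:
        mses = []
        for tr, te in folds:
            learner = cfg.make_learner(seed)
            learner.fit(X[tr], y[tr])
            p = learner.predict_proba(X[te])[:, 1]
            mses.append(float(np.mean((p - y[te]) ** 2)))
        records.append({"config": cfg, "cv_mse": float(np.mean(mses))})
    tab = pd.DataFrame(records)
    tab = tab.sort_values(
        by="cv_mse", kind="stable",
        key=lambda s: s).reset_index(drop=True)
    best_mse = tab["cv_mse"].min()
    cands = [r["config"] for _, r in tab.iterrows() if r["cv_mse"] == best_mse]
    best = sorted(cands, key=lambda c: (c.n_trees, c.interaction_depth))[0]
    return best, tab


def _cv_mse(frame: pd.DataFrame, covariates: list[str], config: GBMConfig,
            seed: int, cv_folds: int, max_rows: int) -> tuple[float, float]:
    if len(frame) > max_rows:
        parts = [g.sample(n=max(1, int(round(max_rows * len(g) / len(frame)))),
                          random_state=seed) for _, g in frame.groupby("label")]
        frame = pd.concat(parts)
    X = frame[covariates].to_numpy(dtype=float)
    y = frame["label"].to_numpy().astype(int)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mses = []
    for tr, te in skf.split(X, y):
        learner = config.make_learner(seed)
        learner.fit(X[tr], y[tr])
        mses.append(float(np.mean((learner.predict_proba(X[te])[:, 1] - y[te]) ** 2)))
    return float(np.mean(mses)), float(np.std(mses) / np.sqrt(cv_folds))


def simplify_covariates(frame: pd.DataFrame, covariates: list[str],
                        config: GBMConfig, seed: int = 0, cv_folds: int = 5,
                        max_rows: int = 8000, min_covariates: int = 2):
    """Backward elimination of low-influence covariates (BRT simplification).

    Repeatedly proposes dropping the current model's lowest-influence
    covariate and accepts the drop while the cross-validated MSE does not
    worsen by more than one standard error — the standard boosted-tree
    model-simplification rule. Overfitted responses to incidental
    environmental variation discriminate in-sample but add no predictive
    value, so they are removed before spatial prediction. Returns
    (kept covariates, elimination trail).
    """
    covs = list(covariates)
    trail = []
    mse, se = _cv_mse(frame, covs, config, seed, cv_folds, max_rows)
    while len(covs) > min_covariates:
        model = fit(frame, covs, config, seed)
        worst = min(covs, key=lambda c: model.relative_influence[c])
        cand = [c for c in covs if c != worst]
        mse_c, se_c = _cv_mse(frame, cand, config, seed, cv_folds, max_rows)
        trail.append({"dropped": worst, "cv_mse_before": mse,
                      "cv_mse_after": mse_c, "accepted": mse_c <= mse + se})
        if mse_c <= mse + se:
            covs, mse, se = cand, mse_c, se_c
        else:
            break
    return covs, trail


def fit(frame: pd.DataFrame, covariates: list[str], config: GBMConfig,
        seed: int = 0, train_ids: np.ndarray | None = None,
        test_ids: np.ndarray | None = None) -> FittedModel:
    """Train the Bernoulli boosted-tree model and normalise influences to 100."""
    X = frame[covariates].to_numpy(dtype=float)
    y = frame["label"].to_numpy().astype(int)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariates in training data")
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes required")
    learner = config.make_learner(seed)
    learner.fit(X, y)
    imp = learner.feature_importances_
    total = imp.sum()
    ri = (imp / total * 100.0) if total > 0 else np.full(len(imp), 100.0 / len(imp))
    influence = dict(zip(covariates, ri.astype(float)))
    return FittedModel(config, learner, list(covariates), influence,
                       train_ids if train_ids is not None else np.arange(len(frame)),
                       test_ids if test_ids is not None else np.array([], int),
                       seed)


def evaluate(model: FittedModel, test_frame: pd.DataFrame,
             threshold: float | None = None) -> dict:
    """Global accuracy metrics on a held-out set.

    AUC by pairwise concordance, Kappa at the prevalence-matched threshold
    (computed on the test scores unless one is supplied), and the Spearman
    rank correlation between predictions and labels. Flags follow the
    conventional floors: AUC > 0.6, Spearman > 0.5.
    """
    y = test_frame["label"].to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("single-class test set")
    p = model.predict(test_frame[model.covariates])
    t = prevalence_threshold(p, y) if threshold is None else threshold
    auc = auc_score(p, y)
    kap = kappa_score(p, y, t)
    rho = float(spearmanr(p, y).statistic)
    return {"global_auc": auc, "global_kappa": kap, "spearman": rho,
            "threshold": t, "auc_ok": auc > 0.6, "spearman_ok": rho > 0.5}


def iterative_variable_refit(frame: pd.DataFrame, covariates: list[str],
                             config: GBMConfig, min_auc: float = 0.6,
                             test_fraction: float = 0.25, seed: int = 0,
                             min_covariates: int = 2):
    """Fit, evaluate, and drop the lowest-influence covariate until the
    model clears the global-AUC floor (or hits the covariate floor).

    Returns (final FittedModel, metrics dict, audit trail). A model that
    exhausts the covariate floor without passing is released flagged.
    """
    if len(covariates) < 2:
        raise EvaluationError("need >= 2 covariates")
    train, test = split_train_test(frame, test_fraction, seed)
    covs = list(covariates)
    audit = []
    while True:
        model = fit(frame.iloc[train], covs, config, seed, train, test)
        metrics = evaluate(model, frame.iloc[test])
        audit.append({"covariates": list(covs), "metrics": dict(metrics)})
        if metrics["global_auc"] > min_auc:
            return model, metrics, audit
        if len(covs) <= min_covariates:
            log.warning("variable refit hit the floor without AUC > %.2f", min_auc)
            metrics["flagged"] = True
            return model, metrics, audit
        worst = min(covs, key=lambda c: model.relative_influence[c])
        covs.remove(worst)
        log.info("iterative_variable_refit: dropped %s", worst)


def predict_surface(model: FittedModel, grid: PredictionGrid,
                    covariate_ranges: dict[str, tuple[float, float]] | None = None
                    ) -> EnvLayer:
    """Per-cell suitability in [0, 1]; cells missing any covariate masked.

    The month covariate, if the model uses one, is filled with the grid
    period's mid-month. When ``covariate_ranges`` (typically the training
    data's min/max per covariate) is given, cells whose covariates fall
    outside those ranges are masked as well: tree ensembles extrapolate as
    arbitrary constant leaves outside the support of the training data, and
    such cells would otherwise carry spurious suitability.
    """
    gs = grid.transform
    cols = []
    mid_month = (grid.period[0] + (grid.period[1] - grid.period[0]) / 2).month
    for name in model.covariates:
        if name == "month":
            cols.append(np.full(gs.nrow * gs.ncol, float(mid_month)))
            continue
        if name not in grid.layers:
            raise KeyError(f"prediction grid lacks covariate {name!r}")
        cols.append(grid.layers[name].grid.ravel())
    X = np.stack(cols, axis=1)
    ok = np.isfinite(X).all(axis=1)
    if covariate_ranges:
        for j, name in enumerate(model.covariates):
            if name in covariate_ranges:
                lo, hi = covariate_ranges[name]
                ok &= (X[:, j] >= lo) & (X[:, j] <= hi)
    out = np.full(gs.nrow * gs.ncol, np.nan)
    if ok.any():
        out[ok] = model.learner.predict_proba(X[ok])[:, 1]
    ref = next(iter(grid.layers.values()))
    layer = EnvLayer("suitability", out.reshape(gs.nrow, gs.ncol), gs,
                     crs=ref.crs, time_window=grid.period, units="probability")
    return layer


def apply_threshold(continuous: EnvLayer, t: float) -> EnvLayer:
    """Binary suitable/unsuitable map at threshold ``t`` (masked cells stay masked)."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    g = continuous.grid
    binary = np.where(np.isfinite(g), (g >= t).astype(float), np.nan)
    out = continuous.with_grid(binary, name="suitable")
    out.units = "binary"
    return out


def partial_dependence(model: FittedModel, frame: pd.DataFrame,
                       covariate: str, values: np.ndarray) -> np.ndarray:
    """Mean prediction with ``covariate`` clamped across ``values``."""
    if covariate not in model.covariates:
        raise KeyError(covariate)
    X = frame[model.covariates].to_numpy(dtype=float).copy()
    j = model.covariates.index(covariate)
    out = []
    for v in np.asarray(values, dtype=float):
        X[:, j] = v
        out.append(float(np.mean(model.learner.predict_proba(X)[:, 1])))
    return np.array(out)


@dataclass
class SuitabilityProduct:
    """Continuous suitability, its threshold, binary and validated maps."""

    continuous: EnvLayer
    threshold: float
    binary: EnvLayer
    validated: EnvLayer | None = None
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        b = self.binary.grid
        c = self.continuous.grid
        ok = np.isfinite(b) & np.isfinite(c)
        if not np.array_equal(b[ok] == 1, c[ok] >= self.threshold):
            raise ValueError("binary map inconsistent with threshold")
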