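"""Ensemble species-distribution modelling.

Variable pruning by pairwise Pearson correlation, landscape-heterogeneity
estimation via PCA, spatial rarefaction of occurrences, pseudo-absence
sampling, a multi-algorithm ensemble evaluated by AUC and the true skill
statistic (TSS) on repeated 75/25 splits, lowest-presence-threshold (LPT)
binarization, and range-shift accounting between scenarios.

Algorithms are scikit-learn classifiers behind a small registry; the
default roster is five (logistic GLM, random forest, gradient boosting,
classification tree, discriminant analysis) with a neural net and a
surface range envelope available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .geo import OccurrenceSet, haversine_km
from .raster import GridSpec, RasterStack, SuitabilityMap, cell_area_km2

__all__ = [
    "ModelEvaluation",
    "EnsembleConfig",
    "RangeShift",
    "prune_correlated_variables",
    "heterogeneity_surface",
    "rarefy_occurrences",
    "sample_pseudo_absences",
    "fit_ensemble",
    "tss",
    "ensemble_predict",
    "lpt_threshold",
    "binarize",
    "range_shift",
    "variable_importance",
]


@dataclass
class ModelEvaluation:
    """Held-out evaluation of one algorithm x repeat."""

    algorithm: str
    repeat: int
    auc: float
    tss: float
    retained: bool


@dataclass
class FittedModel:
    algorithm: str
    repeat: int
    estimator: object
    mean: np.ndarray
    sd: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.sd
        return self.estimator.predict_proba(Z)[:, 1]


class _RangeEnvelope:
    """Surface range envelope: presence iff every predictor falls inside
    the central quantile range of the training presences."""

    def __init__(self, quantile: float = 0.025):
        self.quantile = quantile

    def fit(self, X, y):
        P = X[np.asarray(y) == 1]
        self.lo_ = np.quantile(P, self.quantile, axis=0)
        self.hi_ = np.quantile(P, 1 - self.quantile, axis=0)
        return self

    def predict_proba(self, X):
        inside = np.all((X >= self.lo_) & (X <= self.hi_), axis=1).astype(float)
        return np.column_stack([1 - inside, inside])


def _make_estimator(name: str, seed: int):
    if name == "glm":
        return LogisticRegression(max_iter=1000)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "gbm":
        return GradientBoostingClassifier(random_state=seed)
    if name == "cta":
        return DecisionTreeClassifier(random_state=seed, min_samples_leaf=5)
    if name == "fda":
        return LinearDiscriminantAnalysis()
    if name == "ann":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=2000, random_state=seed)
    if name == "sre":
        return _RangeEnvelope()
    raise ValueError(f"unknown algorithm {name!r}")


@dataclass
class EnsembleConfig:
    algorithms: tuple[str, ...] = ("glm", "rf", "gbm", "cta", "fda")
    n_repeats: int = 10
    train_fraction: float = 0.75
    gate: float = 0.6  # retained iff AUC > gate and TSS > gate
    seed: int = 0
    tss_weighted: bool = False

    def __post_init__(self) -> None:
        if len(self.algorithms) < 1:
            raise ValueError("empty algorithm roster")


@dataclass
class RangeShift:
    """Per-cell range-change categories and cos(latitude)-weighted areas."""

    categories: np.ndarray  # str grid: expansion|contraction|stable|absent
    area_km2: dict[str, float]
    current_area_km2: float
    future_area_km2: float
    percent_change: float


# ---------------------------------------------------------------------------
# variable pruning & heterogeneity


def prune_correlated_variables(stack: RasterStack, r_max: float = 0.75
                               ) -> tuple[RasterStack, list[str]]:
    """Greedily drop layers until all pairwise |Pearson r| <= r_max.

    At each step the layer with the highest mean absolute correlation
    among the offending pairs is removed (ties broken by layer-name
    order). Returns the pruned stack and the retained layer names.
    """
    names = stack.names
    if len(names) < 2:
        warnings.warn("single layer: nothing to prune")
        return stack, names
    _, _, X = stack.table()
    with np.errstate(invalid="ignore"):
        R = np.abs(np.corrcoef(X, rowvar=False))
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    keep = list(range(len(names)))
    while True:
        sub = R[np.ix_(keep, keep)]
        offend = sub > r_max
        if not offend.any():
            break
        mean_off = np.where(offend, sub, 0).sum(axis=1) / np.maximum(
            offend.sum(axis=1), 1
        )
        mean_off[offend.sum(axis=1) == 0] = -1
        worst = int(np.argmax(mean_off))  # argmax keeps first on ties = name order
        keep.pop(worst)
    kept_names = [names[i] for i in keep]
    return stack.subset(kept_names), kept_names


def heterogeneity_surface(stack: RasterStack, window: int = 5) -> np.ndarray:
    """Climatic-heterogeneity grid: moving-window standard deviation of
    the first principal component of the standardized layers."""
    rows, cols, X = stack.table()
    sd = X.std(axis=0)
    if np.all(sd < 1e-12):
        warnings.warn("all layers constant: zero heterogeneity surface")
        return np.zeros(stack.grid.shape)
    Z = (X - X.mean(axis=0)) / np.where(sd > 1e-12, sd, 1.0)
    # PC1 scores via SVD of the standardized cell x layer matrix
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc1 = np.full(stack.grid.shape, np.nan)
    pc1[rows, cols] = Z @ vt[0]
    return _window_sd(pc1, window)


def _window_sd(grid: np.ndarray, window: int) -> np.ndarray:
    """Masked moving-window standard deviation (NaN-aware)."""
    valid = np.isfinite(grid).astype(float)
    filled = np.where(np.isfinite(grid), grid, 0.0)
    size = (window, window)
    n = ndimage.uniform_filter(valid, size=size, mode="constant") * window**2
    s1 = ndimage.uniform_filter(filled, size=size, mode="constant") * window**2
    s2 = ndimage.uniform_filter(filled**2, size=size, mode="constant") * window**2
    with np.errstate(invalid="ignore", divide="ignore"):
        var = s2 / n - (s1 / n) ** 2
    out = np.sqrt(np.clip(var, 0, None))
    out[~np.isfinite(grid)] = np.nan
    return out


# ---------------------------------------------------------------------------
# occurrences


def rarefy_occurrences(points: OccurrenceSet, min_dist_km: float) -> OccurrenceSet:
    """Greedy spatial rarefaction in input order: keep a point iff it is
    at least ``min_dist_km`` (great-circle) from every point already
    kept. Deterministic."""
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    if len(points) == 0:
        return OccurrenceSet(np.array([]), np.array([]), points.provenance)
    keep_lon: list[float] = []
    keep_lat: list[float] = []
    for lon, lat in zip(points.lons, points.lats):
        if not keep_lon:
            keep_lon.append(lon)
            keep_lat.append(lat)
            continue
        d = haversine_km(np.array(keep_lon), np.array(keep_lat), lon, lat)
        if np.all(d >= min_dist_km):
            keep_lon.append(lon)
            keep_lat.append(lat)
    return OccurrenceSet(
        np.array(keep_lon), np.array(keep_lat), points.provenance + "+rarefied"
    )


def sample_pseudo_absences(stack: RasterStack, presences: OccurrenceSet,
                           n_pa: int, seed: int, buffer_cells: int = 0
                           ) -> OccurrenceSet:
    """Random pseudo-absence cells: unmasked, not a presence cell, and
    outside a Chebyshev buffer of ``buffer_cells`` around presences."""
    if n_pa < 1:
        raise ValueError("n_pa must be >= 1")
    grid = stack.grid
    eligible = stack.mask.copy()
    pres = np.zeros(grid.shape, dtype=bool)
    for lon, lat in zip(presences.lons, presences.lats):
        r, c = grid.cell_of(lon, lat)
        pres[r, c] = True
    if buffer_cells > 0:
        size = 2 * buffer_cells + 1
        pres = ndimage.maximum_filter(pres.astype(int), size=size).astype(bool)
    eligible &= ~pres
    rows, cols = np.nonzero(eligible)
    if len(rows) < n_pa:
        raise ValueError(
            f"only {len(rows)} eligible cells for {n_pa} pseudo-absences"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n_pa, replace=False)
    lons, lats = zip(*(grid.center_of(int(rows[i]), int(cols[i])) for i in idx))
    return OccurrenceSet(np.array(lons), np.array(lats), "pseudo-absence")


# ---------------------------------------------------------------------------
# ensemble fitting and evaluation


def tss(tp: int, fn: int, tn: int, fp: int) -> float:
    """True skill statistic = sensitivity + specificity - 1."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TSS undefined: a class margin is zero")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def _max_tss(y_true: np.ndarray, scores: np.ndarray) -> float:
    """TSS at the ROC-optimal cutoff (max over thresholds of TPR-FPR)."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(np.max(tpr - fpr))


def fit_ensemble(presences: OccurrenceSet, absences: OccurrenceSet,
                 stack: RasterStack, config: EnsembleConfig = EnsembleConfig()
                 ) -> tuple[list[FittedModel], list[ModelEvaluation]]:
    """Train each algorithm on repeated stratified 75/25 splits of the
    presence/pseudo-absence data and evaluate AUC and TSS on the held-out
    quarter; a model is retained iff both exceed the gate (default 0.6)."""
    if len(presences) < 10:
        raise ValueError("fewer than 10 presences")
    Xp = stack.values_at_points(presences.lons, presences.lats)
    Xa = stack.values_at_points(absences.lons, absences.lats)
    X = np.vstack([Xp, Xa])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xa))])
    mean = X.mean(axis=0)
    sd = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
    Z = (X - mean) / sd
    models: list[FittedModel] = []
    evals: list[ModelEvaluation] = []
    for rep in range(config.n_repeats):
        split_seed = (config.seed * 10_000 + rep) % (2**31)
        for attempt in range(10):
            Zt, Zv, yt, yv = train_test_split(
                Z, y, train_size=config.train_fraction,
                random_state=split_seed + attempt, stratify=y,
            )
            if len(np.unique(yt)) == 2 and len(np.unique(yv)) == 2:
                break
        else:
            raise RuntimeError("could not obtain a two-class split")
        for name in config.algorithms:
            est = _make_estimator(name, split_seed)
            est.fit(Zt, yt)
            scores = est.predict_proba(Zv)[:, 1]
            auc = float(roc_auc_score(yv, scores))
            t = _max_tss(yv, scores)
            retained = auc > config.gate and t > config.gate
            models.append(FittedModel(name, rep, est, mean, sd))
            evals.append(ModelEvaluation(name, rep, auc, t, retained))
    return models, evals


def ensemble_predict(models: list[FittedModel], evals: list[ModelEvaluation],
                     stack: RasterStack, scenario: str = "current",
                     tss_weighted: bool = False) -> SuitabilityMap:
    """Mean (optionally TSS-weighted) suitability of the retained models."""
    retained = [(m, e) for m, e in zip(models, evals) if e.retained]
    if not retained:
        raise ValueError("no models passed the AUC/TSS retention gate")
    rows, cols, X = stack.table()
    acc = np.zeros(len(rows))
    wsum = 0.0
    for m, e in retained:
        w = max(e.tss, 0.0) if tss_weighted else 1.0
        acc += w * m.predict_proba(X)
        wsum += w
    suit = np.full(stack.grid.shape, np.nan)
    suit[rows, cols] = np.clip(acc / wsum, 0, 1)
    return SuitabilityMap(stack.grid, suit, scenario=scenario)


def lpt_threshold(suit: SuitabilityMap, presences: OccurrenceSet) -> float:
    """Lowest presence threshold: the minimum predicted suitability over
    the presence cells."""
    if len(presences) == 0:
        raise ValueError("empty presence set")
    vals = [suit.value_at(lon, lat) for lon, lat in zip(presences.lons, presences.lats)]
    if not np.all(np.isfinite(vals)):
        raise ValueError("a presence falls on a nodata cell")
    return float(np.min(vals))


def binarize(suit: SuitabilityMap, threshold: float) -> SuitabilityMap:
    """Presence/absence map: cell present iff suitability >= threshold
    (closed at the threshold so LPT keeps every training presence)."""
    binary = np.where(suit.mask, suit.values >= threshold, False)
    return SuitabilityMap(
        suit.grid, suit.values, suit.scenario, binary=binary, lpt=threshold
    )


def range_shift(current: SuitabilityMap, future: SuitabilityMap) -> RangeShift:
    """Expansion / contraction / stable / absent accounting between two
    binarized maps, with areas in km² (spherical cos-latitude weights)
    and percent change relative to the current presence area."""
    if current.grid != future.grid:
        raise ValueError("current and future grids differ")
    if current.binary is None or future.binary is None:
        raise ValueError("binarize both maps before range_shift")
    cur, fut = current.binary, future.binary
    cats = np.full(cur.shape, "absent", dtype=object)
    cats[cur & fut] = "stable"
    cats[~cur & fut] = "expansion"
    cats[cur & ~fut] = "contraction"
    areas = cell_area_km2(current.grid)
    area = {
        cat: float(areas[cats == cat].sum())
        for cat in ("expansion", "contraction", "stable", "absent")
    }
    cur_area = area["contraction"] + area["stable"]
    fut_area = area["expansion"] + area["stable"]
    pct = (fut_area - cur_area) / cur_area * 100.0 if cur_area > 0 else np.nan
    return RangeShift(cats, area, cur_area, fut_area, pct)


def variable_importance(model: FittedModel, stack: RasterStack, seed: int = 0,
                        n_shuffles: int = 3) -> dict[str, float]:
    """Permutation importance: 1 - Pearson r between predictions on the
    intact stack and on a stack with one variable's cells shuffled,
    averaged over ``n_shuffles``."""
    rng = np.random.default_rng(seed)
    _, _, X = stack.table()
    base = model.predict_proba(X)
    if base.std() < 1e-12:
        warnings.warn("constant predictions: all importances zero")
        return {n: 0.0 for n in stack.names}
    out = {}
    for j, name in enumerate(stack.names):
        scores = []
        for _ in range(n_shuffles):
            Xs = X.copy()
            Xs[:, j] = rng.permutation(Xs[:, j])
            pred = model.predict_proba(Xs)
            if pred.std() < 1e-12:
                scores.append(1.0)
            else:
                scores.append(1.0 - np.corrcoef(base, pred)[0, 1])
        out[name] = float(np.mean(scores))
    return out
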