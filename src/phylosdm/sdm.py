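"""Ensemble species-distribution modeling.

The engine mirrors the classic biomod2-style design: pseudo-absence sets
are drawn from the background, four learner families (GLM, GAM, GBM, RF)
are fitted over a grid of pseudo-absence replicates x cross-validation
runs, each member is scored on its held-out split with AUC and the True
Skill Statistic (TSS), and the members are mixed by Committee Averaging
(fraction of binary votes after per-member max-TSS thresholding) and by an
AUC-weighted mean of the continuous scores.  Habitat suitability maps are
then cut into discrete levels with exact Fisher-Jenks natural breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .rasters import RasterLayer, RasterStack

__all__ = [
    "ModelRun", "EnsembleResult", "SuitabilityClassification",
    "gen_pseudo_absences", "auc_score", "tss_score", "best_threshold",
    "fit_model_grid", "predict_map", "member_scores", "ensemble_ca",
    "ensemble_wm", "evaluate_ensemble", "member_stats",
    "variable_importance", "jenks_breaks", "classify_suitability",
]

ALGORITHMS = ("GLM", "GAM", "GBM", "RF")

#: Fixed learner defaults (documented in docs/methods.md).
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "GLM": {},
    "GAM": {"df": 5, "degree": 3},
    "GBM": {"n_estimators": 2500, "max_depth": 3, "learning_rate": 0.01},
    "RF": {"n_estimators": 500},
}

# QC rule: a member "performs well" above these marks.
QC_AUC = 0.8
QC_TSS = 0.7


# -- evaluation metrics -----------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC: probability a random presence outscores a random absence,
    ties counting one half (Mann-Whitney formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def tss_score(tp: int, fp: int, tn: int, fn: int) -> float:
    """True Skill Statistic: sensitivity + specificity - 1."""
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("each class needs at least one observation")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def _tss_curve(scores: np.ndarray, labels: np.ndarray,
               thresholds: np.ndarray) -> np.ndarray:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)
    return sens + spec - 1.0


def best_threshold(scores: Sequence[float],
                   labels: Sequence[int]) -> tuple[float, float]:
    """Binarization threshold maximizing TSS.

    Candidates are the midpoints of consecutive sorted unique scores
    (prediction is positive at score >= threshold); ties go to the lowest
    candidate.  With a single unique score the candidate is that score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        cands = uniq
    else:
        cands = (uniq[:-1] + uniq[1:]) / 2.0
    tss = _tss_curve(scores, labels, cands)
    i = int(np.argmax(tss))  # argmax takes the first (lowest) maximizer
    return float(cands[i]), float(tss[i])


# -- pseudo-absences --------------------------------------------------------

def gen_pseudo_absences(stack: RasterStack, presences: np.ndarray,
                        n: int = 500, n_sets: int = 3,
                        seed: int = 0) -> list[np.ndarray]:
    """Draw *n_sets* independent sets of *n* background points, uniform
    over valid cells not occupied by a presence; points sit at cell
    centers, one cell at most once per set."""
    template = stack.template
    valid = stack.joint_valid_mask.copy()
    nr, nc = template.shape
    for x, y in np.atleast_2d(presences):
        try:
            r, c = template.cell_of(x, y)
        except IndexError:
            continue
        valid[r, c] = False
    avail = np.flatnonzero(valid.ravel())
    if len(avail) < n:
        raise ValueError(f"only {len(avail)} candidate background cells "
                         f"for {n} pseudo-absences")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        flat = rng.choice(avail, size=n, replace=False)
        rows, cols = np.divmod(flat, nc)
        pts = np.array([template.cell_center(r, c)
                        for r, c in zip(rows, cols)])
        sets.append(pts)
    return sets


# -- learners ---------------------------------------------------------------

class _GamClassifier:
    """Binomial GAM with per-feature B-spline smooths (statsmodels)."""

    def __init__(self, df: int = 5, degree: int = 3):
        self.df = df
        self.degree = degree

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GamClassifier":
        import statsmodels.api as sm
        from statsmodels.gam.api import BSplines, GLMGam
        X = np.asarray(X, dtype=float)
        p = X.shape[1]
        # spline bases cannot extrapolate: hold new data at the training
        # range boundaries
        self._lo = X.min(axis=0)
        self._hi = X.max(axis=0)
        self._smoother = BSplines(X, df=[self.df] * p,
                                  degree=[self.degree] * p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = GLMGam(np.asarray(y, dtype=float),
                           smoother=self._smoother,
                           family=sm.families.Binomial())
            self._res = model.fit()
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.clip(np.asarray(X, dtype=float), self._lo, self._hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mu = self._res.predict(exog_smooth=X)
        return np.clip(np.asarray(mu, dtype=float), 0.0, 1.0)


class _SklearnScore:
    """Adapter exposing predict_score() over predict_proba."""

    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.est.fit(X, y)
        return self

    def predict_score(self, X):
        return self.est.predict_proba(X)[:, 1]


def _make_learner(algorithm: str, hp: dict, seed: int):
    if algorithm == "GLM":
        return _SklearnScore(make_pipeline(
            StandardScaler(),
            LogisticRegression(penalty=None, max_iter=2000, **hp)))
    if algorithm == "GAM":
        return _GamClassifier(**hp)
    if algorithm == "GBM":
        return _SklearnScore(GradientBoostingClassifier(
            random_state=seed, **{**DEFAULT_HYPERPARAMS["GBM"], **hp}))
    if algorithm == "RF":
        return _SklearnScore(RandomForestClassifier(
            random_state=seed, n_jobs=1,
            **{**DEFAULT_HYPERPARAMS["RF"], **hp}))
    raise ValueError(f"unknown algorithm {algorithm!r}")


# -- the model grid ---------------------------------------------------------

@dataclass
class ModelRun:
    """One fitted member: (algorithm, pseudo-absence replicate, CV run)."""
    algorithm: str
    pa_replicate: int        # 1-based
    cv_run: int              # 1-based
    predictor: Callable[[np.ndarray], np.ndarray] | None
    auc: float = np.nan
    tss: float = np.nan
    threshold: float = np.nan
    ok: bool = False
    error: str = ""

    @property
    def passes_qc(self) -> bool:
        return bool(self.ok and self.auc > QC_AUC and self.tss >= QC_TSS)


def fit_model_grid(stack: RasterStack, presences: np.ndarray,
                   pa_sets: list[np.ndarray],
                   algorithms: Sequence[str] = ALGORITHMS,
                   cv_runs: int = 10, train_fraction: float = 0.75,
                   seed: int = 0,
                   hyperparams: dict[str, dict] | None = None
                   ) -> list[ModelRun]:
    """Fit the full member grid: one ModelRun per
    (algorithm x pseudo-absence set x cross-validation run).

    Every run splits the presences and its pseudo-absence set
    train_fraction / (1 - train_fraction), fits on the training portion
    and computes AUC, max-TSS threshold and TSS on the held-out portion.
    A failed fit is recorded (ok=False) but never aborts the grid, so the
    run count is always |algorithms| * |pa_sets| * cv_runs.
    """
    if len(presences) < 8:
        raise ValueError("need at least 8 presences")
    if not pa_sets:
        raise ValueError("need at least one pseudo-absence set")
    hp = {**{a: {} for a in ALGORITHMS}, **(hyperparams or {})}
    Xp = stack.features_at(presences)
    runs: list[ModelRun] = []
    ss = np.random.SeedSequence(seed)
    for pa_idx, pa_pts in enumerate(pa_sets, start=1):
        Xa = stack.features_at(pa_pts)
        for cv in range(1, cv_runs + 1):
            split_rng = np.random.default_rng(
                ss.spawn(1)[0].generate_state(1))
            p_tr = _train_mask(len(Xp), train_fraction, split_rng)
            a_tr = _train_mask(len(Xa), train_fraction, split_rng)
            X_tr = np.vstack([Xp[p_tr], Xa[a_tr]])
            y_tr = np.r_[np.ones(p_tr.sum()), np.zeros(a_tr.sum())]
            X_te = np.vstack([Xp[~p_tr], Xa[~a_tr]])
            y_te = np.r_[np.ones((~p_tr).sum()), np.zeros((~a_tr).sum())]
            for alg in algorithms:
                fit_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                run = ModelRun(alg, pa_idx, cv, predictor=None)
                try:
                    learner = _make_learner(alg, hp.get(alg, {}), fit_seed)
                    learner.fit(X_tr, y_tr)
                    scores = learner.predict_score(X_te)
                    run.auc = auc_score(scores, y_te)
                    run.threshold, run.tss = best_threshold(scores, y_te)
                    run.predictor = learner.predict_score
                    run.ok = True
                except Exception as exc:  # flagged, not fatal
                    run.error = f"{type(exc).__name__}: {exc}"
                runs.append(run)
    return runs


def _train_mask(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    n_tr = max(1, min(n - 1, int(round(frac * n))))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n_tr, replace=False)] = True
    return mask


# -- member prediction and ensembles ----------------------------------------

def predict_map(run: ModelRun, stack: RasterStack) -> RasterLayer:
    """Project one member over the valid cells of the stack."""
    if not run.ok:
        raise ValueError(f"cannot project failed run {run.algorithm} "
                         f"PA{run.pa_replicate} CV{run.cv_run}: {run.error}")
    X, idx = stack.feature_table()
    scores = run.predictor(X)
    template = stack.template
    vals = np.full(template.shape, np.nan).ravel()
    vals[idx] = scores
    mask = ~stack.joint_valid_mask
    return RasterLayer(f"{run.algorithm}_pa{run.pa_replicate}_cv{run.cv_run}",
                       vals.reshape(template.shape), template.transform,
                       mask, template.crs_tag)


def member_scores(runs: list[ModelRun],
                  stack: RasterStack) -> tuple[list[ModelRun], np.ndarray, np.ndarray]:
    """Score matrix of the usable members over valid cells.

    Returns (usable_runs, scores (n_members, n_valid), valid flat index)."""
    usable = [r for r in runs if r.ok]
    if not usable:
        raise ValueError("no usable model runs")
    X, idx = stack.feature_table()
    S = np.vstack([r.predictor(X) for r in usable])
    return usable, S, idx


def _scores_to_layer(values: np.ndarray, idx: np.ndarray,
                     stack: RasterStack, name: str) -> RasterLayer:
    template = stack.template
    flat = np.full(template.shape, np.nan).ravel()
    flat[idx] = values
    return RasterLayer(name, flat.reshape(template.shape),
                       template.transform, ~stack.joint_valid_mask,
                       template.crs_tag)


def ensemble_ca(runs: list[ModelRun], stack: RasterStack,
                precomputed=None) -> RasterLayer:
    """Committee Averaging: per cell, the fraction of members voting
    presence after binarizing each member at its own max-TSS threshold."""
    usable, S, idx = precomputed or member_scores(runs, stack)
    thresholds = np.array([r.threshold for r in usable])
    votes = (S >= thresholds[:, None]).mean(axis=0)
    return _scores_to_layer(votes, idx, stack, "ensemble_ca")


def ensemble_wm(runs: list[ModelRun], stack: RasterStack,
                weight_metric: str = "auc", precomputed=None) -> RasterLayer:
    """Weighted Mean: per cell, the evaluation-metric-weighted mean of the
    member continuous scores (weights = member AUC by default)."""
    usable, S, idx = precomputed or member_scores(runs, stack)
    if weight_metric == "auc":
        w = np.array([r.auc for r in usable])
    elif weight_metric == "tss":
        w = np.array([r.tss for r in usable])
    else:
        raise ValueError(f"unknown weight metric {weight_metric!r}")
    if np.any(w <= 0):
        raise ValueError("ensemble weights must be positive")
    wm = (w[:, None] * S).sum(axis=0) / w.sum()
    return _scores_to_layer(wm, idx, stack, "ensemble_wm")


def evaluate_ensemble(map_layer: RasterLayer, presences: np.ndarray,
                      pa_points: np.ndarray) -> tuple[float, float]:
    """AUC and max-TSS of an ensemble map against presence / background
    points (map values extracted at the point cells)."""
    if len(presences) == 0 or len(pa_points) == 0:
        raise ValueError("both point sets must be non-empty")
    try:
        sp = map_layer.values_at(presences)
        sa = map_layer.values_at(pa_points)
    except IndexError as exc:
        raise ValueError(f"evaluation point outside the grid: {exc}") from exc
    scores = np.r_[sp, sa]
    labels = np.r_[np.ones(len(sp)), np.zeros(len(sa))]
    if len(np.unique(scores)) == 1:
        return 0.5, 0.0
    auc = auc_score(scores, labels)
    _, tss = best_threshold(scores, labels)
    return auc, tss


def member_stats(runs: list[ModelRun]) -> dict[str, float]:
    """Mean +/- sd of AUC and TSS over the usable members."""
    usable = [r for r in runs if r.ok]
    aucs = np.array([r.auc for r in usable])
    tsss = np.array([r.tss for r in usable])
    return {
        "n_members": len(runs),
        "n_usable": len(usable),
        "n_passes_qc": sum(r.passes_qc for r in usable),
        "auc_mean": float(aucs.mean()), "auc_sd": float(aucs.std(ddof=1)),
        "tss_mean": float(tsss.mean()), "tss_sd": float(tsss.std(ddof=1)),
    }


# -- permutation variable importance ----------------------------------------

def variable_importance(runs: ModelRun | list[ModelRun], stack: RasterStack,
                        n_perm: int = 3, seed: int = 0) -> dict[str, float]:
    """Permutation importance per variable.

    For one member: 1 - |Pearson r(original predictions, predictions with
    that variable's column shuffled)|, averaged over *n_perm* shuffles.
    For a list of members the per-member scores are averaged, giving the
    ensemble-level importance.  A variable the model ignores scores 0.
    """
    if isinstance(runs, ModelRun):
        runs = [runs]
    usable = [r for r in runs if r.ok]
    if not usable:
        raise ValueError("no usable model runs")
    X, _ = stack.feature_table()
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(X)) for _ in range(n_perm)]
    totals = {name: 0.0 for name in stack.names}
    for run in usable:
        base = run.predictor(X)
        base_sd = base.std()
        for j, name in enumerate(stack.names):
            if base_sd == 0:
                warnings.warn(f"constant predictions for {run.algorithm}; "
                              f"importance of {name} set to 0")
                continue
            acc = 0.0
            for perm in perms:
                Xp = X.copy()
                Xp[:, j] = X[perm, j]
                pred = run.predictor(Xp)
                if pred.std() == 0:
                    r = 0.0
                else:
                    r = np.corrcoef(base, pred)[0, 1]
                acc += 1.0 - abs(r)
            totals[name] += acc / n_perm
    return {name: total / len(usable) for name, total in totals.items()}


# -- Jenks natural breaks ---------------------------------------------------

def jenks_breaks(values: Sequence[float], k: int) -> list[float]:
    """Exact Fisher-Jenks natural breaks.

    Dynamic program over the sorted values minimizing the total
    within-class sum of squared deviations; O(k n^2).  Returns the k-1
    ascending cut values (the maximum of each of the first k-1 classes);
    class assignment uses half-open intervals (lower, upper].
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(x)) < k:
        raise ValueError(f"need at least {k} distinct values, "
                         f"got {len(np.unique(x))}")
    s1 = np.r_[0.0, np.cumsum(x)]
    s2 = np.r_[0.0, np.cumsum(x * x)]

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-class SSD of x[i:j] for an array of starts i
        cnt = j - i
        mean_term = (s1[j] - s1[i]) ** 2 / cnt
        return (s2[j] - s2[i]) - mean_term

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            starts = np.arange(m - 1, j)
            cand = cost[m - 1, starts] + seg_cost(starts, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            back[m, j] = starts[best]
    cuts = []
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        if m > 1:
            cuts.append(x[i - 1])  # upper value of the preceding class
        j = i
    return sorted(float(c) for c in cuts)


@dataclass
class SuitabilityClassification:
    """A 4-level (generally k-level) habitat suitability classification."""
    breaks: list[float]
    class_map: RasterLayer
    class_areas: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.breaks) + 1


def classify_suitability(map_layer: RasterLayer,
                         breaks: Sequence[float]) -> SuitabilityClassification:
    """Assign classes 1..k (1 = least suitable) by half-open intervals
    (lower, upper] and tabulate per-class area and percentage."""
    breaks = sorted(float(b) for b in breaks)
    if len(breaks) != len(set(breaks)):
        raise ValueError("breaks must be strictly ascending")
    valid = ~map_layer.nodata_mask
    classes = np.zeros(map_layer.shape, dtype=float)
    classes[valid] = 1 + np.digitize(map_layer.values[valid], breaks,
                                     right=True)
    classes[~valid] = np.nan
    cls_layer = RasterLayer("suitability_class", classes,
                            map_layer.transform, ~valid, map_layer.crs_tag)
    _, _, dx, dy = map_layer.transform
    cell_area = dx * dy
    total = valid.sum()
    areas = {}
    for c in range(1, len(breaks) + 2):
        cnt = int((classes[valid] == c).sum())
        areas[c] = (cnt * cell_area, 100.0 * cnt / total)
    return SuitabilityClassification(breaks=list(breaks),
                                     class_map=cls_layer, class_areas=areas)
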