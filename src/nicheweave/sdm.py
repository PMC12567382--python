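"""Per-taxon climate-suitability models: pseudo-absences, learners, ensemble.

The modelling protocol mirrors standard presence-only distribution
modelling: pseudo-absences are drawn uniformly over cells without a
presence record, one per presence record; records are split 70/30 into
training and test sets stratified by label; three learners of different
inductive bias (a smooth additive model, an adaptive hinge-basis model and
a kernel margin classifier, all mapping the 9 harmonic predictors to a
probability-scale score) are fitted; members passing a Cohen's-kappa floor
on the held-out test set are averaged with kappa-proportional weights; and
the continuous ensemble surface is binarized at the threshold maximizing
the true skill statistic (TSS = sensitivity + specificity - 1) on the test
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.svm import SVC

from .grids import PREDICTOR_LAYERS, EcosystemMap, GridGeometry, PredictorStack

LEARNER_NAMES = ("smooth_additive", "adaptive_hinge", "kernel_margin")


@dataclass
class LearnerSettings:
    """Learner hyper-parameters shared across members.

    ``max_iter`` and ``tol`` govern the iterative fits (500 iterations at
    tolerance 1e-8 by default); ``cv_folds`` is used for calibrating the
    margin learner's decision values to the probability scale.
    """

    max_iter: int = 500
    tol: float = 1e-8
    n_knots: int = 5
    hinge_quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
    cv_folds: int = 3
    C: float = 1.0


@dataclass
class ModelMetrics:
    """Confusion-matrix evaluation of one model at one threshold."""

    sensitivity: float
    specificity: float
    omission_rate: float
    proportion_correct: float
    kappa: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "omission_rate": self.omission_rate,
            "proportion_correct": self.proportion_correct,
            "kappa": self.kappa,
            "threshold": self.threshold,
        }


@dataclass
class SuitabilityMap:
    """Continuous ensemble suitability surface with member bookkeeping."""

    taxon_id: str
    geometry: GridGeometry
    values: np.ndarray  # (n_rows, n_cols) in [0, 1]; NaN on masked cells
    members: list[dict] = field(default_factory=list)  # name, weight, metrics


@dataclass
class BinaryMap:
    """Thresholded presence/absence surface."""

    taxon_id: str
    geometry: GridGeometry
    values: np.ndarray  # (n_rows, n_cols) of {0, 1}
    threshold: float
    rule: str = "max_tss"


# ---------------------------------------------------------------------------
# Labelled points
# ---------------------------------------------------------------------------


def _presence_cells(presences: pd.DataFrame, geometry: GridGeometry) -> np.ndarray:
    """Flat cell index for every occurrence record."""
    cells = np.empty(len(presences), dtype=int)
    for i, (lon, lat) in enumerate(zip(presences["lon"], presences["lat"])):
        row, col = geometry.cell_index(float(lon), float(lat))
        cells[i] = geometry.flat_index(row, col)
    return cells


def generate_pseudo_absences(
    presences: pd.DataFrame, predictors: PredictorStack, seed: int
) -> pd.DataFrame:
    """Labelled points: one uniform pseudo-absence cell per presence record.

    Pseudo-absence cells are drawn without replacement from valid cells that
    hold no presence record of the taxon, so no cell is both a presence and
    a pseudo-absence.  Returns a DataFrame with ``cell_id``, the nine
    predictor columns, ``label`` (1 presence / 0 pseudo-absence) and an
    unset ``partition`` column.
    """
    if len(presences) == 0:
        raise ValueError("need at least one presence record")
    geom = predictors.geometry
    presence_cells = _presence_cells(presences, geom)
    occupied = np.unique(presence_cells)
    valid = np.flatnonzero(~predictors.mask.reshape(-1))
    candidates = np.setdiff1d(valid, occupied, assume_unique=True)
    n = len(presences)
    if candidates.size < n:
        raise ValueError(
            f"only {candidates.size} candidate cells for {n} pseudo-absences"
        )
    rng = np.random.default_rng(seed)
    absence_cells = rng.choice(candidates, size=n, replace=False)
    flat = predictors.layers.reshape(9, -1).T
    cells = np.concatenate([presence_cells, absence_cells])
    labels = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    out = pd.DataFrame(flat[cells], columns=list(PREDICTOR_LAYERS))
    out.insert(0, "cell_id", cells)
    out["label"] = labels
    out["partition"] = pd.NA
    return out


def split_records(points: pd.DataFrame, train_fraction: float, seed: int) -> pd.DataFrame:
    """Stratified train/test split: round(train_fraction * n) per label."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    out = points.copy()
    out["partition"] = "test"
    for label, group in points.groupby("label"):
        if len(group) < 2:
            raise ValueError(f"label {label} has fewer than 2 records")
        n_train = int(np.clip(round(train_fraction * len(group)), 1, len(group) - 1))
        chosen = rng.choice(group.index.to_numpy(), size=n_train, replace=False)
        out.loc[chosen, "partition"] = "train"
    return out


def _xy(points: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = points[list(PREDICTOR_LAYERS)].to_numpy(dtype=float)
    y = points["label"].to_numpy(dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------


class _HingeFeatures:
    """Two-sided hinge basis max(x - t, 0), max(t - x, 0) at quantile knots."""

    def __init__(self, quantiles: tuple[float, ...]):
        self.quantiles = quantiles
        self.knots_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "_HingeFeatures":
        self.knots_ = np.quantile(X, self.quantiles, axis=0)  # (q, p)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        feats = [X]
        for knots in self.knots_:
            feats.append(np.maximum(X - knots, 0.0))
            feats.append(np.maximum(knots - X, 0.0))
        return np.concatenate(feats, axis=1)


@dataclass
class FittedLearner:
    """A fitted suitability function: 9-vector of predictors -> score in [0, 1]."""

    name: str
    _predict: callable

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.clip(self._predict(X), 0.0, 1.0)


def fit_learner(
    train: pd.DataFrame, learner: str, settings: LearnerSettings | None = None
) -> FittedLearner:
    """Fit one member model on the training partition.

    ``smooth_additive`` — per-predictor cubic-spline basis with a logistic
    link (a penalized additive model); ``adaptive_hinge`` — logistic
    regression on a two-sided hinge basis at data-quantile knots;
    ``kernel_margin`` — RBF support-vector classifier whose decision values
    are calibrated to [0, 1] by a logistic link fitted on cross-validated
    decision values.
    """
    settings = settings or LearnerSettings()
    X, y = _xy(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both labels")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all predictors are degenerate (zero variance)")

    if learner == "smooth_additive":
        n_knots = max(2, min(settings.n_knots, len(train) // 4))
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("spline", SplineTransformer(n_knots=n_knots, degree=3)),
                (
                    "logit",
                    LogisticRegression(
                        max_iter=settings.max_iter, tol=settings.tol, C=settings.C
                    ),
                ),
            ]
        )
        pipe.fit(X, y)
        return FittedLearner("smooth_additive", lambda Q: pipe.predict_proba(Q)[:, 1])

    if learner == "adaptive_hinge":
        scaler = StandardScaler().fit(X)
        hinge = _HingeFeatures(settings.hinge_quantiles).fit(scaler.transform(X))
        logit = LogisticRegression(
            max_iter=settings.max_iter, tol=settings.tol, C=settings.C
        )
        logit.fit(hinge.transform(scaler.transform(X)), y)
        return FittedLearner(
            "adaptive_hinge",
            lambda Q: logit.predict_proba(hinge.transform(scaler.transform(Q)))[:, 1],
        )

    if learner == "kernel_margin":
        scaler = StandardScaler().fit(X)
        Z = scaler.transform(X)
        svm = SVC(kernel="rbf", C=settings.C, tol=settings.tol)
        svm.fit(Z, y)
        n_folds = min(settings.cv_folds, int(np.bincount(y).min()))
        if n_folds >= 2:
            cv = StratifiedKFold(n_splits=n_folds, shuffle=False)
            dec = cross_val_predict(
                SVC(kernel="rbf", C=settings.C, tol=settings.tol),
                Z,
                y,
                cv=cv,
                method="decision_function",
            )
        else:
            dec = svm.decision_function(Z)
        calib = LogisticRegression(max_iter=settings.max_iter, tol=settings.tol)
        calib.fit(dec.reshape(-1, 1), y)
        return FittedLearner(
            "kernel_margin",
            lambda Q: calib.predict_proba(
                svm.decision_function(scaler.transform(Q)).reshape(-1, 1)
            )[:, 1],
        )

    raise ValueError(f"unknown learner {learner!r}; choose from {LEARNER_NAMES}")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def confusion_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ModelMetrics:
    """Confusion-matrix metrics with prediction rule score >= threshold.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    marginal products; a degenerate table with p_e = 1 yields kappa = NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n == 0:
        raise ValueError("no records to evaluate")
    if len(np.unique(labels)) < 2:
        raise ValueError("both labels must be present")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = float("nan") if p_e == 1 else (p_o - p_e) / (1 - p_e)
    return ModelMetrics(
        sensitivity=sens,
        specificity=spec,
        omission_rate=1 - sens,
        proportion_correct=p_o,
        kappa=kappa,
        threshold=threshold,
    )


def threshold_max_tss(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing TSS over midpoints of sorted unique scores.

    Ties are broken toward the lower threshold.  All-equal scores are an
    error (no threshold separates anything).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores are equal; no threshold exists")
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    best_t, best_tss = candidates[0], -np.inf
    for t in candidates:
        m = confusion_metrics(scores, labels, t)
        tss = m.sensitivity + m.specificity - 1
        if tss > best_tss:
            best_t, best_tss = t, tss
    return float(best_t), float(best_tss)


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------


def combine_member_scores(scores: np.ndarray, kappas: np.ndarray) -> np.ndarray:
    """Kappa-weighted mean of member score arrays (members on axis 0)."""
    kappas = np.asarray(kappas, dtype=float)
    if np.any(kappas < 0):
        raise ValueError("member weights require nonnegative kappa")
    w = kappas / kappas.sum()
    return np.tensordot(w, np.asarray(scores, dtype=float), axes=(0, 0))


def ensemble(
    members: list[tuple[FittedLearner, ModelMetrics]],
    predictors: PredictorStack,
    taxon_id: str = "",
    retain_kappa: float = 0.4,
) -> SuitabilityMap:
    """Kappa-weighted ensemble surface over the grid from retained members.

    Members with test kappa below ``retain_kappa`` (the conventional
    "moderate agreement" floor) are dropped; weights are proportional to
    kappa and normalized over the retained set.
    """
    retained = [(f, m) for f, m in members if m.kappa >= retain_kappa]
    if not retained:
        raise ValueError(
            f"no member passed the retain rule kappa >= {retain_kappa}"
        )
    ids, X = predictors.as_table()
    member_scores = np.stack([f.predict(X) for f, _ in retained])
    kappas = np.array([m.kappa for _, m in retained])
    scores = combine_member_scores(member_scores, kappas)
    geom = predictors.geometry
    surface = np.full(geom.n_cells, np.nan)
    surface[ids] = scores
    weights = kappas / kappas.sum()
    return SuitabilityMap(
        taxon_id=taxon_id,
        geometry=geom,
        values=surface.reshape(geom.n_rows, geom.n_cols),
        members=[
            {"name": f.name, "weight": float(w), "metrics": m.as_dict()}
            for (f, m), w in zip(retained, weights)
        ],
    )


def binarize(smap: SuitabilityMap, test: pd.DataFrame, rule: str = "max_tss") -> BinaryMap:
    """Binary presence/absence surface at the max-TSS threshold on test points."""
    if rule != "max_tss":
        raise ValueError(f"unknown thresholding rule {rule!r}")
    if len(np.unique(test["label"])) < 2:
        raise ValueError("test partition must contain both labels")
    flat = smap.values.reshape(-1)
    scores = flat[test["cell_id"].to_numpy(dtype=int)]
    threshold, _ = threshold_max_tss(scores, test["label"].to_numpy())
    binary = np.where(np.isnan(flat), 0, (flat >= threshold).astype(int))
    return BinaryMap(
        taxon_id=smap.taxon_id,
        geometry=smap.geometry,
        values=binary.reshape(smap.values.shape),
        threshold=threshold,
        rule=rule,
    )


def abiotic_suitability(smap: SuitabilityMap, eco: EcosystemMap, ecosystem_id: int) -> float:
    """Percentage mean continuous suitability over one ecosystem's cells."""
    cells = eco.cells_of(ecosystem_id)
    vals = smap.values[cells]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"ecosystem {ecosystem_id} has no evaluable cells")
    return float(100.0 * vals.mean())


# ---------------------------------------------------------------------------
# Convenience end-to-end fit
# ---------------------------------------------------------------------------


@dataclass
class SDMResult:
    taxon_id: str
    suitability: SuitabilityMap
    binary: BinaryMap
    points: pd.DataFrame
    ensemble_metrics: ModelMetrics
    member_metrics: dict[str, ModelMetrics]


def train_sdm(
    presences: pd.DataFrame,
    predictors: PredictorStack,
    seed: int,
    taxon_id: str | None = None,
    train_fraction: float = 0.7,
    retain_kappa: float = 0.4,
    learners: tuple[str, ...] = LEARNER_NAMES,
    settings: LearnerSettings | None = None,
) -> SDMResult:
    """Full per-taxon protocol: pseudo-absences, split, members, ensemble, binary map."""
    taxon_id = taxon_id or str(presences["taxon_id"].iloc[0])
    points = generate_pseudo_absences(presences, predictors, seed=seed)
    points = split_records(points, train_fraction, seed=seed + 1)
    train = points[points["partition"] == "train"]
    test = points[points["partition"] == "test"]
    X_test, y_test = _xy(test)
    members = []
    member_metrics: dict[str, ModelMetrics] = {}
    for name in learners:
        fitted = fit_learner(train, name, settings)
        scores = fitted.predict(X_test)
        t, _ = threshold_max_tss(scores, y_test)
        metrics = confusion_metrics(scores, y_test, t)
        member_metrics[name] = metrics
        members.append((fitted, metrics))
    smap = ensemble(members, predictors, taxon_id=taxon_id, retain_kappa=retain_kappa)
    bmap = binarize(smap, test)
    ens_scores = smap.values.reshape(-1)[test["cell_id"].to_numpy(dtype=int)]
    ens_metrics = confusion_metrics(ens_scores, y_test, bmap.threshold)
    return SDMResult(
        taxon_id=taxon_id,
        suitability=smap,
        binary=bmap,
        points=points,
        ensemble_metrics=ens_metrics,
        member_metrics=member_metrics,
    )
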