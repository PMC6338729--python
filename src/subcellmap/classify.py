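"""Marker-trained SVM localisation prediction with FDR-controlled labels.

Curated organelle markers are the labelled training data; a radial-basis
support vector machine learns the fraction-profile signature of each
compartment and scores every unannotated protein against all classes.
Hyperparameters (kernel width sigma, soft-margin cost C) are tuned by nested
cross-validation: repeated rounds of an outer stratified test/train split,
with an inner grid-search cross-validation on each training partition, scored
by macro F1.  Final assignments are filtered per class by walking down the
score-ranked list and accepting the largest prefix whose disagreement rate
against a reference annotation stays at or below a target false discovery
rate; everything below the resulting score threshold is left "unknown".

Kernel convention: ``K(x, y) = exp(-sigma * ||x - y||^2)``, i.e. sigma is the
radial kernel's gamma.  Printed optima such as sigma = 0.01 refer to this
convention (libraries differ; some parameterise by 1 / (2 sigma^2)).

The per-class SVM "score" is the calibrated class-probability estimate from
pairwise coupling, a value in [0, 1] summing to one across classes — this
makes the score-ordered FDR walk well-defined.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import UNKNOWN, MarkerAnnotation, ProfileDataset

__all__ = [
    "SvmConfig",
    "TuneResult",
    "ClassificationResult",
    "macro_f1",
    "tune_svm",
    "train_and_score",
    "apply_fdr_threshold",
]

DEFAULT_SIGMA_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
DEFAULT_COST_GRID = tuple(2.0**k for k in range(-4, 5))


@dataclass
class SvmConfig:
    """Grid-search and cross-validation settings for SVM tuning."""

    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    rounds: int = 100
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_grid or not self.cost_grid:
            raise ValueError("sigma and cost grids must be non-empty")
        if min(self.sigma_grid) <= 0 or min(self.cost_grid) <= 0:
            raise ValueError("sigma and cost values must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class TuneResult:
    """Outcome of repeated nested cross-validation."""

    per_round_best: list[tuple[float, float]]
    per_round_f1: np.ndarray  # outer macro F1, one per round
    grid_mean_f1: pd.DataFrame  # sigma x cost mean inner-CV macro F1
    sigma: float
    cost: float


@dataclass
class ClassificationResult:
    """Per-protein class scores and (optionally FDR-filtered) labels."""

    scores: pd.DataFrame  # proteins x classes, rows sum to 1
    assigned: pd.Series  # argmax class
    score: pd.Series  # argmax score
    label: pd.Series  # final label: class or "unknown"
    classes: list[str]
    thresholds: dict[str, float] = field(default_factory=dict)
    is_marker: pd.Series | None = None


def macro_f1(y_true, y_pred, classes=None) -> float:
    """Unweighted mean over classes of per-class F1.

    Per-class F1 is the harmonic mean of precision and recall, taken as 0
    when undefined (no predictions and no members, or zero numerator).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = sorted(set(y_true))
    f1s = []
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(f1s))


def _marker_xy(dataset: ProfileDataset, markers: MarkerAnnotation):
    acc = [a for a in dataset.accessions if markers.class_of(a) != UNKNOWN]
    if not acc:
        raise ValueError("no marker proteins present in the dataset")
    X = dataset.matrix.loc[acc].to_numpy(dtype=float)
    y = np.array([markers.class_of(a) for a in acc])
    return np.array(acc), X, y


def _check_class_sizes(y: np.ndarray, folds: int) -> None:
    counts = Counter(y)
    if len(counts) < 2:
        raise ValueError("need at least two marker classes")
    small = [c for c, n in counts.items() if n < folds]
    if small:
        raise ValueError(
            f"marker classes smaller than folds={folds}: {sorted(small)}"
        )


def _fit_svc(X, y, sigma: float, cost: float, **kw) -> SVC:
    return SVC(kernel="rbf", gamma=sigma, C=cost, **kw).fit(X, y)


def tune_svm(dataset: ProfileDataset, markers: MarkerAnnotation, config: SvmConfig) -> TuneResult:
    """Nested cross-validated grid search for (sigma, cost).

    Each round splits the markers into a stratified held-out partition
    (1/folds of each class) and a training partition; an inner
    ``folds``-fold CV on the training partition scores every grid point by
    macro F1 and the winner is refit on the whole training partition and
    evaluated on the held-out part.  The returned (sigma, cost) is the modal
    per-round winner.  Round r uses seed ``config.seed + r``, so results are
    reproducible and invariant to marker row order.
    """
    acc, X, y = _marker_xy(dataset, markers)
    _check_class_sizes(y, config.folds)
    order = np.argsort(acc)  # row-order invariance: sort markers by accession
    X, y = X[order], y[order]
    classes = sorted(set(y))

    grid = [(s, c) for s in config.sigma_grid for c in config.cost_grid]
    grid_sum = np.zeros(len(grid))
    grid_n = 0
    per_round_best: list[tuple[float, float]] = []
    per_round_f1 = np.empty(config.rounds)

    for r in range(config.rounds):
        rs = config.seed + r
        outer = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=rs)
        train_idx, test_idx = next(outer.split(X, y))
        Xtr, ytr, Xte, yte = X[train_idx], y[train_idx], X[test_idx], y[test_idx]

        inner = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=rs)
        inner_splits = list(inner.split(Xtr, ytr))
        scores = np.empty(len(grid))
        for gi, (s, c) in enumerate(grid):
            f1s = []
            for itr, ite in inner_splits:
                model = _fit_svc(Xtr[itr], ytr[itr], s, c)
                f1s.append(macro_f1(ytr[ite], model.predict(Xtr[ite]), classes))
            scores[gi] = np.mean(f1s)
        best_gi = int(np.argmax(scores))  # first maximum: smaller sigma, then cost
        best_sigma, best_cost = grid[best_gi]
        per_round_best.append((best_sigma, best_cost))
        grid_sum += scores
        grid_n += 1

        model = _fit_svc(Xtr, ytr, best_sigma, best_cost)
        per_round_f1[r] = macro_f1(yte, model.predict(Xte), classes)

    modal = Counter(per_round_best).most_common(1)[0][0]
    grid_mean = pd.DataFrame(
        (grid_sum / grid_n).reshape(len(config.sigma_grid), len(config.cost_grid)),
        index=pd.Index(config.sigma_grid, name="sigma"),
        columns=pd.Index(config.cost_grid, name="cost"),
    )
    return TuneResult(
        per_round_best=per_round_best,
        per_round_f1=per_round_f1,
        grid_mean_f1=grid_mean,
        sigma=modal[0],
        cost=modal[1],
    )


def train_and_score(
    dataset: ProfileDataset,
    markers: MarkerAnnotation,
    sigma: float,
    cost: float,
    seed: int = 0,
) -> ClassificationResult:
    """Train on all markers and score every protein against every class.

    Scores are calibrated class probabilities (pairwise coupling), summing
    to one per protein.  Markers retain their curated label and score 1.
    """
    if not dataset.is_complete():
        raise ValueError("dataset must be complete (no missing values)")
    bad = set(markers.labels.values()) - set(markers.classes)
    if bad:
        raise ValueError(f"marker labels outside the class list: {sorted(bad)}")
    acc, X, y = _marker_xy(dataset, markers)
    n_cal = min(5, min(Counter(y).values()))
    if n_cal < 2:
        raise ValueError("every marker class needs >= 2 members for score calibration")
    model = CalibratedClassifierCV(
        SVC(kernel="rbf", gamma=sigma, C=cost),
        cv=StratifiedKFold(n_splits=n_cal, shuffle=True, random_state=seed),
        ensemble=False,
    ).fit(X, y)
    classes = list(model.classes_)

    proba = model.predict_proba(dataset.values())
    scores = pd.DataFrame(proba, index=dataset.accessions, columns=classes)
    assigned = scores.idxmax(axis=1)
    top = scores.max(axis=1)

    is_marker = pd.Series(
        [markers.class_of(a) != UNKNOWN for a in dataset.accessions], index=dataset.accessions
    )
    label = assigned.copy()
    for a in acc:
        label.loc[a] = markers.class_of(a)
        scores.loc[a] = 0.0
        scores.loc[a, markers.class_of(a)] = 1.0
        top.loc[a] = 1.0
    assigned = label.copy()
    return ClassificationResult(
        scores=scores,
        assigned=assigned,
        score=top,
        label=label,
        classes=classes,
        is_marker=is_marker,
    )


def apply_fdr_threshold(
    result: ClassificationResult,
    reference: pd.Series | dict,
    q: float = 0.05,
) -> ClassificationResult:
    """Per-class score-ordered FDR filtering of classifier assignments.

    For each class, the non-marker proteins assigned to it that carry a
    reference label are ranked by descending score; the class threshold is
    the lowest score such that the fraction of reference disagreements among
    accepted proteins stays <= ``q``, maximising the accepted set.  Proteins
    tied in score at the boundary share the boundary's fate.  All assigned
    proteins (with or without a reference) scoring below their class
    threshold are relabelled "unknown".  A class with no referenced
    assignments is left unthresholded with a warning.

    Thresholding only demotes: no protein's assigned class ever changes.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    ref = pd.Series(reference) if not isinstance(reference, pd.Series) else reference
    is_marker = (
        result.is_marker
        if result.is_marker is not None
        else pd.Series(False, index=result.label.index)
    )

    label = result.label.copy()
    thresholds: dict[str, float] = {}
    for cls in result.classes:
        members = result.label.index[(result.assigned == cls) & ~is_marker]
        with_ref = [a for a in members if a in ref.index]
        if not with_ref:
            if len(members):
                warnings.warn(
                    f"class {cls!r} has no referenced assignments; left unthresholded",
                    stacklevel=2,
                )
            thresholds[cls] = -np.inf
            continue
        s = result.score.loc[with_ref].sort_values(ascending=False, kind="mergesort")
        disagree = (ref.loc[s.index] != cls).to_numpy()
        cum_bad = np.cumsum(disagree)
        k = np.arange(1, len(s) + 1)
        fdr = cum_bad / k
        # cut only at distinct-score boundaries so tied proteins share fate
        svals = s.to_numpy()
        boundary = np.r_[svals[1:] < svals[:-1], True]
        ok = (fdr <= q) & boundary
        if ok.any():
            k_star = int(np.max(k[ok]))
            thresholds[cls] = float(svals[k_star - 1])
        else:
            thresholds[cls] = np.inf

        demote = members[(result.score.loc[members] < thresholds[cls]).to_numpy()]
        label.loc[demote] = UNKNOWN

    return ClassificationResult(
        scores=result.scores,
        assigned=result.assigned,
        score=result.score,
        label=label,
        classes=result.classes,
        thresholds=thresholds,
        is_marker=is_marker,
    )
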