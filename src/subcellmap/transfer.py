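"""Theta-weighted k-nearest-neighbour integration of two organelle maps.

Two fractionation chemistries resolve different compartments, so combining a
primary map with an auxiliary one can classify proteins better than either
alone.  For each query protein and each class, a k-NN affinity is computed in
each dataset (the fraction of the k nearest markers carrying that class
label); the two affinity vectors are blended per class by a weight
theta_c in [0, 1]:

    combined_c = theta_c * primary_c + (1 - theta_c) * auxiliary_c

theta_c = 1 trusts the primary map exclusively for class c, theta_c = 0 the
auxiliary map.  The weight vector is chosen by repeated cross-validation on
the markers shared between both datasets, maximising macro F1 over a
candidate grid (default weights {0, 0.5, 1} per class, searched exhaustively
when the combination count fits a budget, by coordinate ascent otherwise).
The reported weight profile is the per-class interpolating median of the
per-iteration winners, so medians such as 0.75 can arise from {0.5, 1}.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .core import UNKNOWN, MarkerAnnotation, ProfileDataset
from .classify import macro_f1

__all__ = [
    "ThetaProfile",
    "knn_class_scores",
    "combine_scores",
    "tune_k",
    "optimize_theta",
    "transfer_classify",
]

DEFAULT_CANDIDATES = (0.0, 0.5, 1.0)


@dataclass
class ThetaProfile:
    """Per-class transfer weights selected over cross-validation iterations."""

    classes: list[str]
    candidates: tuple[float, ...]
    per_iteration_best: np.ndarray  # iterations x classes
    per_iteration_f1: np.ndarray
    per_iteration_f1_primary: np.ndarray  # baseline: theta = all-ones on the same partitions
    median: np.ndarray  # interpolating median per class

    def weight_frequencies(self) -> pd.DataFrame:
        """Fraction of iterations in which each candidate won, per class."""
        freq = {
            c: {
                w: float(np.mean(self.per_iteration_best[:, i] == w))
                for w in self.candidates
            }
            for i, c in enumerate(self.classes)
        }
        return pd.DataFrame(freq).T.loc[self.classes]

    def as_series(self) -> pd.Series:
        return pd.Series(self.median, index=self.classes, name="theta")


def _knn_scores_matrix(
    query_X: np.ndarray,
    marker_X: np.ndarray,
    marker_y: np.ndarray,
    marker_acc: np.ndarray,
    classes: list[str],
    k: int,
) -> np.ndarray:
    """Per-query per-class fraction of the k nearest markers, ties at rank k
    broken by ascending accession."""
    D = cdist(query_X, marker_X)
    # lexsort: primary key distance, secondary key accession
    acc_rank = np.argsort(np.argsort(marker_acc))
    out = np.zeros((len(query_X), len(classes)))
    cls_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([cls_idx[c] for c in marker_y])
    for qi in range(len(query_X)):
        order = np.lexsort((acc_rank, D[qi]))
        for mi in order[:k]:
            out[qi, y_idx[mi]] += 1.0
    return out / k


def knn_class_scores(
    dataset: ProfileDataset,
    markers: MarkerAnnotation,
    query_accessions,
    k: int,
) -> pd.DataFrame:
    """k-NN class affinities for each query protein.

    The score of class c is the fraction of the query's k nearest marker
    neighbours (Euclidean distance on the full concatenated profile) labelled
    c; scores sum to one.  A query that is itself a marker is excluded from
    its own neighbour set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    query_accessions = list(query_accessions)
    missing = [a for a in query_accessions if a not in dataset.matrix.index]
    if missing:
        raise KeyError(f"query accessions not in dataset: {missing[:5]}")
    marker_acc = np.array(
        [a for a in dataset.accessions if markers.class_of(a) != UNKNOWN]
    )
    if k > len(marker_acc):
        raise ValueError(f"k={k} exceeds number of markers {len(marker_acc)}")
    classes = list(markers.classes)
    marker_y = np.array([markers.class_of(a) for a in marker_acc])
    marker_X = dataset.matrix.loc[marker_acc].to_numpy(dtype=float)

    out = pd.DataFrame(
        0.0, index=pd.Index(query_accessions), columns=classes, dtype=float
    )
    plain = [a for a in query_accessions if markers.class_of(a) == UNKNOWN]
    if plain:
        S = _knn_scores_matrix(
            dataset.matrix.loc[plain].to_numpy(dtype=float),
            marker_X, marker_y, marker_acc, classes, k,
        )
        out.loc[plain] = S
    for a in query_accessions:  # marker queries: leave-self-out neighbour pool
        if markers.class_of(a) == UNKNOWN:
            continue
        keep = marker_acc != a
        S = _knn_scores_matrix(
            dataset.matrix.loc[[a]].to_numpy(dtype=float),
            marker_X[keep], marker_y[keep], marker_acc[keep], classes,
            min(k, int(keep.sum())),
        )
        out.loc[a] = S[0]
    return out


def combine_scores(
    primary_scores: pd.DataFrame,
    auxiliary_scores: pd.DataFrame,
    theta,
) -> tuple[pd.DataFrame, pd.Series]:
    """Blend primary and auxiliary class affinities with per-class weights.

    Returns the combined score table and the argmax prediction, ties broken
    to the lexicographically first class name.
    """
    if list(primary_scores.columns) != list(auxiliary_scores.columns):
        raise ValueError("primary and auxiliary score tables must share class order")
    if not primary_scores.index.equals(auxiliary_scores.index):
        auxiliary_scores = auxiliary_scores.loc[primary_scores.index]
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 0:
        theta = np.full(primary_scores.shape[1], float(theta))
    if theta.shape != (primary_scores.shape[1],):
        raise ValueError("theta length must equal the number of classes")
    if theta.min() < 0 or theta.max() > 1:
        raise ValueError("theta weights must lie in [0, 1]")
    combined = primary_scores * theta + auxiliary_scores * (1.0 - theta)
    cols = list(combined.columns)
    order = np.argsort(cols, kind="mergesort")
    arr = combined.to_numpy()[:, order]
    pred_idx = np.argmax(arr, axis=1)  # first max among lexicographically sorted classes
    pred = pd.Series([cols[order[i]] for i in pred_idx], index=combined.index)
    return combined, pred


def _shared_marker_xy(
    primary: ProfileDataset, auxiliary: ProfileDataset, markers: MarkerAnnotation
):
    shared = [
        a
        for a in primary.accessions
        if markers.class_of(a) != UNKNOWN and a in auxiliary.matrix.index
    ]
    if not shared:
        raise ValueError("no marker proteins shared between the two datasets")
    shared = sorted(shared)
    y = np.array([markers.class_of(a) for a in shared])
    return np.array(shared), y


def tune_k(
    dataset: ProfileDataset,
    markers: MarkerAnnotation,
    k_grid=(3, 5, 7, 9, 11, 15),
    rounds: int = 100,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated choice of the k-NN neighbourhood size.

    For each round a stratified 1/folds marker partition is held out and each
    k in the grid is scored by macro F1; the modal per-round winner is
    returned (ties to the smallest k).  Also returns the per-k mean F1 table.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k grid must be non-empty")
    marker_acc = np.array(
        sorted(a for a in dataset.accessions if markers.class_of(a) != UNKNOWN)
    )
    y = np.array([markers.class_of(a) for a in marker_acc])
    counts = Counter(y)
    small = [c for c, n in counts.items() if n < folds]
    if small:
        raise ValueError(f"marker classes smaller than folds={folds}: {sorted(small)}")
    X = dataset.matrix.loc[marker_acc].to_numpy(dtype=float)
    classes = list(markers.classes)

    best_per_round = []
    f1_sum = np.zeros(len(k_grid))
    for r in range(rounds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        tr, te = next(skf.split(X, y))
        f1s = np.empty(len(k_grid))
        for ki, k in enumerate(k_grid):
            kk = min(k, len(tr))
            scores = _knn_scores_matrix(X[te], X[tr], y[tr], marker_acc[tr], classes, kk)
            pred = [classes[i] for i in np.argmax(scores, axis=1)]
            f1s[ki] = macro_f1(y[te], pred, classes)
        best_per_round.append(k_grid[int(np.argmax(f1s))])  # first max: smallest k
        f1_sum += f1s
    modal = Counter(best_per_round).most_common()
    top_count = modal[0][1]
    best_k = min(k for k, n in modal if n == top_count)
    table = pd.DataFrame({"k": k_grid, "mean_macro_f1": f1_sum / rounds}).set_index("k")
    return best_k, table


def _theta_candidates_exhaustive(candidates, n_classes):
    return itertools.product(candidates, repeat=n_classes)


def _evaluate_theta(theta, Sp, Sa, y_true, classes):
    combined = Sp * np.asarray(theta) + Sa * (1.0 - np.asarray(theta))
    pred = [classes[i] for i in np.argmax(combined, axis=1)]
    return macro_f1(y_true, pred, classes)


def optimize_theta(
    primary: ProfileDataset,
    auxiliary: ProfileDataset,
    markers: MarkerAnnotation,
    candidates=DEFAULT_CANDIDATES,
    iterations: int = 100,
    folds: int = 5,
    k_primary: int = 5,
    k_auxiliary: int = 5,
    seed: int = 0,
    budget: int = 10_000,
    mode: str = "auto",
) -> ThetaProfile:
    """Select per-class transfer weights by repeated marker cross-validation.

    Each iteration holds out a stratified 1/folds partition of the markers
    shared by both datasets, computes held-out k-NN affinities from each
    dataset's training markers, and picks the weight vector maximising macro
    F1.  The search is exhaustive over ``candidates ** n_classes`` when that
    count is within ``budget`` (or ``mode='exhaustive'``); otherwise
    coordinate ascent sweeps the classes in random order from the all-ones
    start until no improvement (max 5 sweeps).  Equal-F1 ties resolve toward
    larger weights (prefer the primary, higher-resolution map).
    """
    candidates = tuple(sorted(set(float(c) for c in candidates)))
    if not candidates:
        raise ValueError("candidate weight set must be non-empty")
    if any(c < 0 or c > 1 for c in candidates):
        raise ValueError("candidate weights must lie in [0, 1]")
    shared, y = _shared_marker_xy(primary, auxiliary, markers)
    classes = list(markers.classes)
    n_classes = len(classes)
    Xp = primary.matrix.loc[shared].to_numpy(dtype=float)
    Xa = auxiliary.matrix.loc[shared].to_numpy(dtype=float)

    n_comb = len(candidates) ** n_classes
    if mode == "auto":
        mode = "exhaustive" if n_comb <= budget else "ascent"
    if mode not in ("exhaustive", "ascent"):
        raise ValueError(f"unknown search mode {mode!r}")

    best_mat = np.empty((iterations, n_classes))
    best_f1 = np.empty(iterations)
    primary_f1 = np.empty(iterations)
    for it in range(iterations):
        rng = np.random.default_rng(seed + it)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + it)
        tr, te = next(skf.split(Xp, y))
        kp = min(k_primary, len(tr))
        ka = min(k_auxiliary, len(tr))
        Sp = _knn_scores_matrix(Xp[te], Xp[tr], y[tr], shared[tr], classes, kp)
        Sa = _knn_scores_matrix(Xa[te], Xa[tr], y[tr], shared[tr], classes, ka)
        y_te = y[te]
        primary_f1[it] = _evaluate_theta(np.ones(n_classes), Sp, Sa, y_te, classes)

        if mode == "exhaustive":
            best_theta, best = None, -1.0
            for theta in _theta_candidates_exhaustive(candidates, n_classes):
                f1 = _evaluate_theta(theta, Sp, Sa, y_te, classes)
                if f1 >= best:  # >= : later (larger) candidates win ties
                    best, best_theta = f1, theta
            best_mat[it] = best_theta
            best_f1[it] = best
        else:
            theta = np.full(n_classes, candidates[-1])
            best = _evaluate_theta(theta, Sp, Sa, y_te, classes)
            for _sweep in range(5):
                improved = False
                for ci in rng.permutation(n_classes):
                    for w in candidates:
                        if w == theta[ci]:
                            continue
                        trial = theta.copy()
                        trial[ci] = w
                        f1 = _evaluate_theta(trial, Sp, Sa, y_te, classes)
                        if f1 > best or (f1 == best and w > theta[ci]):
                            if f1 > best:
                                improved = True
                            best = f1
                            theta = trial
                if not improved:
                    break
            best_mat[it] = theta
            best_f1[it] = best

    return ThetaProfile(
        classes=classes,
        candidates=candidates,
        per_iteration_best=best_mat,
        per_iteration_f1=best_f1,
        per_iteration_f1_primary=primary_f1,
        median=np.median(best_mat, axis=0),
    )


def transfer_classify(
    primary: ProfileDataset,
    auxiliary: ProfileDataset,
    markers: MarkerAnnotation,
    theta,
    k_primary: int = 5,
    k_auxiliary: int = 5,
) -> pd.DataFrame:
    """Classify every shared non-marker protein with theta-blended k-NN.

    Proteins present in only one dataset are scored from that dataset alone
    and flagged in the ``source`` column (``both`` / ``primary-only`` /
    ``auxiliary-only``).
    """
    classes = list(markers.classes)
    prim_acc = set(primary.accessions)
    aux_acc = set(auxiliary.matrix.index)
    non_marker = [a for a in sorted(prim_acc | aux_acc) if markers.class_of(a) == UNKNOWN]
    both = [a for a in non_marker if a in prim_acc and a in aux_acc]
    prim_only = [a for a in non_marker if a in prim_acc and a not in aux_acc]
    aux_only = [a for a in non_marker if a not in prim_acc and a in aux_acc]

    frames = []
    if both:
        Sp = knn_class_scores(primary, markers, both, k_primary)
        Sa = knn_class_scores(auxiliary, markers, both, k_auxiliary)
        combined, pred = combine_scores(Sp, Sa, theta)
        f = combined.copy()
        f["predicted"] = pred
        f["score"] = combined.max(axis=1)
        f["source"] = "both"
        frames.append(f)
    for accs, ds, k, tag in (
        (prim_only, primary, k_primary, "primary-only"),
        (aux_only, auxiliary, k_auxiliary, "auxiliary-only"),
    ):
        if accs:
            S = knn_class_scores(ds, markers, accs, k)
            _, pred = combine_scores(S, S, np.ones(len(classes)))
            f = S.copy()
            f["predicted"] = pred
            f["score"] = S.max(axis=1)
            f["source"] = tag
            frames.append(f)
    if not frames:
        raise ValueError("no non-marker proteins to classify")
    return pd.concat(frames).sort_index()
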