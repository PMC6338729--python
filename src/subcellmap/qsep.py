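"""QSep: quantifying experiment-wide subcellular resolution from markers.

The statistic compares average Euclidean distances within and between
organelle marker clusters.  Entry (i, j) of the raw matrix is the mean
distance over all cross-pairs between clusters i and j; the diagonal holds
the mean over unordered distinct within-cluster pairs (self-distances are
excluded — including them would deflate the compactness reference).  The
normalised matrix divides each entry by a reference within-cluster distance,
so N(i, j) says how many times further apart clusters i and j sit than the
reference cluster's own spread; the normalised diagonal is exactly 1 and the
matrix is generally asymmetric.  Larger normalised distances mean better
separated compartments; the metric is invariant to rigid motion and to
global rescaling of the profile space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .core import UNKNOWN, MarkerAnnotation, ProfileDataset

logger = logging.getLogger(__name__)

__all__ = ["QSepMatrix", "cluster_distance_matrix", "normalize_qsep", "summarize_qsep", "qsep"]


@dataclass
class QSepMatrix:
    """Raw and normalised average-distance matrices over marker clusters."""

    raw: pd.DataFrame
    normalised: pd.DataFrame
    classes: list[str]
    orientation: str  # "row" or "column": which cluster's within-distance is the reference


def cluster_distance_matrix(
    dataset: ProfileDataset, markers: MarkerAnnotation
) -> pd.DataFrame:
    """Mean within/between Euclidean distances over marker clusters.

    Markers absent from the dataset are dropped from their cluster (with a
    logged count).  Every class must retain at least two markers, otherwise
    its within-cluster mean is undefined.
    """
    clusters: dict[str, np.ndarray] = {}
    n_dropped = 0
    for cls in markers.classes:
        acc = [a for a in markers.accessions_of(cls)]
        present = [a for a in acc if a in dataset.matrix.index]
        n_dropped += len(acc) - len(present)
        if len(present) < 2:
            raise ValueError(
                f"class {cls!r} has {len(present)} markers in the dataset; need >= 2"
            )
        clusters[cls] = dataset.matrix.loc[present].to_numpy(dtype=float)
    if n_dropped:
        logger.info("cluster_distance_matrix: %d markers absent from dataset", n_dropped)

    classes = list(markers.classes)
    C = len(classes)
    raw = np.zeros((C, C))
    for i, ci in enumerate(classes):
        raw[i, i] = pdist(clusters[ci]).mean()  # unordered distinct pairs
        for j in range(i + 1, C):
            raw[i, j] = raw[j, i] = cdist(clusters[ci], clusters[classes[j]]).mean()
    return pd.DataFrame(raw, index=classes, columns=classes)


def normalize_qsep(raw: pd.DataFrame, orientation: str = "row") -> pd.DataFrame:
    """Divide each entry by the reference within-cluster average distance.

    ``orientation='row'`` (default) uses the row class's within-distance as
    the reference, ``'column'`` the column class's.  The diagonal becomes
    exactly 1.  A zero within-distance (all markers identical) makes the
    cluster's reference degenerate and raises.
    """
    diag = np.diag(raw.to_numpy(dtype=float))
    if np.any(diag <= 0):
        bad = [raw.index[i] for i in np.flatnonzero(diag <= 0)]
        raise ValueError(f"degenerate clusters with zero within-distance: {bad}")
    if orientation == "row":
        normed = raw.to_numpy(dtype=float) / diag[:, None]
    elif orientation == "column":
        normed = raw.to_numpy(dtype=float) / diag[None, :]
    else:
        raise ValueError("orientation must be 'row' or 'column'")
    return pd.DataFrame(normed, index=raw.index, columns=raw.columns)


def summarize_qsep(normalised: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-class minimum off-diagonal distance and pooled distribution stats.

    The per-class minimum identifies each compartment's least-resolved
    neighbour; the pooled off-diagonal median/IQR summarise dataset-level
    resolution for cross-experiment comparison.
    """
    if normalised.shape[0] < 2:
        raise ValueError("need at least two classes to summarise")
    arr = normalised.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, np.inf)
    min_idx = np.argmin(arr, axis=1)
    per_class = pd.DataFrame(
        {
            "min_distance": arr[np.arange(len(arr)), min_idx],
            "nearest_class": [normalised.columns[i] for i in min_idx],
        },
        index=normalised.index,
    )
    off = arr[np.isfinite(arr)]
    q1, med, q3 = np.percentile(off, [25, 50, 75])
    stats = {"median": float(med), "iqr": float(q3 - q1), "q1": float(q1), "q3": float(q3)}
    return per_class, stats


def qsep(
    dataset: ProfileDataset, markers: MarkerAnnotation, orientation: str = "row"
) -> QSepMatrix:
    """Full QSep computation: raw matrix, normalisation, fixed class order."""
    raw = cluster_distance_matrix(dataset, markers)
    normalised = normalize_qsep(raw, orientation)
    return QSepMatrix(
        raw=raw, normalised=normalised, classes=list(markers.classes), orientation=orientation
    )
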