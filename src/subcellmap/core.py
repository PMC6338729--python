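"""Core data model for quantitative subcellular fraction profiles.

A spatial-proteomics experiment measures, for each protein, its relative
abundance across a series of subcellular fractions (TMT reporter channels).
Proteins co-residing in an organelle share a characteristic fraction profile,
so the profile matrix is the substrate for every downstream analysis:
dimensionality reduction, marker-based classification, resolution metrics and
dataset integration.

This module provides the :class:`ProfileDataset` container, marker-annotation
handling, table I/O, the standard preprocessing chain (row sum-normalisation,
median aggregation of PSM-level rows into protein groups, complete-profile
filtering, channel exclusion, contaminant removal, replicate concatenation),
PCA projection, and the agreement analysis between two independent
classification results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"

__all__ = [
    "UNKNOWN",
    "ProfileDataset",
    "MarkerAnnotation",
    "PcaResult",
    "read_profile_table",
    "read_marker_table",
    "sum_normalize_rows",
    "aggregate_protein_groups",
    "filter_complete_profiles",
    "drop_channels",
    "remove_contaminants",
    "concatenate_replicates",
    "merge_marker_classes",
    "pca_project",
    "write_pca_scores",
    "agreement_matrix",
]


@dataclass
class ProfileDataset:
    """Proteins-by-channels relative-abundance matrix with metadata.

    Parameters
    ----------
    matrix
        DataFrame indexed by protein accession, one column per TMT channel,
        values are non-negative relative abundances (unitless ratios).
        Missing quantitation is stored as NaN, never as zero.
    channel_meta
        DataFrame indexed by channel id with columns ``replicate`` and
        ``fraction``; aligned with ``matrix.columns``.
    feature_meta
        DataFrame indexed by accession with at least a ``marker_class``
        column (class name or ``"unknown"``); optional ``true_class`` (ground
        truth for synthetic data) and ``abundance`` columns.
    """

    matrix: pd.DataFrame
    channel_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accessions: {dups}")
        if len(self.channel_meta) != self.matrix.shape[1]:
            raise ValueError(
                f"channel_meta length {len(self.channel_meta)} does not match "
                f"{self.matrix.shape[1]} matrix columns"
            )
        if not self.channel_meta.index.equals(self.matrix.columns):
            self.channel_meta = self.channel_meta.reindex(self.matrix.columns)
            if self.channel_meta.isna().all(axis=1).any():
                raise ValueError("channel_meta does not cover all matrix columns")
        fm = self.feature_meta
        if not fm.index.equals(self.matrix.index):
            fm = fm.reindex(self.matrix.index)
        if "marker_class" not in fm.columns:
            fm = fm.assign(marker_class=UNKNOWN)
        elif fm["marker_class"].isna().any():
            fm = fm.assign(marker_class=fm["marker_class"].fillna(UNKNOWN))
        self.feature_meta = fm
        vals = self.matrix.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("profile values must be non-negative")

    # -- conveniences -------------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    @property
    def accessions(self) -> pd.Index:
        return self.matrix.index

    def is_complete(self) -> bool:
        return not self.matrix.isna().any().any()

    def marker_mask(self) -> pd.Series:
        return self.feature_meta["marker_class"] != UNKNOWN

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def copy(self) -> "ProfileDataset":
        return ProfileDataset(
            self.matrix.copy(), self.channel_meta.copy(), self.feature_meta.copy()
        )

    def subset(self, accessions) -> "ProfileDataset":
        accessions = pd.Index(accessions)
        missing = accessions.difference(self.matrix.index)
        if len(missing):
            raise KeyError(f"accessions not in dataset: {missing.tolist()[:5]}")
        return ProfileDataset(
            self.matrix.loc[accessions],
            self.channel_meta.copy(),
            self.feature_meta.loc[accessions],
        )


@dataclass
class MarkerAnnotation:
    """Curated accession-to-subcellular-class labels.

    ``classes`` fixes the class order used throughout (score columns,
    distance matrices, weight vectors).  ``merge_map`` optionally maps fine
    classes onto coarser ones, e.g. ``nucleus -> nucleus/chromatin`` when a
    workflow cannot resolve a pair of compartments.
    """

    labels: dict[str, str]
    classes: list[str] = field(default_factory=list)
    merge_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted(set(self.labels.values()))
        unknown_classes = set(self.labels.values()) - set(self.classes)
        if unknown_classes:
            raise ValueError(f"labelled classes not in class list: {sorted(unknown_classes)}")

    def class_of(self, accession: str) -> str:
        return self.labels.get(accession, UNKNOWN)

    def accessions_of(self, cls: str) -> list[str]:
        return [a for a, c in self.labels.items() if c == cls]

    def class_series(self, accessions) -> pd.Series:
        return pd.Series(
            [self.labels.get(a, UNKNOWN) for a in accessions], index=accessions, name="marker_class"
        )


@dataclass
class PcaResult:
    """Principal-component projection of the profile matrix.

    ``scores`` holds the protein coordinates, ``loadings`` the channel
    loadings (components x channels), ``variance_fraction`` the per-component
    fraction of total variance.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray


# -- I/O --------------------------------------------------------------------


def read_profile_table(
    path,
    *,
    delimiter: str = "\t",
    id_column: str | None = None,
    channel_columns: list[str] | None = None,
    channel_meta: pd.DataFrame | None = None,
) -> ProfileDataset:
    """Read a protein (or PSM) quantitation table into a :class:`ProfileDataset`.

    The first column (or ``id_column``) is the accession; ``channel_columns``
    selects the reporter channels (default: all remaining columns).  Missing
    cells (empty or ``NA``) are preserved as NaN, never coerced to zero.
    """
    table = pd.read_csv(path, sep=delimiter, dtype=str)
    if id_column is None:
        id_column = table.columns[0]
    if id_column not in table.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    if channel_columns is None:
        channel_columns = [c for c in table.columns if c != id_column]
    missing_cols = [c for c in channel_columns if c not in table.columns]
    if missing_cols:
        raise ValueError(f"channel columns not found: {missing_cols}")
    ids = table[id_column]
    if ids.duplicated().any():
        raise ValueError(
            f"duplicate accessions: {ids[ids.duplicated()].unique().tolist()}"
        )
    raw = table.set_index(id_column)[channel_columns]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()  # read_csv already maps NA tokens to NaN
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    numeric.index.name = "accession"
    if channel_meta is None:
        channel_meta = pd.DataFrame(
            {"replicate": 1, "fraction": np.arange(1, numeric.shape[1] + 1)},
            index=numeric.columns,
        )
    feature_meta = pd.DataFrame({"marker_class": UNKNOWN}, index=numeric.index)
    return ProfileDataset(numeric, channel_meta, feature_meta)


def read_marker_table(path, *, delimiter: str = "\t") -> MarkerAnnotation:
    """Read a two-column (accession, class) marker annotation table."""
    table = pd.read_csv(path, sep=delimiter, dtype=str)
    acc_col, cls_col = table.columns[:2]
    labels = dict(zip(table[acc_col], table[cls_col]))
    return MarkerAnnotation(labels=labels)


# -- preprocessing ----------------------------------------------------------


def sum_normalize_rows(table):
    """Divide each row by its (non-missing) sum so rows sum to one.

    Accepts a DataFrame, ndarray or :class:`ProfileDataset` and returns the
    same type.  Rows whose observed entries sum to zero (or are all missing)
    raise, naming the offending rows.  Idempotent.
    """
    if isinstance(table, ProfileDataset):
        return replace(table, matrix=sum_normalize_rows(table.matrix))
    arr = np.asarray(table, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sums = np.nansum(arr, axis=1)
    all_missing = np.all(np.isnan(arr), axis=1)
    bad = (sums <= 0) | all_missing
    if bad.any():
        if isinstance(table, pd.DataFrame):
            names = table.index[bad].tolist()
        else:
            names = np.flatnonzero(bad).tolist()
        raise ValueError(f"rows with non-positive or all-missing sum: {names}")
    out = arr / sums[:, None]
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(out, index=table.index, columns=table.columns)
    return out


def aggregate_protein_groups(psm_table: pd.DataFrame, group_ids) -> pd.DataFrame:
    """Aggregate sum-normalised PSM rows into protein groups by channel-wise median.

    No renormalisation is applied after aggregation; the aggregated rows are
    the protein-group quantitation values as-is.
    """
    group_ids = pd.Series(np.asarray(group_ids), index=psm_table.index)
    if group_ids.empty or psm_table.empty:
        raise ValueError("empty PSM table or group ids")
    if len(group_ids) != len(psm_table):
        raise ValueError("group_ids length does not match PSM table")
    agg = psm_table.groupby(group_ids, sort=True).median()
    agg.index.name = "accession"
    return agg


def filter_complete_profiles(dataset: ProfileDataset) -> ProfileDataset:
    """Keep only proteins with a full reporter ion series (no missing values)."""
    keep = ~dataset.matrix.isna().any(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_complete_profiles: removed %d incomplete rows", n_removed)
    if not keep.any():
        warnings.warn("all rows removed: no protein has a complete profile", stacklevel=2)
    return ProfileDataset(
        dataset.matrix.loc[keep],
        dataset.channel_meta.copy(),
        dataset.feature_meta.loc[keep],
    )


def drop_channels(dataset: ProfileDataset, channel_ids) -> ProfileDataset:
    """Remove named channels (e.g. low-ion-intensity reporter channels)."""
    channel_ids = list(channel_ids)
    unknown = [c for c in channel_ids if c not in dataset.matrix.columns]
    if unknown:
        raise ValueError(f"unknown channel ids: {unknown}")
    keep = [c for c in dataset.matrix.columns if c not in set(channel_ids)]
    if not keep:
        raise ValueError("cannot drop all channels")
    return ProfileDataset(
        dataset.matrix[keep], dataset.channel_meta.loc[keep], dataset.feature_meta.copy()
    )


def remove_contaminants(dataset: ProfileDataset, contaminants) -> ProfileDataset:
    """Remove rows whose accession appears in a contaminant (cRAP) list."""
    contaminants = set(contaminants)
    keep = ~dataset.matrix.index.isin(contaminants)
    return ProfileDataset(
        dataset.matrix.loc[keep], dataset.channel_meta.copy(), dataset.feature_meta.loc[keep]
    )


def concatenate_replicates(datasets: list[ProfileDataset]) -> ProfileDataset:
    """Join replicate datasets on their common accessions, stacking channels.

    Every input must be complete.  Marker labels must agree across replicates
    for shared accessions; channel ids are suffixed with the replicate index
    when they collide.
    """
    if not datasets:
        raise ValueError("no datasets given")
    if len(datasets) == 1:
        return datasets[0].copy()
    for i, d in enumerate(datasets):
        if not d.is_complete():
            raise ValueError(f"dataset {i} has missing values; filter before concatenating")
    common = datasets[0].matrix.index
    for d in datasets[1:]:
        common = common.intersection(d.matrix.index)
    if common.empty:
        raise ValueError("no shared accessions across replicates")

    mats, metas = [], []
    for i, d in enumerate(datasets, start=1):
        m = d.matrix.loc[common].copy()
        cm = d.channel_meta.copy()
        cm["replicate"] = i
        new_cols = [f"{c}.rep{i}" for c in m.columns]
        m.columns = new_cols
        cm.index = pd.Index(new_cols)
        mats.append(m)
        metas.append(cm)

    label0 = datasets[0].feature_meta.loc[common, "marker_class"]
    for i, d in enumerate(datasets[1:], start=2):
        lab = d.feature_meta.loc[common, "marker_class"]
        conflict = (label0 != lab) & (label0 != UNKNOWN) & (lab != UNKNOWN)
        if conflict.any():
            raise ValueError(
                f"conflicting marker labels for {common[conflict].tolist()[:5]}"
            )
        label0 = label0.where(label0 != UNKNOWN, lab)

    feature_meta = datasets[0].feature_meta.loc[common].copy()
    feature_meta["marker_class"] = label0
    return ProfileDataset(pd.concat(mats, axis=1), pd.concat(metas, axis=0), feature_meta)


def merge_marker_classes(
    markers: MarkerAnnotation, merge_map: dict[str, str]
) -> MarkerAnnotation:
    """Collapse fine marker classes into coarser ones via ``merge_map``.

    Classes not mentioned in the map are kept.  The merged class order keeps
    the position of the first fine class mapping onto each coarse class.
    """
    unknown = set(merge_map) - set(markers.classes)
    if unknown:
        raise ValueError(f"merge_map references unknown classes: {sorted(unknown)}")
    new_labels = {a: merge_map.get(c, c) for a, c in markers.labels.items()}
    new_classes: list[str] = []
    for c in markers.classes:
        target = merge_map.get(c, c)
        if target not in new_classes:
            new_classes.append(target)
    return MarkerAnnotation(labels=new_labels, classes=new_classes)


# -- PCA --------------------------------------------------------------------


def pca_project(dataset: ProfileDataset, n_components: int | None = None) -> PcaResult:
    """Mean-centred SVD projection of the profile matrix.

    Profiles are already on a common ratio scale, so only mean-centring is
    applied (no unit-variance scaling).  The sign of each component is fixed
    so that its largest-magnitude channel loading is positive, making plots
    reproducible across runs and libraries.
    """
    if not dataset.is_complete():
        raise ValueError("PCA requires a complete dataset; filter first")
    X = dataset.values()
    max_rank = min(X.shape)
    if n_components is None:
        n_components = max_rank
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds rank bound {max_rank}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    var_frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=dataset.matrix.index, columns=comp_names),
        loadings=pd.DataFrame(Vt[:n_components], index=comp_names, columns=dataset.matrix.columns),
        variance_fraction=var_frac,
    )


def write_pca_scores(result: PcaResult, path) -> None:
    """Write PCA scores as TSV with the variance fractions in a header comment."""
    with open(path, "w") as fh:
        fractions = "\t".join(f"{v:.6g}" for v in result.variance_fraction)
        fh.write(f"# variance_fraction\t{fractions}\n")
        result.scores.rename_axis("accession").to_csv(fh, sep="\t")


# -- map agreement ----------------------------------------------------------


def agreement_matrix(
    labels_a: pd.Series,
    labels_b: pd.Series,
    class_map: dict[str, str] | None = None,
    *,
    exclude: pd.Index | None = None,
):
    """Contingency table and percent agreement between two assignment maps.

    ``labels_a``/``labels_b`` map accession -> final class label (``unknown``
    allowed and ignored).  ``class_map`` translates dataset-B classes into
    dataset-A vocabulary (e.g. ``chromatin -> nucleus/chromatin``) before
    comparison.  ``exclude`` drops accessions (e.g. markers) from the
    comparison.  Only proteins classified in *both* maps enter the table.

    Returns ``(table, percent_agreement, n_compared)``.
    """
    class_map = class_map or {}
    shared = labels_a.index.intersection(labels_b.index)
    if exclude is not None:
        shared = shared.difference(exclude)
    a = labels_a.loc[shared]
    b = labels_b.loc[shared].map(lambda c: class_map.get(c, c))
    both = (a != UNKNOWN) & (b != UNKNOWN)
    if not both.any():
        raise ValueError("no shared proteins classified in both maps")
    a, b = a[both], b[both]
    table = pd.crosstab(a, b, rownames=["map_a"], colnames=["map_b"])
    agree = int((a == b).sum())
    pct = 100.0 * agree / len(a)
    return table, pct, len(a)
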