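"""Sample-space PCA, consensus temporal profiles, k-means clustering, contrasts.

The 14 samples (2 culture conditions x 7 days) are ordinated by PCA to
visualise developmental trajectories; genes are grouped by k-means (default
k = 6) on their standardized consensus 7-point profiles; and each cluster
receives a High/Low day grouping that drives cluster-specific differential
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .matrix import CODED_X, CONDITIONS, DAYS, ExpressionMatrix

__all__ = [
    "TrajectoryMatrix",
    "PCAResult",
    "ClusterResult",
    "ContrastGroups",
    "pca_samples",
    "consensus_profiles",
    "kmeans_profiles",
    "define_contrasts",
    "contrasts_from_centroids",
]


@dataclass
class TrajectoryMatrix:
    """Per-gene ordered 7-point profiles per condition plus their consensus.

    Each profile DataFrame is genes x days (columns are calendar days in
    order); ``consensus`` is the elementwise mean of the two conditions.
    """

    x: np.ndarray
    days: tuple[int, ...]
    profiles: dict[str, pd.DataFrame]
    consensus: pd.DataFrame = field(repr=False)

    @property
    def gene_ids(self) -> pd.Index:
        return self.consensus.index

    def condition(self, cond: str) -> pd.DataFrame:
        return self.profiles[cond]

    def stacked(self) -> pd.DataFrame:
        """Genes x 14 matrix: the 5X profile followed by the 10X profile."""
        parts = [self.profiles[c].add_prefix(f"{c}_d") for c in CONDITIONS]
        return pd.concat(parts, axis=1)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # genes x components
    explained_variance_ratio: np.ndarray

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series        # gene_id -> cluster label (0..k-1)
    centroids: pd.DataFrame       # k x n_features, mean of standardized members
    inertia: float
    seed: int

    def members(self, label: int) -> pd.Index:
        return self.assignments.index[self.assignments == label]

    def to_tsv(self, path) -> None:
        self.assignments.rename("cluster").to_csv(path, sep="\t", index_label="gene_id")


def pca_samples(m: ExpressionMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the samples in gene space, after per-gene mean-centering.

    Components are ordered by decreasing variance; for reproducibility each
    component's sign is fixed so that its largest-magnitude gene loading is
    positive.
    """
    if m.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > m.n_samples - 1:
        raise ValueError(
            f"n_components={n_components} exceeds samples-1={m.n_samples - 1}"
        )
    X = m.values.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)          # center each gene
    # samples are observations: SVD of the samples x genes matrix
    U, S, Vt = np.linalg.svd(X.T, full_matrices=False)
    total_var = float((S**2).sum())
    ratio = (S**2) / total_var if total_var > 0 else np.zeros_like(S)
    scores = U * S
    loadings = Vt.T
    for j in range(min(n_components, S.size)):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores[:, :n_components], index=m.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings[:, :n_components], index=m.gene_ids, columns=comp_names),
        explained_variance_ratio=ratio[:n_components],
    )


def consensus_profiles(m: ExpressionMatrix) -> TrajectoryMatrix:
    """Pivot the time course into per-condition 7-point profiles and their mean."""
    meta = m.sample_meta
    if not {"condition", "day"}.issubset(meta.columns):
        raise ValueError("sample metadata must contain 'condition' and 'day'")
    missing = [
        (c, d)
        for c in CONDITIONS
        for d in DAYS
        if not ((meta["condition"] == c) & (meta["day"] == d)).any()
    ]
    if missing:
        raise ValueError(f"missing condition-day cells: {missing}")
    profiles: dict[str, pd.DataFrame] = {}
    for c in CONDITIONS:
        cols = [meta.index[(meta["condition"] == c) & (meta["day"] == d)][0] for d in DAYS]
        prof = m.values[cols].copy()
        prof.columns = list(DAYS)
        profiles[c] = prof
    consensus = (profiles["5X"] + profiles["10X"]) / 2.0
    return TrajectoryMatrix(x=CODED_X.copy(), days=DAYS, profiles=profiles, consensus=consensus)


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd[:, 0] == 0)[0]
    if zero.size:
        raise ValueError(f"constant profile(s) cannot be standardized: {df.index[zero[:5]].tolist()}")
    return pd.DataFrame((vals - mean) / sd, index=df.index, columns=df.columns)


def kmeans_profiles(
    t: TrajectoryMatrix,
    k: int = 6,
    seed: int = 0,
    n_restarts: int = 10,
    use_consensus: bool = True,
) -> ClusterResult:
    """k-means on standardized gene profiles (k-means++ with restarts).

    By default clusters the consensus 7-point profiles; with
    ``use_consensus=False`` the full 14-sample vector (both conditions
    concatenated) is clustered instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    feats = _standardize(t.consensus if use_consensus else t.stacked())
    n_distinct = np.unique(feats.to_numpy().round(12), axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct profiles")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(feats.to_numpy())
    assignments = pd.Series(labels, index=feats.index, name="cluster")
    centroids = pd.DataFrame(
        [feats.to_numpy()[labels == j].mean(axis=0) for j in range(k)],
        columns=feats.columns,
    )
    return ClusterResult(k=k, assignments=assignments, centroids=centroids,
                         inertia=float(km.inertia_), seed=seed)


@dataclass(frozen=True)
class ContrastGroups:
    """Per-cluster High/Low day sets (both conditions pooled), or a skip flag."""

    high_days: tuple[int, ...] = ()
    low_days: tuple[int, ...] = ()
    skip: bool = False


def contrasts_from_centroids(c: ClusterResult, oscillation_crossings: int = 3) -> dict[int, ContrastGroups]:
    """Derive a High/Low day grouping per cluster from its centroid shape.

    Days where the (standardized) centroid is above zero form the High
    group, the rest the Low group.  Centroids whose sign changes
    ``oscillation_crossings`` or more times across the time course are
    flagged as oscillatory and skipped, mirroring the practice of not
    interpreting clusters with undefined oscillatory patterns.
    """
    out: dict[int, ContrastGroups] = {}
    try:
        days = np.array([int(d) for d in c.centroids.columns])
    except (TypeError, ValueError) as exc:
        raise ValueError("centroid columns must be calendar days (cluster on consensus profiles)") from exc
    for label in range(c.k):
        cent = c.centroids.iloc[label].to_numpy()
        signs = np.sign(cent)
        crossings = int((np.diff(signs[signs != 0]) != 0).sum())
        high = tuple(days[cent > 0].tolist())
        low = tuple(days[cent <= 0].tolist())
        skip = crossings >= oscillation_crossings or not high or not low
        out[label] = ContrastGroups(high, low, skip)
    return out


def define_contrasts(
    c: ClusterResult,
    spec_table: dict[int, ContrastGroups],
    sample_meta: pd.DataFrame,
) -> dict[int, tuple[list[str], list[str]]]:
    """Resolve per-cluster High/Low day sets into sample-ID groups.

    Both conditions' samples at the listed days are included.  Clusters
    flagged ``skip`` are omitted from the result.
    """
    known_days = set(sample_meta["day"].tolist())
    out: dict[int, tuple[list[str], list[str]]] = {}
    for label, grp in spec_table.items():
        if grp.skip:
            continue
        if set(grp.high_days) & set(grp.low_days):
            raise ValueError(f"cluster {label}: High and Low day sets overlap")
        if not grp.high_days or not grp.low_days:
            raise ValueError(f"cluster {label}: High and Low groups must be nonempty")
        unknown = (set(grp.high_days) | set(grp.low_days)) - known_days
        if unknown:
            raise ValueError(f"cluster {label}: days {sorted(unknown)} not in metadata")
        high = sample_meta.index[sample_meta["day"].isin(grp.high_days)].tolist()
        low = sample_meta.index[sample_meta["day"].isin(grp.low_days)].tolist()
        out[label] = (high, low)
    return out
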