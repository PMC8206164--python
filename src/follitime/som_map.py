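"""Batch self-organizing map for expression-trajectory subsetting.

A small rectangular lattice of prototype vectors (default 3×3, giving nine
gene subsets) is trained by deterministic batch updates with a shrinking
Gaussian neighborhood on standardized per-gene profiles — here the
14-sample vector with both culture conditions concatenated, so that
5X-vs-10X shape differences remain visible to the map.  Codebooks are
initialized on the grid spanned by the first two principal components,
making training fully reproducible without randomness; a seeded random
initialization is available as a fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["SOMModel", "train_som", "merge_similar_nodes"]


@dataclass
class SOMModel:
    grid_rows: int
    grid_cols: int
    codebooks: np.ndarray                 # (rows*cols) x n_features
    assignments: pd.Series                # gene_id -> node index (row-major)
    seed: int
    epochs: int
    quantization_errors: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    def node_coords(self, node: int) -> tuple[int, int]:
        return divmod(node, self.grid_cols)

    def members(self, node: int) -> pd.Index:
        return self.assignments.index[self.assignments == node]

    def node_mean_profiles(self, data: pd.DataFrame) -> np.ndarray:
        """Mean member profile per node; empty nodes fall back to the codebook."""
        out = self.codebooks.copy()
        for node in range(self.n_nodes):
            members = self.members(node)
            if len(members):
                out[node] = data.loc[members].to_numpy(dtype=float).mean(axis=0)
        return out

    def to_tsv(self, path) -> None:
        rows, cols = zip(*(self.node_coords(n) for n in self.assignments))
        df = pd.DataFrame(
            {"node_row": rows, "node_col": cols, "subset_id": self.assignments},
            index=self.assignments.index,
        )
        df.to_csv(path, sep="\t", index_label="gene_id")


def _grid_distances(rows: int, cols: int) -> np.ndarray:
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    return cdist(coords, coords)


def _pca_init(X: np.ndarray, rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Codebooks spanning the grid of the first two principal components."""
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    if S.size < 2 or S[1] <= 1e-12:
        # degenerate data: jitter around the mean
        return mean + rng.normal(0.0, 1e-3, size=(rows * cols, X.shape[1]))
    # fix component signs for reproducibility
    for j in range(2):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
    scale1, scale2 = S[0] / np.sqrt(n), S[1] / np.sqrt(n)
    r_pos = np.linspace(-1, 1, rows) if rows > 1 else np.array([0.0])
    c_pos = np.linspace(-1, 1, cols) if cols > 1 else np.array([0.0])
    books = np.array(
        [
            mean + rp * scale1 * Vt[0] + cp * scale2 * Vt[1]
            for rp in r_pos
            for cp in c_pos
        ]
    )
    return books


def train_som(
    data: pd.DataFrame,
    grid_rows: int = 3,
    grid_cols: int = 3,
    seed: int = 0,
    epochs: int = 30,
    sigma_start: float = 0.6,
    sigma_end: float = 0.15,
    init: str = "pca",
    repair_dead_units: bool = True,
) -> SOMModel:
    """Train a batch SOM on per-gene profiles (rows standardized beforehand).

    Each epoch assigns every gene to its best-matching node, then replaces
    every codebook by the neighborhood-weighted mean of all profiles, with
    the Gaussian neighborhood radius shrinking linearly from ``sigma_start``
    to ``sigma_end``.  The PCA-grid initialization already lays the lattice
    out along the two leading components, so the neighborhood can start
    narrow; a node left without members after an update is reseeded at the
    profile farthest from its own codebook (deterministic dead-unit repair),
    so well-separated pattern groups each claim a node instead of doubling
    up.  Final assignments are nearest-codebook.  Deterministic for a fixed
    seed.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    X = data.to_numpy(dtype=float)
    n_nodes = grid_rows * grid_cols
    n_distinct = np.unique(X.round(12), axis=0).shape[0]
    if n_distinct < n_nodes:
        warnings.warn(
            f"only {n_distinct} distinct profiles for {n_nodes} nodes; some nodes may stay empty",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    if init == "pca":
        books = _pca_init(X, grid_rows, grid_cols, rng)
    elif init == "random":
        books = X[rng.choice(X.shape[0], size=n_nodes, replace=X.shape[0] < n_nodes)]
        books = books + rng.normal(0.0, 1e-6, size=books.shape)
    else:
        raise ValueError(f"unknown init {init!r}")

    gdist = _grid_distances(grid_rows, grid_cols)
    qe_history: list[float] = []
    n_obs = X.shape[0]
    for epoch in range(epochs):
        d = cdist(X, books)
        bmu = d.argmin(axis=1)
        qe_history.append(float(d[np.arange(n_obs), bmu].mean()))
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma_start + (sigma_end - sigma_start) * frac
        H = np.exp(-(gdist**2) / (2.0 * sigma**2))    # n_nodes x n_nodes
        W = H[bmu]                                     # n_genes x n_nodes
        denom = W.sum(axis=0)
        num = W.T @ X
        nonzero = denom > 1e-300
        books[nonzero] = num[nonzero] / denom[nonzero, None]
        if repair_dead_units and n_obs >= n_nodes:
            d = cdist(X, books)
            bmu = d.argmin(axis=1)
            for node in range(n_nodes):
                if not (bmu == node).any():
                    far = int(np.argmax(d[np.arange(n_obs), bmu]))
                    books[node] = X[far]
                    d[:, node] = np.linalg.norm(X - X[far], axis=1)
                    bmu = d.argmin(axis=1)

    d = cdist(X, books)
    bmu = d.argmin(axis=1)
    qe_history.append(float(d[np.arange(X.shape[0]), bmu].mean()))
    empty = [n for n in range(n_nodes) if not (bmu == n).any()]
    if empty:
        warnings.warn(f"empty SOM nodes: {empty}", stacklevel=2)
    assignments = pd.Series(bmu, index=data.index, name="subset_id")
    return SOMModel(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        codebooks=books,
        assignments=assignments,
        seed=seed,
        epochs=epochs,
        quantization_errors=qe_history,
    )


def merge_similar_nodes(
    model: SOMModel, data: pd.DataFrame, correlation_threshold: float = 0.95
) -> dict[int, list[str]]:
    """Union nodes whose mean member profiles correlate above the threshold.

    Merging is by transitive closure (union-find), so chains of similar
    nodes collapse into one subset.  Returns subset ID (smallest member
    node index) -> gene list; the subsets partition all assigned genes.
    """
    profiles = model.node_mean_profiles(data)
    n = model.n_nodes
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = profiles[i], profiles[j]
            if np.std(pi) == 0 or np.std(pj) == 0:
                continue
            if np.corrcoef(pi, pj)[0, 1] > correlation_threshold:
                union(i, j)

    out: dict[int, list[str]] = {}
    for gene, node in model.assignments.items():
        out.setdefault(find(int(node)), []).append(gene)
    return out
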