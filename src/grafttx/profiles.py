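"""Expression-profile analyses: log-ratio profiles, Ward clustering, PCA, SOM.

Sample-level structure is assessed on log2 ratios of each grafted/wounded
condition against the intact control; gene-level profile shape is
summarised with a batch-trained self-organizing map (SOM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .expression import ConditionMatrix


@dataclass
class RatioMatrix:
    """Genes x non-intact conditions, values log2((x_t + c)/(x_intact + c))."""

    data: pd.DataFrame  # columns: MultiIndex (treatment, time_dag)
    species: str
    pseudocount: float


def ratio_profiles(
    cond: ConditionMatrix, species: str, pseudocount: float = 1.0
) -> RatioMatrix:
    """log2 expression ratio of every (treatment, time) condition vs intact.

    The intact column compared against itself is identically zero and is
    not emitted; exactly the non-intact conditions of the species appear.
    """
    cols = [c for c in cond.data.columns if c[0] == species]
    if (species, "intact", 0) not in cond.data.columns:
        raise KeyError(f"no intact column for species {species!r}")
    intact = cond.data[(species, "intact", 0)].to_numpy()
    out = {}
    for _, treatment, t in cols:
        if treatment == "intact":
            continue
        x = cond.data[(species, treatment, t)].to_numpy()
        out[(treatment, t)] = np.log2((x + pseudocount) / (intact + pseudocount))
    df = pd.DataFrame(out, index=cond.data.index)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=("treatment", "time_dag"))
    return RatioMatrix(df, species, pseudocount)


@dataclass
class Dendrogram:
    """Agglomerative merge history under Ward's minimum-variance criterion.

    ``merges`` lists (member_a, member_b, height, new_cluster_id) where
    leaves are 0..n-1, internal nodes n..2n-2, and height is the increase
    in total within-cluster sum of squares caused by the merge.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def ward_cluster(vectors: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Hierarchical clustering (Euclidean distance, Ward linkage) of rows.

    Heights are reported as the within-cluster sum-of-squares increase of
    each merge, so heights are non-decreasing and identical-point merges
    sit at exactly zero.
    """
    if isinstance(vectors, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in vectors.index]
        X = vectors.to_numpy(dtype=float)
    else:
        X = np.asarray(vectors, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("ward_cluster needs >= 2 equal-length vectors")
    Z = hierarchy.linkage(X, method="ward")
    # scipy reports sqrt(2 * delta-SSE); convert back to the SSE increase.
    n = X.shape[0]
    merges = [
        (int(a), int(b), float(h) ** 2 / 2.0, n + k)
        for k, (a, b, h, _) in enumerate(Z)
    ]
    return Dendrogram(merges, list(labels))


def dendrogram_to_newick(d: Dendrogram) -> str:
    """Serialize as Newick with branch lengths = parent height − child height."""
    heights = {i: 0.0 for i in range(d.n_leaves)}
    nodes = {i: d.labels[i] for i in range(d.n_leaves)}
    for a, b, h, new_id in d.merges:
        la = nodes.pop(a)
        lb = nodes.pop(b)
        nodes[new_id] = f"({la}:{h - heights[a]:.6g},{lb}:{h - heights[b]:.6g})"
        heights[new_id] = h
    (root,) = nodes.values()
    return root + ";"


@dataclass
class PCAResult:
    """Principal-component scores per sample and variance fractions."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_fractions: np.ndarray
    components: np.ndarray  # k x n_features, orthonormal rows


def pca(vectors: pd.DataFrame | np.ndarray, n_components: int | None = None) -> PCAResult:
    """PCA of the mean-centred rows (no per-feature scaling).

    Computed by singular-value decomposition; variance fractions are the
    eigenvalue shares of the covariance matrix.  Degenerate input whose
    rows are all identical yields all-zero fractions rather than an error.
    Component signs follow the largest-absolute-loading-positive
    convention so reruns are deterministic.
    """
    if isinstance(vectors, pd.DataFrame):
        index = list(vectors.index)
        X = vectors.to_numpy(dtype=float)
    else:
        X = np.asarray(vectors, dtype=float)
        index = list(range(X.shape[0]))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca needs >= 2 samples")
    n, m = X.shape
    k = min(n - 1, m) if n_components is None else min(n_components, n - 1, m)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, : U.shape[1]]
    var = S**2 / (n - 1)
    total = var.sum()
    fractions = var[:k] / total if total > 0 else np.zeros(k)
    scores = (U[:, :k] * S[:k]) if total > 0 else np.zeros((n, k))
    return PCAResult(
        pd.DataFrame(scores, index=index, columns=[f"PC{i + 1}" for i in range(k)]),
        np.asarray(fractions, dtype=float),
        Vt[:k],
    )


@dataclass
class SOMResult:
    """Trained self-organizing map.

    grid_shape
        (rows, cols) of the rectangular node grid.
    codebooks
        (rows*cols) x n_features prototype vectors, row-major node order.
    assignments
        Best-matching node index per input profile (ties -> lowest index).
    qe_trace
        Quantization error (mean squared Euclidean distance of profiles
        to their best-matching node), one entry per epoch; non-increasing
        by construction.
    """

    grid_shape: tuple[int, int]
    codebooks: np.ndarray
    assignments: np.ndarray
    qe_trace: np.ndarray

    def node_coords(self) -> np.ndarray:
        r, c = self.grid_shape
        return np.array([(i // c, i % c) for i in range(r * c)], dtype=float)


def _bmu(X: np.ndarray, codebooks: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - codebooks[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def train_som(
    profiles: pd.DataFrame | np.ndarray,
    grid: tuple[int, int] = (4, 4),
    epochs: int = 50,
    seed: int = 0,
) -> SOMResult:
    """Batch-train a rectangular SOM on expression profiles.

    Each epoch assigns every profile to its best-matching node (Euclidean
    distance) and replaces every codebook by the Gaussian-neighborhood-
    weighted mean of the data; the neighborhood radius shrinks linearly
    from half the grid diagonal to 0.5, so late epochs approach plain
    k-means refinement.  An epoch whose smoothed update would raise the
    quantization error falls back to the radius-zero (per-node centroid)
    update, which cannot raise it, so the recorded error trace is
    non-increasing.  Codebooks are initialised by sampling data rows with
    the given seed; the whole run is deterministic.
    """
    X = profiles.to_numpy(dtype=float) if isinstance(profiles, pd.DataFrame) else np.asarray(
        profiles, dtype=float
    )
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("train_som needs at least one profile")
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)
    codebooks = X[rng.integers(0, X.shape[0], size=n_nodes)].copy()
    coords = np.array([(i // cols, i % cols) for i in range(n_nodes)], dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    r0 = max(np.sqrt((rows - 1) ** 2 + (cols - 1) ** 2) / 2.0, 0.5)
    qe_trace: list[float] = []
    bmu = _bmu(X, codebooks)

    def _qe(books, assign):
        return float(((X - books[assign]) ** 2).sum(axis=1).mean())

    for epoch in range(epochs):
        frac = epoch / (epochs - 1) if epochs > 1 else 1.0
        radius = r0 + (0.5 - r0) * frac
        # Gaussian neighborhood truncated at the current radius: once the
        # radius drops below the grid spacing only the BMU is updated, so
        # the final phase is an exact k-means refinement
        H = np.exp(-grid_d2 / (2.0 * radius**2)) * (grid_d2 <= radius**2)
        for weights in (H[:, bmu], np.eye(n_nodes)[:, bmu]):
            new_books = codebooks.copy()
            wsum = weights.sum(axis=1)
            active = wsum > 1e-12
            new_books[active] = (weights[active] @ X) / wsum[active, None]
            new_bmu = _bmu(X, new_books)
            qe = _qe(new_books, new_bmu)
            if not qe_trace or qe <= qe_trace[-1]:
                break  # smoothed update accepted; else retry with radius 0
        codebooks, bmu = new_books, new_bmu
        qe_trace.append(min(qe, qe_trace[-1]) if qe_trace else qe)
    return SOMResult((rows, cols), codebooks, bmu, np.asarray(qe_trace))
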