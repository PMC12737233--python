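"""Channel reduction, inter-subject DTW dissimilarity, and MDS embedding.

PCA is fitted across the three IMU channels with all subjects' time points
pooled as observations, so each subject's representative stride stays a
time series after projection (m channels x L samples).  Classic
unconstrained dynamic time warping with dependent multivariate Euclidean
local cost then yields the inter-subject dissimilarity matrix, optionally
fused with a Euclidean block on cohort-standardized age and height.  Metric
MDS (SMACOF stress majorization) turns the matrix into coordinates for the
algorithms that need a vector space.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

from .config import ReducerConfig
from .types import DissimilarityMatrix, Embedding, RepresentativeGait


def reduce_channels(
    reps: list[RepresentativeGait], config: ReducerConfig
) -> tuple[np.ndarray, object]:
    """Project every subject's 3xL curve onto m principal channels.

    The PCA sample matrix pools all subjects and time points as rows of the
    3 channel values; m is the smallest component count whose cumulative
    explained variance reaches ``config.variance_target``.  Returns an
    (n_subjects, L, m) array and the fitted reducer.

    For method "tsne" no channel reduction is meaningful (a t-SNE embedding
    is not a time series); subjects are embedded directly into 2-D points
    and downstream distances fall back to Euclidean.  That route is a
    documented deviation kept only for completeness.
    """
    if len(reps) < 2:
        raise ValueError("need at least 2 subjects")
    curves = np.stack([r.curves for r in reps])  # (n, 3, L)
    n, c, L = curves.shape
    pooled = curves.transpose(0, 2, 1).reshape(n * L, c)
    if np.allclose(pooled.var(axis=0), 0.0):
        raise ValueError("degenerate zero-variance curves")

    if config.method == "tsne":
        from sklearn.manifold import TSNE

        flat = curves.reshape(n, c * L)
        perpl = max(2.0, min(30.0, (n - 1) / 3.0))
        emb = TSNE(
            n_components=2, random_state=config.random_seed, perplexity=perpl,
            init="pca",
        ).fit_transform(flat)
        return emb[:, None, :], None  # (n, 1, 2): one "time point" per subject

    pca = PCA(n_components=c, random_state=config.random_seed)
    pca.fit(pooled)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, config.variance_target - 1e-12) + 1)
    m = min(m, c)
    proj = pca.transform(pooled)[:, :m].reshape(n, L, m)
    return proj, pca


@njit(cache=False)
def _dtw_from_cost(cost: np.ndarray) -> float:
    """Classic DP over a precomputed local-cost matrix; steps match/insert/delete,
    no warping window."""
    n, m = cost.shape
    big = 1e300
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = big
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = big
        for j in range(1, m + 1):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = cost[i - 1, j - 1] + best
        for j in range(m + 1):
            prev[j] = cur[j]
    return prev[m]


def _local_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) Euclidean distances across channels."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff * diff).sum(axis=2))


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Unconstrained DTW distance between two (length, channels) series.

    Local cost is the Euclidean distance across channels; the optimal
    cumulative cost over all monotone alignments is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"channel mismatch: {a.shape[1]} vs {b.shape[1]}")
    return float(_dtw_from_cost(np.ascontiguousarray(_local_cost(a, b))))


def _maxmin_rescale(D: np.ndarray) -> np.ndarray:
    """Rescale off-diagonal entries to [0, 1]; constant matrices map to 0."""
    n = D.shape[0]
    if n < 2:
        return np.zeros_like(D)
    off = D[~np.eye(n, dtype=bool)]
    lo, hi = off.min(), off.max()
    if hi - lo <= 0:
        out = np.zeros_like(D)
        return out
    out = (D - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return np.clip(out, 0.0, None)


def pairwise_dissimilarity(
    series: np.ndarray,
    subject_ids: list,
    basic: np.ndarray | None = None,
    mode: str = "waveform_only",
    fusion_weight: float = 1.0,
) -> DissimilarityMatrix:
    """Inter-subject dissimilarity matrix.

    ``series`` is (n, L, m).  In "waveform_only" mode the matrix holds raw
    DTW distances.  In "waveform_plus_basic" mode both the DTW block and a
    Euclidean block on cohort-standardized age/height are max-min rescaled
    to [0, 1] and added, the basic block weighted by ``fusion_weight``.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(series[i], series[j])

    if mode == "waveform_only":
        return DissimilarityMatrix(D, list(subject_ids), mode, 0.0)
    if mode != "waveform_plus_basic":
        raise ValueError(f"unknown mode {mode!r}")
    if basic is None:
        raise ValueError("waveform_plus_basic mode requires the age/height table")
    basic = np.asarray(basic, dtype=float)
    if basic.shape[0] != n or not np.all(np.isfinite(basic)):
        raise ValueError("age/height table must be complete for fused mode")
    sd = basic.std(axis=0)
    sd[sd == 0] = 1.0
    z = (basic - basic.mean(axis=0)) / sd
    diff = z[:, None, :] - z[None, :, :]
    Db = np.sqrt((diff * diff).sum(axis=2))
    fused = _maxmin_rescale(D) + fusion_weight * _maxmin_rescale(Db)
    return DissimilarityMatrix(fused, list(subject_ids), mode, fusion_weight)


def mds_embed(D: DissimilarityMatrix, d: int = 5, seed: int = 0) -> Embedding:
    """Metric least-squares MDS (SMACOF) of a dissimilarity matrix."""
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    if np.allclose(D.D, 0.0):
        return Embedding(np.zeros((D.n, d)), 0.0, D.subject_ids)
    mds = MDS(
        n_components=d,
        metric="precomputed",
        metric_mds=True,
        n_init=8,
        init="random",
        max_iter=3000,
        eps=1e-9,
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(D.D)
    return Embedding(coords, float(mds.stress_), D.subject_ids)
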