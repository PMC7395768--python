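"""Similarity network fusion and spectral subtyping of irradiated samples.

The pipeline: (1) keep the 10% of features per data level most correlated
(absolute Pearson r) with MED; (2) build a scaled-exponential affinity per
level from Euclidean distances on standardized features; (3) fuse the levels
by iterative cross-diffusion (each level's kernel is propagated through the
average of the other levels' kernels, restricted to k-nearest-neighbor
support); (4) spectral-cluster the fused network, with the cluster number
chosen by the eigen-gap of the normalized Laplacian spectrum.

Affinity: with d the pairwise Euclidean distance,
``eps_ij = (mean d(i, kNN(i)) + mean d(j, kNN(j)) + d(i,j)) / 3`` and
``W(i,j) = exp(-d(i,j)^2 / (alpha * eps_ij))``.

Fusion: per level, the full kernel P has off-diagonal rows normalized to sum
1/2 with diagonal 1/2; the sparse kernel S is row-normalized over the k
nearest neighbors and zero elsewhere. Each of t iterations updates
``P_v <- S_v @ mean_{u != v}(P_u) @ S_v.T`` followed by re-normalization and
symmetrization; the output is the level average, symmetrized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

EPS_FLOOR = 1e-12


@dataclass
class FusionParams:
    """SNF hyperparameters (defaults as used for the 32-subject cohort)."""

    k: int = 10                 # neighbor count
    t: int = 20                 # diffusion iterations
    alpha: float = 0.5          # kernel scale
    prefilter_fraction: float = 0.10

    def validate(self, n_samples: int | None = None) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 < self.prefilter_fraction <= 1:
            raise ValueError("prefilter_fraction must lie in (0, 1]")
        if n_samples is not None and self.k >= n_samples:
            raise ValueError(f"k ({self.k}) must be < n_samples ({n_samples})")


@dataclass
class FusedNetwork:
    """Symmetric non-negative sample x sample similarity after cross-diffusion."""

    matrix: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        W = self.matrix
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.sample_ids):
            raise ValueError("fused matrix shape does not match sample ids")
        if np.abs(W - W.T).max() > 1e-10:
            raise ValueError("fused matrix is not symmetric within 1e-10")
        if (W < 0).any():
            raise ValueError("fused matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids,
                            columns=self.sample_ids)


def prefilter_by_med_correlation(matrix: pd.DataFrame, med: pd.Series,
                                 fraction: float) -> pd.DataFrame:
    """Keep the ceil(fraction * n) features most |Pearson r|-correlated with MED.

    Ties are broken by feature id (lexicographic), making the selection
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(matrix) < 2:
        raise ValueError("prefilter needs >= 2 input features")
    med_v = med.reindex(matrix.columns).to_numpy(dtype=float)
    if np.isnan(med_v).any():
        raise ValueError("MED missing for some samples")
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    mc = med_v - med_v.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (mc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, xc @ mc / np.where(denom > 0, denom, 1.0), 0.0)
    n_keep = max(1, int(np.ceil(fraction * len(matrix))))
    order = sorted(range(len(matrix)),
                   key=lambda i: (-abs(r[i]), str(matrix.index[i])))
    keep = sorted(order[:n_keep], key=lambda i: i)  # preserve original order
    return matrix.iloc[keep]


def build_affinity(data: pd.DataFrame, params: FusionParams,
                   standardize: bool = True) -> pd.DataFrame:
    """Scaled-exponential kernel affinity from one data level.

    ``data`` is sample x feature. Features are standardized (z across
    samples) before the Euclidean distance unless ``standardize=False``.
    """
    n = len(data)
    params.validate(n_samples=n)
    x = data.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    # mean distance to the k nearest neighbors (excluding self)
    d_sorted = np.sort(d, axis=1)[:, 1: params.k + 1]
    mu = d_sorted.mean(axis=1)
    eps = (mu[:, None] + mu[None, :] + d) / 3.0
    eps = np.maximum(eps, EPS_FLOOR)
    W = np.exp(-(d ** 2) / (params.alpha * eps))
    W = (W + W.T) / 2.0
    return pd.DataFrame(W, index=data.index, columns=data.index)


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Off-diagonal mass row-normalized to 1/2, diagonal set to 1/2."""
    P = W.copy().astype(float)
    np.fill_diagonal(P, 0.0)
    rows = P.sum(axis=1)
    rows[rows == 0] = 1.0
    P = P / (2.0 * rows[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def _sparse_kernel(W: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic kernel restricted to the k nearest neighbors."""
    n = W.shape[0]
    S = np.zeros_like(W, dtype=float)
    for i in range(n):
        w = W[i].copy()
        w[i] = -np.inf  # self excluded from the neighborhood
        nn = np.argsort(-w)[:k]
        S[i, nn] = W[i, nn]
    rows = S.sum(axis=1)
    rows[rows == 0] = 1.0
    return S / rows[:, None]


def snf_fuse(affinities: list, params: FusionParams) -> FusedNetwork:
    """Cross-diffusion fusion of >= 2 per-level affinity matrices."""
    if len(affinities) < 2:
        raise ValueError("fusion needs >= 2 affinity matrices")
    ids = list(affinities[0].index)
    for W in affinities[1:]:
        if list(W.index) != ids or list(W.columns) != ids:
            raise ValueError("affinity matrices have mismatched sample ids")
    params.validate(n_samples=len(ids))
    Ws = [W.to_numpy(dtype=float) for W in affinities]
    Ps = [_full_kernel(W) for W in Ws]
    Ss = [_sparse_kernel(W, params.k) for W in Ws]
    m = len(Ps)
    for _ in range(params.t):
        new = []
        for v in range(m):
            others = sum(Ps[u] for u in range(m) if u != v) / (m - 1)
            P = Ss[v] @ others @ Ss[v].T
            P = (P + P.T) / 2.0
            new.append(_full_kernel(P))
        Ps = new
    fused = sum(Ps) / m
    fused = (fused + fused.T) / 2.0
    return FusedNetwork(matrix=fused, sample_ids=ids)


def _normalized_laplacian(W: np.ndarray) -> np.ndarray:
    deg = W.sum(axis=1)
    zero = np.where(deg <= 0)[0]
    if len(zero):
        raise ValueError(f"isolated sample(s) with zero degree at index {zero.tolist()}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = -W * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(L, 1.0 + np.diag(L))
    return (L + L.T) / 2.0


def spectral_cluster(network: FusedNetwork, n_clusters: int,
                     seed: int = 0, n_init: int = 50) -> pd.Series:
    """Normalized spectral clustering of the fused network.

    Embeds samples with the eigenvectors of the ``n_clusters`` smallest
    eigenvalues of the symmetric normalized Laplacian, row-normalizes the
    embedding, and runs k-means with ``n_init`` restarts. Labels are
    canonicalized so the first-occurring cluster is 0, the next 1, ...
    """
    n = len(network.sample_ids)
    if not 2 <= n_clusters < n:
        raise ValueError(f"n_clusters must satisfy 2 <= K < {n}")
    W = network.matrix
    ids = network.sample_ids
    zero = [ids[i] for i in np.where(W.sum(axis=1) <= 0)[0]]
    if zero:
        raise ValueError(f"isolated sample(s): {zero}")
    L = _normalized_laplacian(W)
    _, vec = eigh(L, subset_by_index=[0, n_clusters - 1])
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = vec / norms
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    raw = km.fit_predict(emb)
    # canonicalize by first occurrence
    remap, nxt = {}, 0
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        labels[i] = remap[lab]
    return pd.Series(labels, index=ids, name="subtype")


def estimate_cluster_number(network: FusedNetwork, k_min: int = 2,
                            k_max: int = 5) -> tuple[int, pd.Series]:
    """Eigen-gap choice of the cluster number.

    With Laplacian eigenvalues sorted ascending, eigengap(K) =
    lambda_{K+1} - lambda_K; the best K maximizes the gap over
    [k_min, k_max], smallest K on ties.
    """
    n = len(network.sample_ids)
    if not 1 <= k_min <= k_max < n:
        raise ValueError("need 1 <= k_min <= k_max < n_samples")
    L = _normalized_laplacian(network.matrix)
    vals = np.sort(eigh(L, eigvals_only=True))
    ks = np.arange(k_min, k_max + 1)
    gaps = pd.Series(vals[ks] - vals[ks - 1], index=ks, name="eigengap")
    best = int(gaps.index[np.argmax(gaps.to_numpy())])  # argmax -> first/smallest K
    return best, gaps


def subtype_cohort(expr_log_irr: pd.DataFrame, meth_m_irr: pd.DataFrame,
                   med: pd.Series, params: FusionParams | None = None,
                   n_clusters: int | None = None, seed: int = 0):
    """Full subtyping path on irradiated samples: prefilter -> affinity per
    level -> fusion -> eigen-gap -> spectral clustering.

    Returns dict with the fused network, best_k, eigengaps and labels.
    """
    params = params or FusionParams()
    levels = []
    for mat in (expr_log_irr, meth_m_irr):
        kept = prefilter_by_med_correlation(mat, med, params.prefilter_fraction)
        levels.append(build_affinity(kept.T, params))
    fused = snf_fuse(levels, params)
    best_k, gaps = estimate_cluster_number(fused)
    k = n_clusters if n_clusters is not None else best_k
    labels = spectral_cluster(fused, k, seed=seed)
    return {"network": fused, "best_k": best_k, "eigengaps": gaps,
            "labels": labels}
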