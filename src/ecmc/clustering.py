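"""Normalized spectral clustering with replicated k-means.

The clustering step runs on the linear sum of the per-view consensus kernels,
C = sum_i C_i, using the symmetric-normalization variant of spectral
clustering (Ng–Jordan–Weiss): form D^{-1/2} C D^{-1/2} with D the degree
matrix, take the top-k eigenvectors, normalize the rows of the resulting
n-by-k embedding to unit length, and run k-means on the rows. Because
k-means is sensitive to initialization, it is restarted ``n_replicates``
times from seeded random initializations; all replicate labelings are
retained (metrics are averaged over replicates downstream) and the replicate
with the lowest within-cluster sum of squares is reported as the consensus
labeling.

Consensus kernels can carry small negative eigenvalues or near-zero degrees;
the affinity is made usable by shifting K <- K - lambda_min(K) I when
lambda_min < 0 and, if any degree is still non-positive, adding a small
ridge to the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import KernelMatrix

__all__ = ["ClusteringResult", "combine_consensus", "spectral_cluster"]


@dataclass
class ClusteringResult:
    """Labels, spectral embedding, and per-replicate k-means outcomes."""

    labels: np.ndarray          # consensus assignment, values in 1..k
    embedding: np.ndarray       # (n, k) row-normalized spectral coordinates
    replicate_labels: np.ndarray  # (n_replicates, n)
    replicate_inertia: np.ndarray  # within-cluster sum of squares per replicate
    replicate_count: int
    seed: int


def combine_consensus(C_list: list[KernelMatrix | np.ndarray]) -> KernelMatrix:
    """Elementwise sum of consensus kernels; trace = number of views."""
    if not C_list:
        raise ValueError("empty kernel list")
    vals = [C.values if isinstance(C, KernelMatrix) else np.asarray(C, float)
            for C in C_list]
    shape = vals[0].shape
    for i, v in enumerate(vals):
        if v.shape != shape:
            raise ValueError(f"kernel {i} has shape {v.shape}, expected {shape}")
    return KernelMatrix(np.sum(vals, axis=0), kind="reconstructed")


def _spectral_embedding(K: np.ndarray, k: int) -> np.ndarray:
    """NJW embedding: top-k eigenvectors of D^-1/2 K D^-1/2, rows unit-norm."""
    n = K.shape[0]
    eigmin = float(np.linalg.eigvalsh(K)[0])
    if eigmin < 0:
        K = K - eigmin * np.eye(n)
    deg = K.sum(axis=1)
    min_deg = deg.min()
    if min_deg <= 0:
        ridge = 1e-10 - min_deg
        K = K + ridge * np.eye(n)
        deg = K.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(deg)
    L = K * np.outer(d_isqrt, d_isqrt)
    vals, vecs = np.linalg.eigh((L + L.T) / 2.0)
    U = vecs[:, -k:]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return U / norms


def _kmeans_replicates(
    X: np.ndarray, k: int, n_replicates: int, seed: int, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd k-means restarted ``n_replicates`` times, vectorized over restarts.

    Each replicate draws a k-means++-style random initialization from its own
    deterministic substream of ``seed``; all replicates then run Lloyd
    iterations in lockstep (batched numpy) until every one is converged. An
    emptied cluster is re-seeded at the point farthest from its replicate's
    centers. Returns (labels (R, n) 1-based, within-cluster sum of squares (R,)).
    """
    n, d = X.shape
    R = n_replicates
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # k-means++ init, batched: one center chain per replicate
    centers = np.empty((R, k, d))
    first = rng.integers(n, size=R)
    centers[:, 0] = X[first]
    closest = np.sum((X[None, :, :] - centers[:, 0, None, :]) ** 2, axis=2)  # (R, n)
    for j in range(1, k):
        tot = closest.sum(axis=1, keepdims=True)
        prob = np.where(tot > 0, closest / np.where(tot == 0, 1, tot), 1.0 / n)
        cum = np.cumsum(prob, axis=1)
        u = rng.random((R, 1))
        idx = (u > cum).sum(axis=1).clip(max=n - 1)
        centers[:, j] = X[idx]
        dist_new = np.sum((X[None, :, :] - centers[:, j, None, :]) ** 2, axis=2)
        closest = np.minimum(closest, dist_new)

    labels = np.zeros((R, n), dtype=np.int64)
    for _ in range(max_iter):
        # squared distances (R, n, k)
        d2 = (np.einsum("rkd,rkd->rk", centers, centers)[:, None, :]
              - 2.0 * np.einsum("nd,rkd->rnk", X, centers)
              + np.einsum("nd,nd->n", X, X)[None, :, None])
        new_labels = d2.argmin(axis=2)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        onehot = np.eye(k)[labels]                     # (R, n, k)
        counts = onehot.sum(axis=1)                    # (R, k)
        sums = np.einsum("rnk,nd->rkd", onehot, X)
        empty = counts == 0
        if empty.any():
            # re-seed empty clusters at the farthest point from current centers
            far = d2.min(axis=2).argmax(axis=1)        # (R,)
            for r, kk in zip(*np.nonzero(empty)):
                sums[r, kk] = X[far[r]]
                counts[r, kk] = 1
        centers = sums / counts[:, :, None]
    d2 = (np.einsum("rkd,rkd->rk", centers, centers)[:, None, :]
          - 2.0 * np.einsum("nd,rkd->rnk", X, centers)
          + np.einsum("nd,nd->n", X, X)[None, :, None])
    inertia = np.take_along_axis(d2, labels[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    return labels + 1, np.maximum(inertia, 0.0)


def spectral_cluster(
    K: KernelMatrix | np.ndarray,
    k: int,
    n_replicates: int = 100,
    seed: int = 0,
) -> ClusteringResult:
    """Normalized spectral clustering of a kernel with replicated k-means.

    Replicate seeds derive deterministically from ``seed``: the same seed
    reproduces every replicate labeling bit-for-bit. Labels are 1-based.
    """
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    n = Kv.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if np.abs(Kv - Kv.T).max() > 1e-8:
        raise ValueError("kernel must be symmetric")

    if k == 1:
        labels = np.ones(n, dtype=int)
        emb = np.ones((n, 1))
        reps = np.tile(labels, (n_replicates, 1))
        return ClusteringResult(labels, emb, reps, np.zeros(n_replicates),
                                n_replicates, seed)

    emb = _spectral_embedding(Kv, k)
    rep_labels, inertia = _kmeans_replicates(emb, k, n_replicates, seed)
    best = int(np.argmin(inertia))
    return ClusteringResult(
        labels=rep_labels[best].copy(),
        embedding=emb,
        replicate_labels=rep_labels,
        replicate_inertia=inertia,
        replicate_count=n_replicates,
        seed=seed,
    )
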