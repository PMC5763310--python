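"""Synthetic two-view datasets with known ground truth.

Two generator families mirror the evaluation protocol the models were
designed around; both build each view by stacking a *consensus* feature
block A_i on top of a *disagreement* block B_i over the same n samples, so
the shared cluster signal and the view-specific interference are controlled
separately.

Family 1 (scaled permuted block): n = 100 two-dimensional samples from a
two-component Gaussian mixture (means mu1 = [-4, 3], mu2 = [7, -8], shared
covariance diag(10, 5); 50 samples per component, ground truth = first half
vs second half). Per-view white noise of strength (sd) 1 gives A_1 and A_2.
B_i is a column-permuted copy of A_i (an independent uniform permutation per
view) with fresh noise — the same marginal structure but scrambled sample
identity, i.e. pure disagreement. All four blocks are row-normalized to zero
mean and unit norm, then X_i = [A_i; t * B_i]. The scale t >= 0 dials the
disagreement strength: t = 0 leaves only consensus signal, t = 2 makes the
disagreement dominate the raw kernels.

Family 2 (exchanged samples): A_1, A_2 from a second mixture (means [0, 1]
and [11, -10], identity covariance), built the same way. B_1 and B_2
exchange s samples between the views at scrambled positions: s source
columns of A_2 (random, without replacement) overwrite s random target
positions in B_1, and symmetrically for B_2 from A_1. Because source and
target positions are drawn independently, an exchanged sample lands in the
other component's half about half the time, so the B-blocks carry cluster
identities that conflict with the truth for ~s samples and the two views'
kernel agreement decreases monotonically in s; X_i = [A_i; B_i], no scale
factor. (Exchanging at aligned positions would be a near no-op — both
views' column j come from the same mixture component — and could not
produce the degradation with s that motivates the design.)

All randomness flows through one seeded generator per dataset; a fixed seed
reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .kernels import ViewSet, KernelMatrix, normalize_features

__all__ = ["SimulationSpec", "LabeledViewSet", "simulate1", "simulate2",
           "block_kernel_fixture"]

SIM1_MEANS = (np.array([-4.0, 3.0]), np.array([7.0, -8.0]))
SIM1_COV = np.diag([10.0, 5.0])
SIM2_MEANS = (np.array([0.0, 1.0]), np.array([11.0, -10.0]))
SIM2_COV = np.eye(2)


@dataclass
class SimulationSpec:
    """Full parameterization of one synthetic two-view dataset."""

    family: str                      # "sim1" | "sim2"
    n: int = 100
    mean1: tuple = (0.0, 0.0)
    mean2: tuple = (0.0, 0.0)
    cov: tuple = ((1.0, 0.0), (0.0, 1.0))
    noise_sd: float = 1.0
    t: float | None = None           # sim1 disagreement scale
    s: int | None = None             # sim2 exchanged-sample count
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class LabeledViewSet:
    """A ViewSet together with its ground-truth two-class labels."""

    views: ViewSet
    truth: np.ndarray
    spec: SimulationSpec


def _mixture_base(mean1, mean2, cov, n: int, rng) -> np.ndarray:
    """(2, n) draw: first n/2 columns from component 1, rest from component 2."""
    half = n // 2
    s1 = rng.multivariate_normal(mean1, cov, size=half)
    s2 = rng.multivariate_normal(mean2, cov, size=n - half)
    return np.vstack([s1, s2]).T


def simulate1(t: float, seed: int = 0, n: int = 100,
              noise_sd: float = 1.0) -> LabeledViewSet:
    """Scaled-permuted-block dataset X_i = [A_i; t*B_i], two 4-by-n views."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if n % 2:
        raise ValueError("n must be even (equal-size clusters)")
    rng = np.random.default_rng(seed)
    base = _mixture_base(*SIM1_MEANS, SIM1_COV, n, rng)
    views = []
    for _ in range(2):
        A = base + noise_sd * rng.standard_normal((2, n))
        perm = rng.permutation(n)
        B = A[:, perm] + noise_sd * rng.standard_normal((2, n))
        A = normalize_features(A, "row_zero_mean_unit_norm")
        B = normalize_features(B, "row_zero_mean_unit_norm")
        views.append(np.vstack([A, t * B]))
    spec = SimulationSpec(
        family="sim1", n=n,
        mean1=tuple(SIM1_MEANS[0]), mean2=tuple(SIM1_MEANS[1]),
        cov=tuple(map(tuple, SIM1_COV)), noise_sd=noise_sd, t=t, seed=seed)
    truth = np.repeat([1, 2], n // 2)
    return LabeledViewSet(ViewSet(views), truth, spec)


def simulate2(s: int, seed: int = 0, n: int = 100,
              noise_sd: float = 1.0) -> LabeledViewSet:
    """Exchanged-samples dataset X_i = [A_i; B_i] with s swapped columns."""
    if not 0 <= s <= n // 2:
        raise ValueError(f"s must be in [0, {n // 2}], got {s}")
    if n % 2:
        raise ValueError("n must be even (equal-size clusters)")
    rng = np.random.default_rng(seed)
    base = _mixture_base(*SIM2_MEANS, SIM2_COV, n, rng)
    A1 = base + noise_sd * rng.standard_normal((2, n))
    A2 = base + noise_sd * rng.standard_normal((2, n))
    B1, B2 = A1.copy(), A2.copy()
    # exchange s samples between the views at scrambled positions
    tgt1, src2 = rng.choice(n, size=s, replace=False), rng.choice(n, size=s, replace=False)
    tgt2, src1 = rng.choice(n, size=s, replace=False), rng.choice(n, size=s, replace=False)
    B1[:, tgt1] = A2[:, src2]
    B2[:, tgt2] = A1[:, src1]
    blocks = [normalize_features(M, "row_zero_mean_unit_norm")
              for M in (A1, A2, B1, B2)]
    views = [np.vstack([blocks[0], blocks[2]]), np.vstack([blocks[1], blocks[3]])]
    spec = SimulationSpec(
        family="sim2", n=n,
        mean1=tuple(SIM2_MEANS[0]), mean2=tuple(SIM2_MEANS[1]),
        cov=tuple(map(tuple, SIM2_COV)), noise_sd=noise_sd, s=int(s), seed=seed)
    truth = np.repeat([1, 2], n // 2)
    return LabeledViewSet(ViewSet(views), truth, spec)


def block_kernel_fixture(
    block_sizes: list[int],
    within: float = 1.0,
    between: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[KernelMatrix, np.ndarray]:
    """Block-constant kernel plus optional symmetric noise, PSD-projected.

    A unit-test fixture: with ``noise_sd = 0`` the top-k eigenvectors are
    exact block indicators, so spectral clustering must recover the blocks.
    Requires ``within > between >= 0``.
    """
    if not within > between >= 0:
        raise ValueError("need within > between >= 0")
    n = int(sum(block_sizes))
    K = np.full((n, n), float(between))
    truth = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(block_sizes, start=1):
        K[start:start + size, start:start + size] = within
        truth[start:start + size] = b
        start += size
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        E = rng.standard_normal((n, n)) * noise_sd
        K = K + (E + E.T) / 2.0
        vals, vecs = np.linalg.eigh(K)
        K = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        K = (K + K.T) / 2.0
    return KernelMatrix(K, kind="input"), truth
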