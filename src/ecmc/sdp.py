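"""The shared trace-maximization subproblem over the spectraplex.

Every block update of both the CMC and the ECMC model reduces to

    max  tr(M C)   s.t.  C >= 0 (PSD),  tr(C) = 1,

a linear program over the unit-trace PSD simplex ("spectraplex"). Its optimum
is the largest eigenvalue of M, attained at the top eigenprojector: for a
simple top eigenvalue, C* = v v^T with v the unit top eigenvector; when
lambda_max has multiplicity r (within a degeneracy tolerance), the uniform
average of the top-r eigenprojectors, C* = (1/r) sum_j v_j v_j^T, is returned
— a deterministic, symmetric choice that is still optimal and invariant to
the sign/rotation ambiguity of the individual eigenvectors.

The closed eigen form is the primary solver. An independent numerical route
(``method="sdp"``) solves the same semidefinite program through a
Burer–Monteiro factorization C = L L^T / tr(L L^T) maximized with L-BFGS;
it serves as a cross-check, not as the production path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["SubproblemResult", "max_trace_psd"]

#: eigenvalues within this relative distance of lambda_max count as tied
DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class SubproblemResult:
    """Optimizer of max tr(MC) over the spectraplex."""

    C_star: np.ndarray
    objective: float
    method: str

    def certify(self, tol: float = 1e-8) -> None:
        """Post-hoc feasibility certificate: PSD and unit trace."""
        eigmin = float(np.linalg.eigvalsh(self.C_star)[0])
        if eigmin < -tol:
            raise AssertionError(f"C* not PSD: min eigenvalue {eigmin:.2e}")
        tr = float(np.trace(self.C_star))
        if abs(tr - 1.0) > tol:
            raise AssertionError(f"C* trace {tr!r} deviates from 1")


def _check_symmetric(M: np.ndarray, tol: float) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"M must be square, got shape {M.shape}")
    if not np.isfinite(M).all():
        raise ValueError("M contains NaN/Inf")
    asym = np.abs(M - M.T).max()
    scale = max(1.0, np.abs(M).max())
    if asym > tol * scale:
        raise ValueError(f"M asymmetry {asym:.2e} exceeds tolerance")
    return (M + M.T) / 2.0


def _solve_eigen(M: np.ndarray) -> tuple[np.ndarray, float]:
    vals, vecs = np.linalg.eigh(M)
    lam_max = vals[-1]
    gap = DEGENERACY_RTOL * max(1.0, abs(lam_max))
    top = vals >= lam_max - gap
    V = vecs[:, top]  # (n, r) orthonormal
    r = V.shape[1]
    C = (V @ V.T) / r
    return (C + C.T) / 2.0, float(lam_max)


def _solve_bm(M: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """Burer–Monteiro: maximize tr(M L L^T)/tr(L L^T) over full-rank L."""
    n = M.shape[0]
    rng = np.random.default_rng(seed)
    L0 = rng.standard_normal((n, n))

    def neg(x: np.ndarray) -> tuple[float, np.ndarray]:
        L = x.reshape(n, n)
        G = L @ L.T
        tr = np.trace(G)
        obj = np.sum(M * G) / tr
        # d/dL of tr(MG)/tr(G) = 2(M L tr(G) - tr(MG) L)/tr(G)^2
        grad = 2.0 * (M @ L - obj * L) / tr
        return -obj, -grad.ravel()

    res = minimize(neg, L0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
    L = res.x.reshape(n, n)
    C = L @ L.T
    C /= np.trace(C)
    C = (C + C.T) / 2.0
    return C, float(np.sum(M * C))


def max_trace_psd(
    M: np.ndarray,
    tol: float = 1e-8,
    method: str = "eigen",
    seed: int = 0,
) -> SubproblemResult:
    """Maximize tr(MC) over unit-trace PSD matrices C.

    Parameters
    ----------
    M : (n, n) symmetric matrix
        Symmetrized as (M + M^T)/2 if the asymmetry is within ``tol``,
        rejected otherwise.
    method : {"eigen", "sdp"}
        "eigen" (default) is the exact top-eigenprojector closed form;
        "sdp" runs the Burer–Monteiro numerical solve of the same program
        (cross-check route).
    seed : int
        Initialization seed for the "sdp" route (ignored by "eigen").
    """
    M = _check_symmetric(M, tol)
    if method == "eigen":
        C, obj = _solve_eigen(M)
    elif method == "sdp":
        C, obj = _solve_bm(M, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    result = SubproblemResult(C_star=C, objective=obj, method=method)
    result.certify(tol=max(tol, 1e-8))
    return result
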