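"""First-order structured antedependence (SAD(1)) residual covariance.

SAD(1) lets each timepoint's residual depend on the immediately preceding
one: eps_t = rho * eps_{t-1} + eta_t with eta_t ~ N(0, phi2) and eps_0 = 0.
This yields nonstationary variances

    sigma2(t)      = phi2 * (1 - rho^(2t)) / (1 - rho^2)
    sigma(t1, t2)  = rho^(t2 - t1) * phi2 * (1 - rho^(2 t1)) / (1 - rho^2)

with t the 1-based integer rank on the analysis grid.  The implied
covariance factorises as Sigma = phi2 * A^-1 A^-T where A is the unit
lower-bidiagonal whitening operator (1 on the diagonal, -rho on the first
subdiagonal), giving O(T) whitening, log|Sigma| = T log phi2, and exact
solves without dense factorisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve


@dataclass(frozen=True)
class SADParams:
    """Innovation variance phi2 > 0 and antedependence rho in (-1, 1)."""

    phi2: float
    rho: float

    def __post_init__(self):
        if not np.isfinite(self.phi2) or self.phi2 <= 0:
            raise ValueError(f"innovation variance must be positive, got {self.phi2}")
        if not np.isfinite(self.rho) or abs(self.rho) >= 1:
            raise ValueError(f"antedependence must satisfy |rho| < 1, got {self.rho}")


def sad1_variances(params: SADParams, T: int) -> np.ndarray:
    """Marginal variances sigma2(t) for t = 1..T."""
    t = np.arange(1, T + 1)
    if params.rho == 0.0:
        return np.full(T, params.phi2)
    return params.phi2 * (1.0 - params.rho ** (2 * t)) / (1.0 - params.rho**2)


def sad1_covariance(params: SADParams, T: int) -> np.ndarray:
    """Dense T x T SAD(1) covariance matrix (1-based time ranks)."""
    if T < 1:
        raise ValueError(f"need at least one timepoint, got T={T}")
    var = sad1_variances(params, T)
    t = np.arange(1, T + 1)
    # sigma(t1,t2) = rho^(t2-t1) sigma2(min(t1,t2))
    lag = np.abs(t[:, None] - t[None, :])
    vmin = np.minimum(var[:, None], var[None, :])
    if params.rho == 0.0:
        return np.diag(var)
    return params.rho**lag * vmin


def whitening_operator(rho: float, T: int) -> np.ndarray:
    """Unit lower-bidiagonal A with A Sigma A' = phi2 * I."""
    A = np.eye(T)
    idx = np.arange(1, T)
    A[idx, idx - 1] = -rho
    return A


def whiten(rho: float, y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply the AR(1) differencing (A y)_t = y_t - rho y_{t-1} along ``axis``.

    After whitening, SAD(1)-correlated residuals become iid N(0, phi2).
    """
    y = np.asarray(y, dtype=float)
    z = y.copy()
    sl_t = [slice(None)] * y.ndim
    sl_tm1 = [slice(None)] * y.ndim
    sl_t[axis] = slice(1, None)
    sl_tm1[axis] = slice(None, -1)
    z[tuple(sl_t)] -= rho * y[tuple(sl_tm1)]
    return z


def sad1_logdet_and_solve(params: SADParams, T: int, rhs: np.ndarray):
    """log|Sigma| and Sigma^-1 rhs via the analytic factorisation.

    Sigma = phi2 A^-1 A^-T with |A| = 1, hence log|Sigma| = T log phi2 and
    Sigma^-1 rhs = A' A rhs / phi2.
    """
    rhs = np.asarray(rhs, dtype=float)
    if not np.all(np.isfinite(rhs)):
        raise ValueError("right-hand side contains non-finite values")
    if rhs.shape[0] != T:
        raise ValueError(f"rhs has leading dimension {rhs.shape[0]}, expected {T}")
    logdet = T * np.log(params.phi2)
    A = whitening_operator(params.rho, T)
    sol = A.T @ (A @ rhs) / params.phi2
    return logdet, sol


def sad1_logdet_and_solve_dense(params: SADParams, T: int, rhs: np.ndarray):
    """Dense-Cholesky reference path for the analytic solve."""
    sigma = sad1_covariance(params, T)
    c, low = cho_factor(sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return logdet, cho_solve((c, low), np.asarray(rhs, dtype=float))


def stage_block_covariance(params: SADParams, stage_lengths, per_stage: bool = False):
    """Covariance over the concatenated stage grid.

    By default a single SAD chain runs over the full concatenated grid
    (physical time is continuous across treatment phases).  With
    ``per_stage=True`` each stage gets an independent chain (block
    diagonal), restarting the antedependence at each phase change.
    """
    total = int(sum(stage_lengths))
    if not per_stage:
        return sad1_covariance(params, total)
    out = np.zeros((total, total))
    off = 0
    for T in stage_lengths:
        out[off : off + T, off : off + T] = sad1_covariance(params, int(T))
        off += int(T)
    return out
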