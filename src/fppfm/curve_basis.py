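"""Legendre orthogonal polynomial (LOP) basis for genotype mean curves.

Trajectories within each treatment stage are modelled as linear
combinations of Legendre polynomials P_0..P_k evaluated on the stage's
time grid rescaled to [-1, 1].  Each stage carries its own rescaling, so
the fitted mean curve is a piecewise-polynomial over the full treatment
course with independent coefficients per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
from numpy.polynomial import legendre as _leg


def rescale_time(t, t_min: float, t_max: float):
    """Affinely map time ``t`` in [t_min, t_max] onto tau in [-1, 1].

    tau = -1 + 2 (t - t_min) / (t_max - t_min); the first and last times
    of the stage map exactly to -1 and +1.
    """
    if not t_max > t_min:
        raise ValueError(f"degenerate time grid: t_min={t_min!r} >= t_max={t_max!r}")
    t = np.asarray(t, dtype=float)
    return -1.0 + 2.0 * (t - t_min) / (t_max - t_min)


def legendre_value(k: int, tau):
    """Value of the k-th Legendre polynomial at tau (stable recurrence)."""
    if k < 0:
        raise ValueError(f"polynomial order must be non-negative, got {k}")
    coeffs = np.zeros(k + 1)
    coeffs[k] = 1.0
    return _leg.legval(np.asarray(tau, dtype=float), coeffs)


def legendre_value_sum(k: int, tau) -> float:
    """Closed-form factorial-sum evaluation of P_k(tau).

    P_k(tau) = 2^-k * sum_{r=0}^{floor(k/2)} (-1)^r (2k-2r)! /
               (r! (k-r)! (k-2r)!) tau^(k-2r)

    Numerically inferior to the three-term recurrence for large k; kept as
    an independent cross-check of :func:`legendre_value`.
    """
    if k < 0:
        raise ValueError(f"polynomial order must be non-negative, got {k}")
    tau = float(tau)
    total = 0.0
    for r in range(k // 2 + 1):
        num = factorial(2 * k - 2 * r)
        den = factorial(r) * factorial(k - r) * factorial(k - 2 * r)
        total += (-1) ** r * num / den * tau ** (k - 2 * r)
    return total / 2**k


def design_matrix(times, k: int) -> np.ndarray:
    """LOP design matrix: row t = (P_0(tau_t), ..., P_k(tau_t)).

    ``times`` must be strictly increasing; its endpoints define the
    rescaling to [-1, 1].  Column 0 is all ones and the last row is all
    ones (P_k(1) = 1).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("time grid must be strictly increasing")
    if times.size == 1:
        tau = np.array([0.0])
    else:
        tau = rescale_time(times, times[0], times[-1])
    cols = [legendre_value(j, tau) for j in range(k + 1)]
    return np.column_stack(cols)


@dataclass
class LOPBasis:
    """Per-stage LOP basis over a stage's raw time grid.

    Attributes
    ----------
    order : polynomial order k (columns 0..k).
    times : raw stage times, strictly increasing.
    tau : times rescaled to [-1, 1].
    design : (T, k+1) evaluation matrix.
    """

    order: int
    times: np.ndarray
    tau: np.ndarray = field(init=False)
    design: np.ndarray = field(init=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.design = design_matrix(self.times, self.order)
        if self.times.size == 1:
            self.tau = np.array([0.0])
        else:
            self.tau = rescale_time(self.times, self.times[0], self.times[-1])

    @property
    def n_times(self) -> int:
        return self.times.size

    def evaluate(self, coeffs) -> np.ndarray:
        """Mean curve on the stage grid for coefficient vector v."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape[-1] != self.order + 1:
            raise ValueError(
                f"expected {self.order + 1} coefficients, got {coeffs.shape[-1]}"
            )
        return self.design @ coeffs

    def derivative_design(self) -> np.ndarray:
        """Design matrix of dP_j/dt on the stage grid (chain rule through tau)."""
        if self.times.size < 2:
            return np.zeros((self.times.size, self.order + 1))
        dtau_dt = 2.0 / (self.times[-1] - self.times[0])
        cols = []
        for j in range(self.order + 1):
            c = np.zeros(j + 1)
            c[j] = 1.0
            dc = _leg.legder(c)
            cols.append(_leg.legval(self.tau, dc) * dtau_dt)
        return np.column_stack(cols)
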