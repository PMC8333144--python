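"""Joint likelihood, genotype-specific mean curves, and ML fitting.

The observation model: individual i in genotype class j has trajectory
y_i ~ N(mu_j, Sigma) over the concatenated (trait, stage, time) grid, with
mu_j built from per-stage Legendre polynomial coefficient vectors v_lsj and
Sigma a SAD(1) covariance shared across genotype classes.

Fitting exploits the SAD(1) factorisation Sigma = phi2 A^-1 A^-T: for a
fixed antedependence rho the whitened model is ordinary least squares, so
the coefficient vectors and the innovation variance have closed forms and
the profile likelihood is a smooth 1-D function of rho, maximised by a
bounded Brent search.  A joint Nelder-Mead optimiser over all parameters is
retained as an alternative (`method="nelder-mead"`) and as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from fppfm.curve_basis import LOPBasis
from fppfm.io_data import PhenotypeSeries
from fppfm.sad_covariance import SADParams, stage_block_covariance

logger = logging.getLogger(__name__)

RHO_BOUND = 0.99


class MarkerSkipped(RuntimeError):
    """A genotype class is below the minimum size; the marker is not testable."""


@dataclass
class FitOptions:
    """Knobs for marker fitting."""

    order: int = 4
    method: str = "profile"  # or "nelder-mead"
    per_stage: bool = False  # restart the SAD chain at each stage boundary
    min_group_size: int = 2
    max_restarts: int = 3
    seed: int = 0
    constraint: str = "none"  # none | genotype | stage | trait


@dataclass
class CurveFit:
    """Result of fitting one marker (or the no-QTL null)."""

    order: int
    genotypes: list
    # coefficients[(trait, stage, genotype)] -> (k+1,) vector
    coefficients: dict
    sad: SADParams
    loglik: float
    n_parameters: int
    converged: bool
    n_individuals: int
    traits: list = field(default_factory=list)
    stages: list = field(default_factory=list)
    constraint: str = "none"
    group_sizes: dict = field(default_factory=dict)

    def mean_curve(self, genotype, trait, bases: dict) -> np.ndarray:
        """Fitted mean over the concatenated stage grid for one genotype."""
        return np.concatenate(
            [bases[s].evaluate(self.coefficients[(trait, s, genotype)]) for s in self.stages]
        )


@dataclass
class ModelSelection:
    orders: list
    aics: list
    selected: int


# ---------------------------------------------------------------------------
# grid / design plumbing


@dataclass
class GridLayout:
    """Concatenated (trait-major) grid with whitening-chain structure."""

    traits: list
    stages: list
    stage_lengths: list
    bases: dict  # stage_id -> LOPBasis
    per_stage: bool = False

    @property
    def T(self) -> int:
        return int(sum(self.stage_lengths))

    @property
    def M(self) -> int:
        return self.T * len(self.traits)

    def chain_starts(self) -> np.ndarray:
        """Boolean mask (M,) marking positions where the SAD chain restarts.

        Chains never cross trait blocks; they also restart at stage
        boundaries when ``per_stage`` is set.
        """
        starts = np.zeros(self.M, dtype=bool)
        off = 0
        for _ in self.traits:
            starts[off] = True
            if self.per_stage:
                pos = off
                for T in self.stage_lengths:
                    starts[pos] = True
                    pos += T
            off += self.T
        return starts

    def design(self, order: int, share_stages=False, share_traits=False) -> np.ndarray:
        """Design matrix mapping coefficient blocks to the concatenated grid.

        Default: an independent (k+1)-vector per (trait, stage).  Sharing
        collapses the corresponding blocks (used by the Q-by-E and
        pleiotropy null hypotheses).
        """
        k1 = order + 1
        L, S = len(self.traits), len(self.stages)
        nt = 1 if share_traits else L
        ns = 1 if share_stages else S
        p = nt * ns * k1
        X = np.zeros((self.M, p))
        row = 0
        for li in range(L):
            for si, s in enumerate(self.stages):
                D = self.bases[s].design[:, :k1]
                ci = (0 if share_traits else li) * ns + (0 if share_stages else si)
                X[row : row + D.shape[0], ci * k1 : (ci + 1) * k1] = D
                row += D.shape[0]
        return X

    def coefficient_keys(self, share_stages=False, share_traits=False) -> list:
        keys = []
        for li, tr in enumerate(self.traits):
            for si, s in enumerate(self.stages):
                if (share_traits and li > 0) or (share_stages and si > 0):
                    continue
                keys.append((tr, s))
        return keys


def layout_from_series(phenos: PhenotypeSeries, order: int, per_stage=False,
                       trait_id=None) -> GridLayout:
    grid = phenos.grid()
    traits = [trait_id] if trait_id is not None else phenos.traits
    bases = {s: LOPBasis(order, grid[s]) for s in phenos.stages}
    return GridLayout(
        traits=traits,
        stages=list(phenos.stages),
        stage_lengths=[len(grid[s]) for s in phenos.stages],
        bases=bases,
        per_stage=per_stage,
    )


def mean_vector(coeffs_by_stage, bases) -> np.ndarray:
    """Concatenate design x coefficients over stages for one genotype/trait."""
    out = []
    for v, basis in zip(coeffs_by_stage, bases):
        out.append(basis.evaluate(np.asarray(v, dtype=float)))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# whitening and profile likelihood


def _whiten(x: np.ndarray, rho: float, chain_starts: np.ndarray) -> np.ndarray:
    """(A x)_t = x_t - rho x_{t-1}, restarting at chain starts; axis 0."""
    z = x.astype(float).copy()
    z[1:] -= rho * x[:-1]
    z[chain_starts] = x[chain_starts]
    return z


@dataclass
class _GroupStats:
    """Sufficient statistics of one genotype class for the profile likelihood."""

    n: int
    ybar: np.ndarray  # (M,)
    s_all: float      # sum_i sum_t y_it^2
    s_prev: float     # sum over positions feeding a within-chain lag term
    s_cross: float    # sum_i sum_{t not chain start} y_it y_i,t-1


def _group_stats(Y: np.ndarray, idx: np.ndarray, chain_starts: np.ndarray) -> _GroupStats:
    sub = Y[idx]
    interior = ~chain_starts  # positions with a within-chain predecessor
    prev_mask = np.zeros_like(chain_starts)
    prev_mask[:-1] = interior[1:]
    return _GroupStats(
        n=len(idx),
        ybar=sub.mean(axis=0),
        s_all=float(np.sum(sub**2)),
        s_prev=float(np.sum(sub[:, prev_mask] ** 2)),
        s_cross=float(np.sum(sub[:, interior] * sub[:, np.flatnonzero(interior) - 1])),
    )


def _profile_rss(rho, groups, X, chain_starts):
    """Pooled residual sum of squares in the whitened scale, v profiled out."""
    WX = _whiten(X, rho, chain_starts)
    Q, _ = np.linalg.qr(WX)
    rss = 0.0
    for g in groups:
        wm = _whiten(g.ybar, rho, chain_starts)
        raw = g.s_all + rho**2 * g.s_prev - 2.0 * rho * g.s_cross
        proj = Q.T @ wm
        rss += raw - g.n * float(proj @ proj)
    return rss, Q, WX


def _profile_negll(rho, groups, X, chain_starts, n_tot, M):
    rss, _, _ = _profile_rss(rho, groups, X, chain_starts)
    phi2 = max(rss / (n_tot * M), 1e-300)
    return 0.5 * n_tot * M * (np.log(2 * np.pi) + np.log(phi2) + 1.0)


def _solve_coefficients(rho, groups, X, chain_starts):
    WX = _whiten(X, rho, chain_starts)
    coefs = []
    for g in groups:
        wm = _whiten(g.ybar, rho, chain_starts)
        v, *_ = np.linalg.lstsq(WX, wm, rcond=None)
        coefs.append(v)
    return coefs


# ---------------------------------------------------------------------------
# public likelihood


def joint_log_likelihood(Y: np.ndarray, genotype: np.ndarray, means: dict,
                         params: SADParams, layout: GridLayout,
                         cross_trait_rho: float = 0.0) -> float:
    """Sum of multivariate-normal log-densities over individuals.

    ``means`` maps genotype code -> (M,) mean vector on the concatenated
    grid.  Dense evaluation; used for validation and small problems.  With
    several traits the covariance is R (x) Sigma_time where R has unit
    diagonal and ``cross_trait_rho`` off-diagonal.
    """
    sigma_t = stage_block_covariance(params, layout.stage_lengths, layout.per_stage)
    L = len(layout.traits)
    if L > 1:
        R = np.full((L, L), cross_trait_rho) + (1.0 - cross_trait_rho) * np.eye(L)
        sigma = np.kron(R, sigma_t)
    else:
        sigma = sigma_t
    total = 0.0
    for code, mu in means.items():
        idx = np.flatnonzero(genotype == code)
        if len(idx) == 0:
            continue
        total += float(
            np.sum(stats.multivariate_normal.logpdf(Y[idx], mean=mu, cov=sigma))
        )
    return total


# ---------------------------------------------------------------------------
# fitting


def _split_groups(genotype: np.ndarray, min_group_size: int):
    genotype = np.asarray(genotype, dtype=float)
    usable = ~np.isnan(genotype)
    codes = np.unique(genotype[usable])
    groups = {c: np.flatnonzero(usable & (genotype == c)) for c in codes}
    small = {c: len(ix) for c, ix in groups.items() if len(ix) < min_group_size}
    if small:
        raise MarkerSkipped(
            f"genotype class(es) below minimum size {min_group_size}: {small}"
        )
    return groups


def n_parameters(layout: GridLayout, order: int, J: int, constraint: str) -> int:
    L, S, k1 = len(layout.traits), len(layout.stages), order + 1
    if constraint == "genotype":
        J = 1
    if constraint == "stage":
        S = 1
    if constraint == "trait":
        L = 1
    return J * L * S * k1 + 2


def fit_marker(phenos: PhenotypeSeries, genotype, options: FitOptions | None = None,
               trait_id=None) -> CurveFit:
    """Maximum-likelihood curve fit at one marker.

    ``genotype`` is the per-individual code vector aligned with
    ``phenos.individuals`` (NaN = missing, those individuals are excluded
    from this marker only).  ``options.constraint`` selects the hypothesis:
    "none" (full model), "genotype" (no-QTL null), "stage" (no Q-by-E null)
    or "trait" (pleiotropy null).
    """
    options = options or FitOptions()
    layout = layout_from_series(phenos, options.order, options.per_stage, trait_id)
    _, Y = phenos.to_matrix(trait_id)
    return fit_marker_matrix(Y, np.asarray(genotype, dtype=float), layout, options)


def fit_marker_matrix(Y: np.ndarray, genotype: np.ndarray, layout: GridLayout,
                      options: FitOptions) -> CurveFit:
    """Fit from a pre-built (n, M) matrix; the fast path used by scans."""
    groups = _split_groups(genotype, options.min_group_size)
    codes = sorted(groups)
    share_g = options.constraint == "genotype"
    X = layout.design(
        options.order,
        share_stages=options.constraint == "stage",
        share_traits=options.constraint == "trait",
    )
    chain_starts = layout.chain_starts()
    if share_g:
        stat_groups = [_group_stats(Y, np.concatenate([groups[c] for c in codes]),
                                    chain_starts)]
    else:
        stat_groups = [_group_stats(Y, groups[c], chain_starts) for c in codes]
    n_tot = sum(g.n for g in stat_groups)
    M = layout.M

    if options.method == "profile":
        res = optimize.minimize_scalar(
            _profile_negll,
            bounds=(-RHO_BOUND, RHO_BOUND),
            args=(stat_groups, X, chain_starts, n_tot, M),
            method="bounded",
            options={"xatol": 1e-7},
        )
        rho = float(res.x)
        rss, _, _ = _profile_rss(rho, stat_groups, X, chain_starts)
        phi2 = rss / (n_tot * M)
        loglik = -float(res.fun)
        coefs = _solve_coefficients(rho, stat_groups, X, chain_starts)
        converged = bool(res.success)
    elif options.method == "nelder-mead":
        rho, phi2, loglik, coefs, converged = _fit_nelder_mead(
            stat_groups, X, chain_starts, n_tot, M, options
        )
    else:
        raise ValueError(f"unknown fitting method {options.method!r}")

    coefficients = _unpack_coefficients(coefs, codes, layout, options)
    J = 1 if share_g else len(codes)
    return CurveFit(
        order=options.order,
        genotypes=codes,
        coefficients=coefficients,
        sad=SADParams(phi2=float(phi2), rho=float(rho)),
        loglik=float(loglik),
        n_parameters=n_parameters(layout, options.order, J, options.constraint),
        converged=converged,
        n_individuals=n_tot,
        traits=list(layout.traits),
        stages=list(layout.stages),
        constraint=options.constraint,
        group_sizes={c: int(len(groups[c])) for c in codes},
    )


def _unpack_coefficients(coefs, codes, layout: GridLayout, options: FitOptions) -> dict:
    """Expand packed coefficient vectors to a {(trait, stage, genotype): v} map."""
    k1 = options.order + 1
    share_s = options.constraint == "stage"
    share_t = options.constraint == "trait"
    share_g = options.constraint == "genotype"
    L, S = len(layout.traits), len(layout.stages)
    ns = 1 if share_s else S
    out = {}
    for gi, code in enumerate(codes):
        v = coefs[0] if share_g else coefs[gi]
        for li, tr in enumerate(layout.traits):
            for si, s in enumerate(layout.stages):
                ci = (0 if share_t else li) * ns + (0 if share_s else si)
                out[(tr, s, code)] = v[ci * k1 : (ci + 1) * k1].copy()
    return out


def _fit_nelder_mead(stat_groups, X, chain_starts, n_tot, M, options: FitOptions):
    """Joint simplex optimisation over (v per group, atanh rho, log phi2).

    Initialised from per-group OLS of the mean trajectories; restarts with
    perturbed starts from a fixed seed; one quasi-Newton polish at the end.
    """
    p = X.shape[1]
    G = len(stat_groups)

    def negll(theta):
        rho = np.tanh(theta[-2])
        phi2 = np.exp(theta[-1])
        rss = 0.0
        WX = _whiten(X, rho, chain_starts)
        for gi, g in enumerate(stat_groups):
            v = theta[gi * p : (gi + 1) * p]
            wm = _whiten(g.ybar, rho, chain_starts)
            raw = g.s_all + rho**2 * g.s_prev - 2.0 * rho * g.s_cross
            resid_mean = wm - WX @ v
            # sum_i ||W y_i - WX v||^2 decomposed about the group mean
            rss += (raw - g.n * float(wm @ wm)) + g.n * float(resid_mean @ resid_mean)
        return 0.5 * (n_tot * M * np.log(2 * np.pi * phi2) + rss / phi2)

    # OLS initialisation
    v0 = np.concatenate(
        [np.linalg.lstsq(X, g.ybar, rcond=None)[0] for g in stat_groups]
    )
    resid0 = np.concatenate([g.ybar - X @ v0[i * p : (i + 1) * p]
                             for i, g in enumerate(stat_groups)])
    rho0 = 0.0
    if len(resid0) > 2 and np.var(resid0) > 0:
        rho0 = float(np.clip(
            np.corrcoef(resid0[:-1], resid0[1:])[0, 1], -0.9, 0.9))
        if not np.isfinite(rho0):
            rho0 = 0.0
    phi20 = max(float(np.var(resid0)) * (1 - rho0**2), 1e-8)
    theta0 = np.concatenate([v0, [np.arctanh(rho0), np.log(phi20)]])

    rng = np.random.default_rng(options.seed)
    best = None
    for attempt in range(options.max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, theta0.size)
        res = optimize.minimize(negll, start, method="Nelder-Mead",
                                options={"maxiter": 20000, "fatol": 1e-8, "xatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(negll, best.x, method="BFGS",
                               options={"gtol": 1e-8, "maxiter": 2000})
    if polish.fun <= best.fun:
        best = polish
    theta = best.x
    rho = float(np.tanh(theta[-2]))
    phi2 = float(np.exp(theta[-1]))
    coefs = [theta[i * p : (i + 1) * p] for i in range(G)]
    return rho, phi2, -float(best.fun), coefs, bool(np.isfinite(best.fun))


# ---------------------------------------------------------------------------
# order selection


def select_order_aic(phenos: PhenotypeSeries, genotype, k_range,
                     options: FitOptions | None = None) -> ModelSelection:
    """Pick the LOP order minimising AIC = -2 lnL + 2 dim; ties -> smaller k."""
    options = options or FitOptions()
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("empty order range")
    orders, aics = [], []
    for k in k_range:
        try:
            fit = fit_marker(phenos, genotype, replace(options, order=k))
        except (MarkerSkipped, np.linalg.LinAlgError) as exc:
            logger.warning("order %d failed: %s", k, exc)
            continue
        if not fit.converged:
            continue
        orders.append(k)
        aics.append(-2.0 * fit.loglik + 2.0 * fit.n_parameters)
    if not orders:
        raise RuntimeError("AIC selection failed: no converged fits")
    selected = orders[int(np.argmin(aics))]
    return ModelSelection(orders=orders, aics=aics, selected=selected)
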