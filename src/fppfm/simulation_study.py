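"""Synthetic introgression-line data and the power / false-positive benchmark.

The generator emulates the structure of a lysimeter-phenotyped IL trial:
biallelic two-genotype markers at a given class frequency, a three-stage
daily time grid, genotype-specific smooth curves built from per-stage
Legendre polynomials, and SAD(1)-correlated residuals.  The innovation
variance is solved numerically so that the realized curve heritability

    h2_bar = mean_t V(t) / (V(t) + sigma2(t)),   V(t) = 2 p1 p0 a(t)^2

hits the configured target exactly.  The benchmark compares the functional
existence LRT against single-day one-way ANOVA (the standard static method
for IL populations) on the same replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from fppfm.curve_basis import LOPBasis
from fppfm.funmap_core import FitOptions, GridLayout
from fppfm.io_data import GenotypeTable, PhenotypeSeries
from fppfm.qtl_scan import ScanEngine
from fppfm.sad_covariance import SADParams, sad1_variances

DEFAULT_STAGES = ("pre_drought", "drought", "recovery")


# ---------------------------------------------------------------------------
# trajectory template
#
# A three-phase transpiration-like template: gradual rise while well-watered,
# decline under drought, and a rapid recovery rise peaking mid-phase before
# easing off.  The genotype contrast is small in the first two phases and
# concentrated in the recovery phase (a conditional, environment-dependent
# QTL), mirroring the behaviour of a major recovery-phase locus in a tomato
# IL population.  Curves are projected onto the per-stage LOP space of the
# configured order, so the truth lies exactly in the fitted model family.


def _template_base(stage: int, u: np.ndarray) -> np.ndarray:
    if stage == 0:
        return 0.5 + 0.5 * u
    if stage == 1:
        return 1.0 - 0.4 * u
    return 0.6 + 0.8 * np.sin(np.pi * u)


def _template_half_difference(stage: int, u: np.ndarray) -> np.ndarray:
    if stage == 0:
        return np.full_like(u, 0.03)
    if stage == 1:
        return np.full_like(u, 0.05)
    return 0.10 + 0.25 * np.sin(np.pi * u)


@dataclass
class SimConfig:
    """Study conditions for one simulated IL dataset."""

    n_individuals: int = 200
    n_markers: int = 1000
    n_causal: int = 1
    heritability: float = 0.10
    correlated: bool = True
    rho_sim: float = 0.6
    n_stages: int = 3
    days_per_stage: int = 10
    genotype_freq: float = 0.5
    order: int = 4
    n_chromosomes: int = 10

    def __post_init__(self):
        if not 0.0 < self.heritability < 1.0:
            raise ValueError(f"heritability must be in (0,1), got {self.heritability}")
        if self.n_causal >= self.n_markers:
            raise ValueError("n_causal must be smaller than n_markers")
        if not 0.0 < self.genotype_freq < 1.0:
            raise ValueError("genotype frequency must be in (0,1)")

    @property
    def rho(self) -> float:
        return self.rho_sim if self.correlated else 0.0

    @property
    def stage_ids(self) -> list:
        return [DEFAULT_STAGES[s] if s < 3 else f"stage_{s}" for s in range(self.n_stages)]

    def stage_days(self) -> list:
        T = self.days_per_stage
        return [np.arange(s * T, (s + 1) * T) for s in range(self.n_stages)]

    def layout(self) -> GridLayout:
        bases = {
            sid: LOPBasis(self.order, days)
            for sid, days in zip(self.stage_ids, self.stage_days())
        }
        return GridLayout(
            traits=["trait"],
            stages=self.stage_ids,
            stage_lengths=[self.days_per_stage] * self.n_stages,
            bases=bases,
        )


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_indices: list
    causal_marker_ids: list
    mean_qq: np.ndarray
    mean_QQ: np.ndarray
    phi2: float
    rho: float
    heritability: float
    coefficients: dict = field(default_factory=dict)


def template_curves(config: SimConfig):
    """Genotype mean trajectories (mu_qq, mu_QQ) on the concatenated grid.

    Built from the three-phase template, projected per stage onto the LOP
    space of ``config.order`` and scaled so the pooled mean trajectory has
    unit standard deviation over the grid.
    """
    layout = config.layout()
    qq_parts, QQ_parts, coefs = [], [], {}
    for si, sid in enumerate(config.stage_ids):
        basis = layout.bases[sid]
        u = (basis.tau + 1.0) / 2.0
        base = _template_base(min(si, 2), u)
        a = _template_half_difference(min(si, 2), u)
        D = basis.design
        v = np.linalg.lstsq(D, np.column_stack([base - a, base + a]), rcond=None)[0]
        proj = D @ v
        coefs[sid] = v
        qq_parts.append(proj[:, 0])
        QQ_parts.append(proj[:, 1])
    mu_qq = np.concatenate(qq_parts)
    mu_QQ = np.concatenate(QQ_parts)
    scale = 1.0 / np.std((mu_qq + mu_QQ) / 2.0)
    return mu_qq * scale, mu_QQ * scale, {s: v * scale for s, v in coefs.items()}


def calibrate_innovation_variance(mu_qq, mu_QQ, p1: float, rho: float,
                                  h2: float) -> float:
    """Solve phi2 so the realized curve heritability equals ``h2``.

    V(t) = 2 p1 p0 a(t)^2 with a = (mu_QQ - mu_qq)/2; sigma2(t) are the
    SAD(1) marginal variances.  mean_t V/(V+sigma2) is strictly decreasing
    in phi2, so a bracketed root always exists unless a(t) is identically 0.
    """
    a = (np.asarray(mu_QQ) - np.asarray(mu_qq)) / 2.0
    V = 2.0 * p1 * (1.0 - p1) * a**2
    if np.all(V == 0):
        raise ValueError("zero genetic effect: target heritability unattainable")
    T = len(a)
    t = np.arange(1, T + 1)
    w = np.ones(T) if rho == 0 else (1.0 - rho ** (2 * t)) / (1.0 - rho**2)

    def gap(log_phi2):
        s2 = np.exp(log_phi2) * w
        return float(np.mean(V / (V + s2))) - h2

    lo, hi = -40.0, 40.0
    if gap(lo) < 0 or gap(hi) > 0:
        raise ValueError(f"heritability {h2} unattainable with this effect curve")
    return float(np.exp(optimize.brentq(gap, lo, hi, xtol=1e-13, rtol=1e-15)))


def simulate_matrices(config: SimConfig, seed):
    """Fast path: (Y, codes, truth) as raw arrays.

    Y is (n, M) over the concatenated grid; codes is (n_markers, n) in
    {0, 2}; residuals follow the SAD(1) recursion eps_t = rho eps_{t-1} +
    eta_t starting from eps_0 = 0.
    """
    rng = np.random.default_rng(seed)
    n, m = config.n_individuals, config.n_markers
    mu_qq, mu_QQ, coefs = template_curves(config)
    M = len(mu_qq)
    phi2 = calibrate_innovation_variance(
        mu_qq, mu_QQ, config.genotype_freq, config.rho, config.heritability
    )
    codes = np.where(rng.random((m, n)) < config.genotype_freq, 2.0, 0.0)
    causal = rng.choice(m, size=config.n_causal, replace=False)

    eta = rng.standard_normal((n, M)) * np.sqrt(phi2)
    eps = np.empty_like(eta)
    eps[:, 0] = eta[:, 0]
    rho = config.rho
    for t in range(1, M):
        eps[:, t] = rho * eps[:, t - 1] + eta[:, t]

    Y = np.tile(mu_qq, (n, 1)) + eps
    for c in causal:
        is_QQ = codes[c] == 2.0
        Y[is_QQ] += mu_QQ - mu_qq

    truth = SimTruth(
        causal_indices=list(map(int, sorted(causal))),
        causal_marker_ids=[f"m{int(c)}" for c in sorted(causal)],
        mean_qq=mu_qq,
        mean_QQ=mu_QQ,
        phi2=phi2,
        rho=rho,
        heritability=config.heritability,
        coefficients=coefs,
    )
    return Y, codes, truth


def simulate_dataset(config: SimConfig, seed):
    """Simulate one dataset as (PhenotypeSeries, GenotypeTable, SimTruth)."""
    Y, codes, truth = simulate_matrices(config, seed)
    n, m = config.n_individuals, config.n_markers
    individuals = [f"IL{i:04d}" for i in range(n)]
    days = np.concatenate(config.stage_days())
    stage_of_col = np.repeat(config.stage_ids, config.days_per_stage)
    long = pd.DataFrame(
        {
            "individual_id": np.repeat(individuals, len(days)),
            "trait_id": "trait",
            "stage_id": np.tile(stage_of_col, n),
            "day": np.tile(days, n),
            "value": Y.ravel(),
        }
    )
    phenos = PhenotypeSeries(long, list(config.stage_ids))

    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chroms = [f"chr{1 + i // per_chrom}" for i in range(m)]
    pos = [float(i % per_chrom) for i in range(m)]
    markers = pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(m)], "chromosome": chroms,
         "position_cM": pos}
    )
    genos = GenotypeTable(markers, individuals, codes)
    return phenos, genos, truth


# ---------------------------------------------------------------------------
# static ANOVA baseline


def _anova_f_matrix(Y: np.ndarray, codes: np.ndarray):
    """One-way ANOVA F and p for every (marker, timepoint) pair, vectorized.

    Two genotype classes; markers with an empty class get NaN rows.
    """
    codes = np.atleast_2d(codes)
    m0 = (codes == 0.0).astype(float)
    m2 = (codes == 2.0).astype(float)
    n0 = m0.sum(axis=1)[:, None]
    n2 = m2.sum(axis=1)[:, None]
    n = n0 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        mean0 = (m0 @ Y) / n0
        mean2 = (m2 @ Y) / n2
        grand = (m0 @ Y + m2 @ Y) / n
        ssb = n0 * (mean0 - grand) ** 2 + n2 * (mean2 - grand) ** 2
        tot = (m0 + m2) @ (Y**2)
        ssw = tot - n0 * mean0**2 - n2 * mean2**2
        df2 = n - 2
        F = (ssb / 1.0) / (ssw / df2)
        p = stats.f.sf(F, 1, df2)
    bad = (n0[:, 0] < 1) | (n2[:, 0] < 1)
    F[bad] = np.nan
    p[bad] = np.nan
    return F, p


def anova_scan(phenos: PhenotypeSeries, markers, day):
    """Per-marker one-way ANOVA of the phenotype at a single day.

    Returns a DataFrame with columns marker, F, p, neg_log10_p.  Markers
    where a genotype class is empty are reported as NaN (skipped).
    """
    inds, Y = phenos.to_matrix()
    codes = markers.codes if hasattr(markers, "codes") else np.atleast_2d(markers)
    days = np.concatenate([phenos.grid()[s] for s in phenos.stages])
    col = np.flatnonzero(days == day)
    if col.size == 0:
        raise ValueError(f"day {day!r} not on the analysis grid")
    F, p = _anova_f_matrix(Y[:, col], codes)
    ids = (markers.bins["bin_id"].tolist() if hasattr(markers, "bins")
           else markers.markers["marker_id"].tolist() if hasattr(markers, "markers")
           else [f"m{i}" for i in range(codes.shape[0])])
    return pd.DataFrame(
        {"marker": ids, "F": F[:, 0], "p": p[:, 0],
         "neg_log10_p": -np.log10(p[:, 0])}
    )


# ---------------------------------------------------------------------------
# power / false-positive benchmark


@dataclass
class DetectionRule:
    """Significance rules of the benchmark.

    FM: chi-square p at the causal (or any) marker below alpha/n_markers.
    ANOVA: p minimized over days below alpha/(n_markers * n_days).
    """

    alpha: float = 0.05


def _fm_replicate(engine: ScanEngine, codes, causal_idx, alpha_bonf,
                  full_scan: bool):
    if full_scan:
        lr, df, p = engine.lrt(codes)
        detected = bool(np.nanmin(p[causal_idx]) < alpha_bonf)
        null_p = np.delete(p, causal_idx)
        false_pos = bool(np.nanmin(null_p) < alpha_bonf)
        return detected, false_pos
    lr, df, p = engine.lrt(codes[causal_idx])
    return bool(np.nanmin(p) < alpha_bonf), None


def estimate_power_fpr(configs, n_replicates: int = 200, seed: int = 0,
                       rule: DetectionRule | None = None,
                       methods=("ANOVA", "FPP-FM"),
                       fm_full_scan: bool = False,
                       options: FitOptions | None = None) -> pd.DataFrame:
    """Monte-Carlo power and false-positive table over a config grid.

    Power = fraction of replicates in which the causal marker is declared
    significant; FPR = fraction in which at least one null marker is.  The
    FM false-positive column requires full per-marker scans
    (``fm_full_scan=True``); otherwise only the causal marker is fitted and
    the FM FPR is reported as NaN.  Identical seeds give identical tables.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rule = rule or DetectionRule()
    if isinstance(configs, SimConfig):
        configs = [configs]
    rows = []
    root = np.random.SeedSequence(seed)
    for ci, config in enumerate(configs):
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(ci,))
        rep_seeds = child.spawn(n_replicates)
        opts = options or FitOptions(order=config.order)
        layout = config.layout()
        n_days = config.n_stages * config.days_per_stage
        alpha_fm = rule.alpha / config.n_markers
        alpha_anova = rule.alpha / (config.n_markers * n_days)

        counts = {m: {"power": 0, "fp": 0, "n": 0, "n_fp": 0} for m in methods}
        for rs in rep_seeds:
            Y, codes, truth = simulate_matrices(config, rs)
            causal = np.asarray(truth.causal_indices)
            if "ANOVA" in methods:
                F, p = _anova_f_matrix(Y, codes)
                pmin = np.nanmin(p, axis=1)
                counts["ANOVA"]["power"] += int(np.min(pmin[causal]) < alpha_anova)
                null_p = np.delete(pmin, causal)
                counts["ANOVA"]["fp"] += int(np.min(null_p) < alpha_anova)
                counts["ANOVA"]["n"] += 1
                counts["ANOVA"]["n_fp"] += 1
            if "FPP-FM" in methods:
                engine = ScanEngine.from_matrix(Y, layout, opts)
                det, fp = _fm_replicate(engine, codes, causal, alpha_fm, fm_full_scan)
                counts["FPP-FM"]["power"] += int(det)
                counts["FPP-FM"]["n"] += 1
                if fp is not None:
                    counts["FPP-FM"]["fp"] += int(fp)
                    counts["FPP-FM"]["n_fp"] += 1

        for m in methods:
            c = counts[m]
            power = c["power"] / c["n"] if c["n"] else np.nan
            fpr = c["fp"] / c["n_fp"] if c["n_fp"] else np.nan
            rows.append(
                {
                    "method": m,
                    "correlated": config.correlated,
                    "n": config.n_individuals,
                    "h2": config.heritability,
                    "power": power,
                    "false_positive_rate": fpr,
                    "n_replicates": c["n"],
                    "mc_se_power": float(np.sqrt(power * (1 - power) / c["n"]))
                    if c["n"] else np.nan,
                    "mc_se_fpr": float(np.sqrt(fpr * (1 - fpr) / c["n_fp"]))
                    if c["n_fp"] and np.isfinite(fpr) else np.nan,
                }
            )
    return pd.DataFrame(rows)
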