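"""Time-varying genetic variance per QTL and phase-specific QTL networks.

For a biallelic QTL with allele (class) frequencies p1 + p0 = 1, additive
effect a(t) and dominance d(t), the genetic variance at time t is

    V(t) = 2 p1 p0 (a + (p1 - p0) d)^2 + 4 p1^2 p0^2 d^2

(in the two-homozygote introgression-line design d is identically 0 and
a(t) = (mu_QQ(t) - mu_qq(t)) / 2).  The genetic standard deviations
s_j(t) = sqrt(V_j(t)) of the mapped QTLs are coupled through the ODE system

    ds_j/dt = W_j(s_j(t); Theta_j) + sum_{j' != j} W_jj'(s_j'(t); Theta_jj')

whose main-effect and coupling functions are expanded in Legendre
polynomials of the state and estimated by two-stage gradient matching:
smooth each s_j(t), differentiate analytically, then regress the derivative
on the basis expansions with forward BIC selection of the coupling terms.
Hub QTLs are the high-degree nodes of the resulting directed network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from fppfm.curve_basis import LOPBasis, legendre_value
from fppfm.funmap_core import CurveFit

# ---------------------------------------------------------------------------
# genetic variance curves


@dataclass
class VarianceCurve:
    """Per-QTL time courses of additive/dominance effects and genetic s.d."""

    qtl_id: str
    times: np.ndarray
    a: np.ndarray
    d: np.ndarray
    p1: float
    V: np.ndarray = field(init=False)
    s: np.ndarray = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError(f"allele frequency p1 must lie in [0,1], got {self.p1}")
        p1, p0 = self.p1, 1.0 - self.p1
        a = np.asarray(self.a, dtype=float)
        d = np.asarray(self.d, dtype=float)
        self.V = 2 * p1 * p0 * (a + (p1 - p0) * d) ** 2 + 4 * p1**2 * p0**2 * d**2
        self.s = np.sqrt(self.V)


def genetic_variance_curve(a, d, p1: float, qtl_id: str = "", times=None) -> VarianceCurve:
    """Pointwise genetic variance decomposition for one QTL."""
    a = np.asarray(a, dtype=float)
    d = np.zeros_like(a) if d is None else np.asarray(d, dtype=float)
    if times is None:
        times = np.arange(len(a), dtype=float)
    return VarianceCurve(qtl_id=qtl_id, times=np.asarray(times, dtype=float),
                         a=a, d=d, p1=float(p1))


def effects_from_fit(fit: CurveFit, bases: dict, trait=None, p1: float | None = None):
    """Additive effect curve from a two-genotype curve fit.

    a(t) = (mu_QQ(t) - mu_qq(t)) / 2, d(t) = 0 (two homozygous classes);
    p1 defaults to the observed frequency of the QQ class in the fit.
    """
    if len(fit.genotypes) != 2:
        raise ValueError(
            f"additive decomposition needs exactly 2 genotype classes, "
            f"got {len(fit.genotypes)}"
        )
    trait = trait if trait is not None else fit.traits[0]
    lo, hi = sorted(fit.genotypes)
    mu_qq = fit.mean_curve(lo, trait, bases)
    mu_QQ = fit.mean_curve(hi, trait, bases)
    a = (mu_QQ - mu_qq) / 2.0
    if p1 is None:
        n_hi = fit.group_sizes.get(hi, 0)
        n_lo = fit.group_sizes.get(lo, 0)
        p1 = n_hi / (n_hi + n_lo) if (n_hi + n_lo) else 0.5
    return a, np.zeros_like(a), float(p1)


# ---------------------------------------------------------------------------
# ODE gradient matching


@dataclass
class QTLNetwork:
    """Directed QTL interaction network for one treatment phase."""

    phase: str
    node_ids: list
    s_curves: dict                 # id -> s_j(t) on the phase grid
    times: np.ndarray
    theta_main: dict               # id -> main-effect basis coefficients
    edges: list                    # dicts: src, dst, sign, weight, theta
    hubs: list = field(default_factory=list)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph(phase=self.phase)
        g.add_nodes_from(self.node_ids)
        for e in self.edges:
            g.add_edge(e["src"], e["dst"], weight=e["weight"], sign=e["sign"])
        return g

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "nodes": [
                {
                    "id": i,
                    "s_curve": list(map(float, self.s_curves[i])),
                    "theta_main": list(map(float, self.theta_main[i])),
                }
                for i in self.node_ids
            ],
            "edges": [
                {
                    "src": e["src"], "dst": e["dst"], "sign": int(e["sign"]),
                    "weight": float(e["weight"]),
                    "theta_coupling": list(map(float, e["theta"])),
                }
                for e in self.edges
            ],
            "hubs": list(self.hubs),
            "times": list(map(float, self.times)),
        }


def _state_basis(s: np.ndarray, order: int, include_const: bool) -> np.ndarray:
    """Legendre expansion columns of a state trajectory rescaled to [-1, 1].

    Degenerate (constant) states collapse to the constant column alone.
    """
    lo, hi = float(np.min(s)), float(np.max(s))
    if hi - lo < 1e-12:
        tau = np.zeros_like(s)
    else:
        tau = -1.0 + 2.0 * (s - lo) / (hi - lo)
    start = 0 if include_const else 1
    cols = [legendre_value(k, tau) for k in range(start, order + 1)]
    return np.column_stack(cols) if cols else np.zeros((len(s), 0))


def _smooth_and_differentiate(s: np.ndarray, times: np.ndarray, order: int):
    """LOP-smooth one s_j(t) and return (smoothed values, analytic ds/dt)."""
    T = len(times)
    order = min(order, T - 1)
    basis = LOPBasis(order, times)
    c, *_ = np.linalg.lstsq(basis.design, s, rcond=None)
    return basis.design @ c, basis.derivative_design() @ c


def _bic(rss: float, n: int, p: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + p * np.log(n)


def fit_ode_network(s_curves: dict, times, phase: str = "",
                    smooth_order: int = 8, main_order: int = 2,
                    coupling_order: int = 1, bic_margin: float = 10.0,
                    hub_rule: str = "decile",
                    hub_cutoff: float | None = None) -> QTLNetwork:
    """Reconstruct the QTL interaction network by gradient matching.

    Per target QTL j the derivative of its smoothed genetic-s.d. curve is
    regressed on a Legendre expansion of its own state (main effect, always
    kept) plus expansions of every other QTL's state; couplings enter by
    forward selection and are retained only while BIC improves by at least
    ``bic_margin`` (the default of 10 demands very strong evidence, which
    keeps spurious couplings between smooth, mutually predictable curves
    rare -- on a handful of phase timepoints almost any pair of monotone
    curves can partially explain each other's derivatives).
    Edge weight is the integrated absolute coupling over the phase; edge
    sign says whether the coupling increases with the driver state
    (activation) or decreases (repression).
    """
    times = np.asarray(times, dtype=float)
    ids = list(s_curves)
    if not ids:
        raise ValueError("no QTL curves supplied")
    T = len(times)
    if T < 4:
        raise ValueError(f"need at least 4 phase timepoints, got {T}")

    smoothed, deriv = {}, {}
    for i in ids:
        s = np.asarray(s_curves[i], dtype=float)
        if len(s) != T:
            raise ValueError(f"curve {i!r} has {len(s)} points, grid has {T}")
        smoothed[i], deriv[i] = _smooth_and_differentiate(s, times, smooth_order)

    # basis blocks in the state variables
    main_blocks = {i: _state_basis(smoothed[i], main_order, include_const=True)
                   for i in ids}
    coup_blocks = {i: _state_basis(smoothed[i], coupling_order, include_const=False)
                   for i in ids}

    theta_main, edges = {}, []
    for j in ids:
        y = deriv[j]
        Xm = main_blocks[j]
        if Xm.shape[1] + 1 > T:
            Xm = Xm[:, : max(T - 1, 1)]
        candidates = [i for i in ids if i != j and coup_blocks[i].shape[1] > 0
                      and np.ptp(smoothed[i]) > 1e-12]
        chosen: list = []

        def rss_of(blocks):
            X = np.hstack([Xm] + [coup_blocks[c] for c in blocks]) if blocks else Xm
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r), beta, X

        rss, beta, X = rss_of(chosen)
        best_bic = _bic(rss, T, X.shape[1])
        improved = True
        while improved and candidates:
            improved = False
            trial_best = None
            for c in candidates:
                p_new = X.shape[1] + coup_blocks[c].shape[1]
                if p_new >= T:
                    continue
                r2, b2, X2 = rss_of(chosen + [c])
                bic2 = _bic(r2, T, X2.shape[1])
                if bic2 < best_bic - bic_margin and (trial_best is None or bic2 < trial_best[0]):
                    trial_best = (bic2, c, r2, b2, X2)
            if trial_best is not None:
                best_bic, c, rss, beta, X = trial_best
                chosen.append(c)
                candidates.remove(c)
                improved = True

        pm = Xm.shape[1]
        theta_main[j] = beta[:pm]
        off = pm
        for c in chosen:
            pc = coup_blocks[c].shape[1]
            theta = beta[off : off + pc]
            w_curve = coup_blocks[c] @ theta
            off += pc
            weight = float(np.trapezoid(np.abs(w_curve), times))
            # activating if the coupling increases with the driver state;
            # the constant part of W_jj' is absorbed by the main effect, so
            # the slope (not the mean) carries the direction of regulation
            slope = np.corrcoef(w_curve, smoothed[c])[0, 1] if np.ptp(w_curve) > 0 else 0.0
            sign = int(np.sign(slope)) or 1
            edges.append({"src": c, "dst": j, "sign": sign,
                          "weight": weight, "theta": theta})

    net = QTLNetwork(
        phase=phase, node_ids=ids, s_curves={i: np.asarray(s_curves[i], float) for i in ids},
        times=times, theta_main=theta_main, edges=edges,
    )
    net.hubs = identify_hubs(net, rule=hub_rule, cutoff=hub_cutoff)
    return net


def identify_hubs(network: QTLNetwork, rule: str = "decile",
                  cutoff: float | None = None) -> list:
    """Hub QTLs: nodes with total degree at or above the 90th percentile.

    An edgeless network has no hubs; otherwise at least the top-degree node
    is returned.  ``rule="absolute"`` uses ``cutoff`` as a degree threshold.
    """
    if not network.node_ids:
        raise ValueError("empty network")
    g = network.graph()
    degrees = {n: g.in_degree(n) + g.out_degree(n) for n in network.node_ids}
    if not network.edges:
        return []
    if rule == "absolute":
        if cutoff is None:
            raise ValueError("absolute hub rule needs a cutoff")
        thr = float(cutoff)
    elif rule == "decile":
        thr = float(np.quantile(list(degrees.values()), 0.9))
    else:
        raise ValueError(f"unknown hub rule {rule!r}")
    hubs = [n for n, dg in degrees.items() if dg >= thr and dg > 0]
    if not hubs:
        top = max(degrees.values())
        hubs = [n for n, dg in degrees.items() if dg == top and dg > 0]
    return sorted(hubs, key=lambda n: (-degrees[n], str(n)))


def phase_slices(stage_lengths, stages):
    """Column slices of the concatenated grid per treatment phase."""
    out, off = {}, 0
    for s, T in zip(stages, stage_lengths):
        out[s] = slice(off, off + T)
        off += T
    return out
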