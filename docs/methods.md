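# Methods

## Observation model

Phenotypes are daily trait values on a shared grid spanning S treatment
stages (default three: pre-drought, drought, recovery).  For a marker with
J genotype classes (J = 2 in the introgression-line design, codes 0 = qq
and 2 = QQ), individual i in class j has

    y_i ~ N(mu_j, Sigma),      mu_j = (mu_j(t_1), ..., mu_j(t_T)),

where within each stage s the mean is a Legendre orthogonal polynomial
(LOP) expansion of order K with genotype-specific coefficients v_sj.  Each
stage is rescaled to tau in [-1, 1] over its own first/last day, so fitted
curves are piecewise polynomials that may be discontinuous at phase
changes — deliberate, since treatment switches can change trajectories
abruptly.  The same order K is used for all genotypes, stages and traits of
one fit so that likelihood-ratio degrees of freedom are well defined;
K = 4 by default (three-phase transpiration curves need at least cubic
flexibility), or chosen by AIC (`-2 lnL + 2 dim`, minimum wins, ties to the
smaller order).

Residuals follow first-order structured antedependence, SAD(1):
eps_t = rho·eps_{t-1} + eta_t with innovation variance phi2 and eps_0 = 0,
indexed by the integer rank of the timepoint on the analysis grid (not raw
days).  This gives nonstationary variances sigma2(t) = phi2(1-rho^(2t))/
(1-rho^2) rising toward phi2/(1-rho^2), and correlations decaying as
rho^lag.  One SAD chain runs across the concatenated stage grid by default
(physical time is continuous across phases); `cov.per_stage` restarts the
chain at each phase boundary.  Sigma is shared across genotype classes at a
marker.  With several traits, cross-trait covariance blocks default to zero
(the single-trait path is the validated one); a single cross-correlation
scalar is available for dense likelihood evaluation via
`cross_trait_rho` (covariance = R ⊗ Sigma_time).

## Fitting

The SAD(1) covariance factorises exactly: Sigma = phi2·A⁻¹A⁻ᵀ with A unit
lower-bidiagonal (−rho on the subdiagonal), so |Sigma| = phi2^T and
whitening is an O(T) filter.  For fixed rho the whitened model is ordinary
least squares: the coefficient vectors have closed-form GLS solutions from
the per-class mean trajectories, and phi2's MLE is the pooled whitened
residual mean square.  The profile log-likelihood is therefore a smooth 1-D
function of rho, maximised by bounded Brent search on (−0.99, 0.99) to
xatol 1e-7.  This replaces a joint simplex search over all parameters: it
reaches the same maximum (the test suite cross-checks it against a joint
Nelder-Mead optimiser with OLS initialisation, tanh/log transforms and
seeded restarts, which remains available via `method="nelder-mead"`), is
deterministic with no starting-value sensitivity, and is fast enough to
make full permutation scans routine.

Genome scans evaluate the profile likelihood of every marker simultaneously
on a fixed 53-point rho grid with per-marker parabolic refinement of the
maximum; this reproduces the exact per-marker Brent fit to ~1e-2 LR units
(asserted in tests) at a small fraction of the cost.  Individuals missing a
genotype at a marker are excluded from that marker's fit only; a genotype
class below `min_group_size` (default 2) makes the marker untestable
(NaN/skip, logged).

## Hypothesis tests

- Existence of a QTL: H0 constrains coefficient vectors equal across
  genotype classes; LR = 2(lnL1 − lnL0) referred to chi-square with
  df = (J−1)·L·S·(K+1).
- QTL-by-environment: H0 equal across stages; df = (S−1)·J·L·(K+1).
- Pleiotropy: H0 equal across traits; df = (L−1)·J·S·(K+1).

Reported p-values are chi-square tail probabilities; the genome-wide
significance threshold comes from permutation: whole multi-stage
trajectories are reshuffled against genotype labels (preserving
within-individual correlation under the null), and per reshuffle the
genome-wide maximum LR enters the null distribution whose (1−alpha)
quantile is the critical value.  The maximum-LR statistic gives family-wise
control; a pooled per-marker mode (`--perm-mode marker`) is also shipped
because per-marker nulls are sometimes preferred.  Q-by-E and pleiotropy
tests are run on scan hits only, with Bonferroni correction by the number
of hits tested.  QTL regions are contiguous runs of significant bins on a
chromosome, reported with member cM bounds and peak bin.

Per-marker null calibration of the existence LRT is exact to binomial error
at the nominal 5% level from n = 100 individuals upward (acceptance suite,
500 null replicates).

## Marker binning

In an IL panel many adjacent SNPs cosegregate.  Runs of adjacent identical
genotype columns within a chromosome are merged into bins (identity judged
on the intersection of non-missing individuals; the representative column
fills missing entries from other members).  Merging only adjacent markers
preserves map order; binning is idempotent and bins partition the marker
set.  Heterozygote codes are rejected with a clear error — the two-genotype
design has no heterozygous class.

## Genetic variance and QTL networks

For a biallelic QTL with class frequencies p1 + p0 = 1,

    V(t) = 2 p1 p0 (a(t) + (p1 − p0) d(t))² + 4 p1² p0² d(t)²,

with a(t) = (mu_QQ(t) − mu_qq(t))/2 and d ≡ 0 in the IL design (dominance
is unidentifiable with two homozygous classes).  The genetic s.d. curves
s_j(t) = sqrt(V_j(t)) of the QTLs entering the network (scan bins passing a
relaxed per-marker threshold, `network.alpha` = 0.05) are modelled per
treatment phase by the coupled ODE system

    ds_j/dt = W_j(s_j; Theta_j) + sum_{j'≠j} W_jj'(s_j'; Theta_jj'),

estimated by two-stage gradient matching: each s_j is smoothed with a LOP
of order 8 (auto-reduced on short grids) and differentiated analytically;
then ds_j/dt is regressed on Legendre expansions of the states — order 2 in
the QTL's own state (main effect, always kept, including the constant) and
order 1 in each candidate driver (constant excluded: it is absorbed by the
main intercept).  Couplings enter by forward selection and are retained
only if BIC improves by at least 10 ("very strong evidence"): on a
ten-point phase grid almost any pair of smooth monotone curves can partly
explain each other's derivatives, and a plain BIC comparison retains many
such spurious edges, while the margin-10 rule keeps the null edge rate low
(~1%) yet recovers a genuinely driven direction in >90% of noisy
replicates (both measured in the acceptance suite).  Edge weight is the
integrated |W_jj'| over the phase; edge sign is the slope of the coupling
in the driver state (positive = activating) — the mean of the identifiable
coupling is ~0 by construction, so a mean-based sign would be noise.  Hubs
are nodes with total degree at or above the 90th percentile (at least the
top-degree node in any network with edges; an edgeless network has none).

Identifiability caveat: autonomous gradient matching can only attribute a
coupling when the target's derivative is not a single-valued function of
its own state.  Monotone curves that happen to be affinely similar are
mutually confounded drivers; interpret edges between near-collinear s
curves with caution.

## Synthetic data generator

`simulation_study.SimConfig`/`simulate_dataset` emulate the IL trial
design: n individuals; biallelic markers drawn independently with class
frequency 0.5; a three-stage grid of 10 days per stage; one causal marker
imposing genotype-specific mean curves; SAD(1) residuals with rho = 0.6 in
the correlated scenario and rho = 0 otherwise.  The genotype curve template
is a three-phase transpiration-like shape (rise, decline under drought,
rapid recovery peaking mid-phase) with the genotype contrast concentrated
in the recovery phase, mimicking a conditional recovery-phase QTL; the
template is projected onto the per-stage LOP space of the configured order
(so the truth lies in the fitted family) and scaled to unit s.d. of the
pooled mean trajectory.  The innovation variance is solved by root finding
so the realized curve heritability, mean_t V(t)/(V(t)+sigma2(t)), equals
the target exactly (to 1e-6).

What the generator does not emulate: measurement-day gaps and dropout,
diurnal structure within days, plant-size confounding of transpiration,
genetic map structure/linkage between markers (markers are independent),
multiple segregating QTLs, and genotype-by-microenvironment noise.  Passing
tests therefore certify the statistical machinery under the stated model,
not robustness to those real-data features.

## Power / false-positive benchmark

`estimate_power_fpr` simulates replicate datasets per (correlated, n, h2)
cell and analyses each both ways: the functional LRT (chi-square p at the
causal marker, Bonferroni alpha/n_markers; family-wise false positives from
full per-marker scans) and single-day one-way ANOVA (p minimised over days,
Bonferroni over markers × days; a replicate counts as a false positive when
any null marker passes).  Desk scale is 200 replicates per cell for power
and 100 for the FM family-wise rates (Monte-Carlo s.e. columns are
reported); identical seeds give bit-identical tables.

Two structural findings, both recomputed by `scripts/acceptance.py`:

- At curve heritabilities of 0.05–0.10 with n = 200–500, a single
  fixed-effect QTL is an overwhelmingly strong signal — per-day variance
  ratios near h2 already give ANOVA noncentralities ≳ 5 at the Bonferroni
  threshold, and the functional LRT accumulates ~30 timepoints — so both
  methods sit at ~100% power in every cell of the default grid.
- The "any null marker significant" event is driven by finite-sample
  correlation between null markers and the causal locus: a null marker with
  sample correlation r to the causal genotype inherits noncentrality
  ≈ r²·lambda_causal.  With a saturated causal signal this leakage inflates
  the extreme tail that Bonferroni probes, so family-wise FM rates are well
  above the per-marker 5% calibration (which is exact when no causal QTL is
  present).  The effect grows with the accumulated causal signal, hence is
  strongest for uncorrelated residuals, where the trajectory carries the
  most independent information.

## Numerical choices and degenerate inputs

rho is optimised on (−0.99, 0.99); phi2 is profiled in closed form and
floored at 1e-300 before logging.  Time grids must be strictly increasing;
a single-point stage maps to tau = 0.  Constant state curves in the network
step collapse to an intercept-only block and emit no outgoing influence.
Order selection skips non-converged fits and errors only if all fail.
Permutations, simulations and the benchmark derive all randomness from
explicit integer seeds (`numpy` SeedSequence spawning), so every artifact
is reproducible from its manifest.

## Limitations

No interval mapping between markers, no LD/GWAS mode, no higher-order
SAD(r) or stationary alternatives (CS/ARMA), no dominance variance in IL
mode, and no per-genotype covariance.  The ANOVA baseline is the standard
single-timepoint F-test, not a repeated-measures variant.  Real-data
checks (marker binning counts, scan regions, day-4 ANOVA peak) require the
user to supply the trial's source tables under `data/real/`.
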