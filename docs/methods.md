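# Methods

## The coupled regulatory interaction (CRI) growth system

Two sigmoid traits — stem height H (m) and stem diameter D (cm) — grow
under a Lotka–Volterra-type pair of ODEs:

    dH/dt = α_H (1 − H/K_H) H + α_H β_{H←D} H D
    dD/dt = α_D (1 − D/K_D) D + α_D β_{D←H} D H

Each right-hand side splits into a *self-regulated* logistic term (the
trait's independent growth, determined by its intrinsic rate α > 0 and
asymptote K > 0) and an *interactive* term proportional to the product of
the two traits, whose coefficient β measures how the co-existing trait
promotes (β > 0) or inhibits (β < 0) growth. The sign pattern of
(β_{H←D}, β_{D←H}) classifies the interaction strategy: *neutral* (both
zero, to an absolute tolerance of 1e-8 since exact zeros never arise in
floating point), *cooperative* (at least one positive, none negative), and
*antagonistic* (any negative). `decompose_growth` evaluates both components
along the coupled trajectory and accumulates them by trapezoid quadrature;
by construction they sum to the full derivative at machine precision. An
"uncoupled" alternative — re-solving the logistic with β = 0 — is available
behind a flag for the independent-effect curves; the along-trajectory
component is the default because the decomposition is defined on the
system's own solution.

The system is integrated by classic fixed-step RK4 with an internal step of
0.01 year (configurable). Fitting uses Nelder–Mead least squares on the RK4
solution with the initial state pinned to the first observation, keeping
the free parameter count at six; ten deterministic starts surround
method-of-moments guesses (K ≈ 1.05 × max observation, α from the early
log-slope, β = 0) because the coupled-fit surface is multimodal. The two
traits' residuals are weighted by the inverse variance of each trait's
observations so units do not dominate the objective. Classical single-trait
equations (Gompertz a·e^{−b·e^{−ct}}, Korf a·e^{−b·t^{−c}}, Richards
a(1 − b·e^{−ct})^{1/(1−m)} in a 4-parameter form, logistic) are fit by
bounded least squares for model comparison.

Note on identifiability: K and the incoming β trade off along the effective
asymptote (the stationary condition is 1 − X*/K + β·Y* = 0), so on noisy
population data individual parameters are estimated less precisely than
the mean curve itself. Parameter-recovery checks therefore bound the
*relative bias* of the structural parameters (α, K) at 5% over replicates
and the couplings — which sit near zero — at 0.005 absolute; noise-free
single-trajectory fits recover all six parameters to better than 1%.

## System mapping

Phenotypes are stacked per individual as a 2T-vector (height at t = 1..T,
then diameter). Residuals follow a bivariate first-order structured
antedependence process, SAD(1): y_r(t) = φ_r y_r(t−1) + ε_r(t) with
y_r(0) = 0, innovation standard deviations ν_r and contemporaneous
innovation correlation ρ. The implied covariance has the closed form
(for s ≤ t)

    Cov(y_r(s), y_r(t)) = ν_r² φ_r^{t−s} (1 − φ_r^{2s}) / (1 − φ_r²),
    Cov(y_1(s), y_2(t)) = ρ ν_1 ν_2 φ_2^{t−s} (1 − (φ_1φ_2)^s) / (1 − φ_1φ_2),

with φ → 1 limits taken by continuity; it is validated entrywise against
the Monte-Carlo covariance of one million simulated paths. Likelihood
evaluations use a Cholesky factorization throughout.

Genotype classes at a marker are observed (testcross 1:1 with J = 2,
intercross 1:2:1 with J = 3, phases collapsed), so the alternative
likelihood factorizes: with the covariance fixed, the maximum over each
class's parameter set Θ_j is a generalized-least-squares fit of the RK4
mean curve to that class's mean vector. The covariance ψ is estimated under
the null (moment start from lag-1 residual regressions, then a Nelder–Mead
refinement of the exact likelihood) and shared with the alternative within
a marker, which stabilizes small-class fits; re-estimation per marker is a
flag. The scan statistic is LRT = 2(ℓ_alt − ℓ_null), referred to χ² with
6(J−1) df; a permutation calibration (max-LRT over markers under label
shuffling) is available because the χ² reference is an approximation.
Benjamini–Hochberg FDR is always reported; the genome-wide significance
call defaults to Bonferroni at α = 0.05. Sub-hypothesis tests constrain the
independence block (α_H, K_H, α_D, K_D; df = 4(J−1)) or the interaction
block (β_{H←D}, β_{D←H}; df = 2(J−1)) to be shared across classes.

Per-marker genetic-effect curves are weighted standard deviations of the
genotype-class mean curves, g(t) = √(Σ_j w_j (μ_j(t) − μ̄(t))²), with
observed class frequencies by default (Mendelian expectations by flag), and
the dynamic genetic correlation is the weighted Pearson correlation of the
class deviations between traits at each time.

The per-class GLS fits run inside a compiled (numba) Nelder–Mead/RK4
kernel; a 100-marker scan of 66 individuals takes about two seconds, which
is what makes the replicated operating-characteristic studies tractable.

## Synthetic data and the operating-characteristic studies

The generator emulates the target study design: a full-sib tree cross with
~60.5% testcross markers, T = 14 annual measurements, and poplar-like
defaults (α_H = 0.60/yr, K_H = 24 m, β_{H←D} = −0.010 per cm — diameter
growth inhibits height; α_D = 0.45/yr, K_D = 30 cm, β_{D←H} = +0.004 per m
— height promotes diameter; initial state H = 1.2 m, D = 1.0 cm at age 1;
SAD(1) with φ = 0.85, ν_H:ν_D = 1:1.2, ρ = 0.3). The causal marker shifts
both asymptotes by ±10% across genotype classes (evenly spaced over
classes); heritability is imposed by rescaling the innovation variances so
the time- and trait-averaged genetic variance fraction equals the requested
H², verified empirically to ±0.01 at n = 10⁴. Markers are in linkage
equilibrium and each replicate carries one causal marker.

`run_power_study` simulates, scans, and scores replicates with seeds
spawned deterministically from a master seed. Significance in the study is
declared per marker at level α (default 0.05): at that operating point the
null false-positive rate equals the nominal test level, which is the
operating point at which power and FPR are meaningful together; a
Bonferroni policy is available. ROC curves sweep the LRT statistic downward
over its observed range pooling causal (positive) and null (negative)
markers across replicates, with trapezoid AUC. The replicated studies use
an RK4 step of 0.1 year after verifying that a full scan's LRT statistics
change by less than 1e-5 relative to the 0.01-year step. Study sizes (100
markers per replicate, 50 replicates for power/ROC, 20 per sample size for
the null study) are the package's desk-scale defaults; the full-scale
1,000-marker study is a configuration change.

What the generator does not emulate: linkage disequilibrium between
markers, multi-QTL architectures, unbalanced measurement grids,
genotyping error, and environment-by-age interactions. Passing
operating-characteristic tests therefore demonstrate the estimator's
behaviour under the stated stochastic model, not performance on real
genotyping data.

## Functional clustering

Per-SNP bivariate effect curves (stacked 2T-vectors) are clustered with a
Gaussian mixture whose module mean curves are Legendre orthogonal
polynomial (LOP) expansions of order 4 per trait (T = 14 comfortably
supports order ≤ 6) and whose 2T×2T covariance is a single shared SAD(1)
(per-module covariance behind a flag). EM details: the E-step uses
log-sum-exp; the weight update is exact (ω_l = mean posterior); the
coefficient update is weighted GLS, which for a shared design reduces to
projecting the posterior-weighted mean curve; the covariance update is a
short Nelder–Mead move on the expected complete-data likelihood started at
the current ψ, so the generalized-EM ascent property holds (monotonicity is
asserted in tests at 1e-8). Initialization is k-means with five restarts
keeping the best likelihood; empty modules (ω < 1/(10p)) are re-seeded from
the worst-fit curve so the requested L is honoured during selection. L is
chosen by BIC (penalty log p; AIC available) over a configurable grid.
Hard assignments take the MAP module, ties to the lowest index.
Subclustering refits the machinery on one node's member curves, producing
the module → submodule → SNP hierarchy (labels M7, SM2/M7, ...); children
partition their parent by construction. Module mean curves default to the
empirical mean of member curves, with the model-based LOP means by flag.

## Network inference

Nodes (modules, submodules, or SNPs) carry one effect curve per trait.
Curves are smoothed with LOP least squares and interpolated on a 100-point
dense grid with analytic derivatives, which also handles more nodes than
time points.

**Selection.** For each focal node, LASSO screens candidate regulators and
a backward elimination keeps only regulators whose partial R² — the
relative residual-sum-of-squares reduction when the regulator enters last —
is at least 0.7 (configurable). Two design choices matter here. First, the
default response is the focal node's smoothed *derivative* (the left side
of the network ODE), not its values: value-on-value regression is
directionally symmetric, so it cannot distinguish a regulator from a
target, whereas explaining a node's rate of change is asymmetric. The
static value screen remains available (`target="value"`). Second, smooth
curves occupy few effective dimensions, so chance fits between independent
curves reach R² well above what white-noise intuition suggests;
conventional cross-validation on the interpolated grid badly over-selects
(it treats 100 interpolated points as independent), which is why the
partial-R² floor, and not the CV penalty, controls false edges. CV
(minimum and one-standard-error) and BIC selectors are implemented for
comparison. An optional in-degree cap enforces additional sparsity, and a
``fixed_support`` map bypasses selection entirely — the independent-effect
networks re-run selection on the independent curves by default, but can
reuse the support selected from the overall curves instead.

**Decomposition.** The focal derivative is modelled as

    dg_l/dt = G_l0(g_l) + Σ_{l'} G_{l←l'}(g_{l'}),

with each term a Legendre expansion (default order 3) in the corresponding
node's value mapped to [−1, 1] over its range; only G_l0 carries a constant
(an intercept is not attributable between components). Coefficients are
least squares against the smoothed derivative, with a small ridge fallback
when the design's condition number exceeds 1e10. The least-squares residual
is folded into the independent term, so independent + dependent reproduces
the smoothed derivative exactly at every grid point; the focal curve is
re-solved by RK4 from its first value as a consistency check, and
per-component effect curves are cumulative integrals.

**Edges.** Each retained regulator contributes a directed edge l' → l with
weight = time-averaged |G_{l←l'}| and sign = the time-averaged slope of
G_{l←l'} with respect to the regulator's state (positive slope =
activation). The slope-based sign is used because the dependent expansions
are constant-free, making the sign of their time average numerically
arbitrary, while the response direction is exactly sign(c) for a linear
coupling c·g and matches the planted truth in 97% of constructed cases.

**Planted-truth fixture.** Constructed 5-node systems use a two-layer
layout (3 autonomous sources, 2 sinks with 2 planted parents each),
flat-spectrum order-9 Legendre base curves on a 30-point grid, couplings
5× the sink's own derivative RMS, and 1% observation noise. The two-layer
restriction is a property of the fixture, not the method: in a deep
cascade a node's curve inherits its ancestors' shapes, and no value-based
selector can then separate parents from grandparents — a known limitation
of this class of network reconstruction that applies equally to real
module hierarchies.

## Degenerate inputs and numerical tolerances

Non-finite states or parameters raise typed errors; RK4 blow-up raises an
integration error carrying the offending time. Inside the scan, the ODE's
fixed initial state is floored at 0.1% of the trait's scale when a noisy
class mean dips non-positive at the youngest age (the fit target itself is
untouched) — the logistic dynamics are only defined in the positive
domain, and at low heritability the grand mean's first time point sits
within a few standard errors of zero. Constant trajectories yield
a degenerate classical fit (asymptote = constant) rather than a failure.
Markers with fewer than two usable genotype classes are flagged, not
fatal, in a scan. EM convergence is |Δ log L| < 1e-6 (relative) with a
500-iteration cap; the scan's simplex stops at a relative function spread
of 1e-12 or 2,500 iterations. Negative LRTs from finite optimization are
clamped at zero.

## Known limitations

Two traits only; no linkage map, haplotype phase, or composite-interval
scan — markers are tested marginally. The χ² reference for the LRT is
asymptotic; small genotype classes make it mildly conservative (the
simplex undershoots the intercross maximum slightly, which depresses the
null LRT mean a few percent below its df). Network edges express
predictive, not causal, dependence among effect curves, and static
topology only — time-varying networks are out of scope.
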