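"""System mapping: longitudinal QTL scan through the coupled growth model.

Each individual contributes a stacked 2T-vector (height at t=1..T; diameter
at t=1..T).  Under the null every individual shares one coupled-growth mean
curve; under the alternative at a marker, each genotype class j has its own
parameter set Theta_j, while a single first-order structured antedependence
(SAD(1)) covariance is shared.  Marker significance is a likelihood-ratio
test of the genotype-specific fit against the pooled fit, referred to a
chi-square with 6(J-1) degrees of freedom (or calibrated by permutation).

Under SAD(1), the residual of trait r at time t is a scaled carry-over of the
previous residual plus an innovation:

    y_r(t) = phi_r y_r(t-1) + eps_r(t),   y_r(0) = 0,

with innovation standard deviations nu_r and contemporaneous cross-trait
innovation correlation rho.  This yields the closed-form covariance
implemented in :func:`sad1_covariance`.

Because genotype classes are observed, the alternative likelihood factorizes
over classes: with the covariance fixed, maximizing over Theta_j reduces to a
generalized-least-squares fit of the coupled-system mean curve to each class
mean, which is what the compiled Nelder-Mead kernel does.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests

from ._kernels import cri_rk4, nm_minimize_gls
from .errors import DegenerateMarkerError, InvalidInputError
from .growth import (CRIParams, DEFAULT_RK4_STEP, TraitState,
                     decompose_growth, fit_cri, integrate_cri)

SEGREGATION_TESTCROSS = "testcross"   # 1:1, two genotype classes
SEGREGATION_INTERCROSS = "intercross"  # 1:2:1, three classes (phases collapsed)

_N_CLASSES = {SEGREGATION_TESTCROSS: 2, SEGREGATION_INTERCROSS: 3}
MENDELIAN_FREQS = {SEGREGATION_TESTCROSS: np.array([0.5, 0.5]),
                   SEGREGATION_INTERCROSS: np.array([0.25, 0.5, 0.25])}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SADParams:
    """Parameters of the bivariate SAD(1) longitudinal covariance."""

    phi_h: float
    phi_d: float
    nu_h: float
    nu_d: float
    rho: float

    def __post_init__(self):
        if abs(self.rho) >= 1:
            raise InvalidInputError("|rho| must be < 1")
        if self.nu_h <= 0 or self.nu_d <= 0:
            raise InvalidInputError("innovation sds nu must be positive")
        if abs(self.phi_h) >= 1 or abs(self.phi_d) >= 1:
            warnings.warn("|phi| >= 1: residual variance grows without bound",
                          stacklevel=2)

    def to_array(self):
        return np.array([self.phi_h, self.phi_d, self.nu_h, self.nu_d, self.rho])

    def to_dict(self):
        return {"phi_h": self.phi_h, "phi_d": self.phi_d,
                "nu_h": self.nu_h, "nu_d": self.nu_d, "rho": self.rho}


@dataclass
class MarkerGenotypes:
    """One marker's per-individual genotype codes.

    ``codes`` are integers in {0..J-1} with -1 for missing; testcross markers
    have J=2 classes (1:1), intercross J=3 (1:2:1).
    """

    marker_id: str
    segregation: str
    codes: np.ndarray
    chromosome: str | None = None
    position: float | None = None

    def __post_init__(self):
        if self.segregation not in _N_CLASSES:
            raise InvalidInputError(
                f"unknown segregation {self.segregation!r}; "
                f"expected one of {sorted(_N_CLASSES)}")
        self.codes = np.asarray(self.codes, dtype=np.int64)
        J = _N_CLASSES[self.segregation]
        bad = (self.codes >= J) | ((self.codes < 0) & (self.codes != -1))
        if np.any(bad):
            raise InvalidInputError(
                f"marker {self.marker_id}: codes must be in 0..{J - 1} or -1")

    @property
    def n_classes(self) -> int:
        return _N_CLASSES[self.segregation]


@dataclass
class PhenotypeSet:
    """Balanced bivariate longitudinal phenotypes: n individuals at a shared
    time grid of length T."""

    individuals: list
    times: np.ndarray
    heights: np.ndarray   # (n, T)
    diameters: np.ndarray  # (n, T)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        n, T = self.heights.shape
        if self.diameters.shape != (n, T) or self.times.shape != (T,):
            raise InvalidInputError("phenotype arrays are inconsistent")

    @property
    def n(self) -> int:
        return self.heights.shape[0]

    @property
    def T(self) -> int:
        return self.times.size

    def stacked(self) -> np.ndarray:
        """(n, 2T) matrix, height block first."""
        return np.hstack([self.heights, self.diameters])


@dataclass
class NullFit:
    theta: CRIParams
    psi: SADParams
    loglik: float
    mu: np.ndarray        # (2T,)
    init: TraitState
    quad_by_individual: np.ndarray  # (n,) Mahalanobis distances to mu


@dataclass
class AlternativeFit:
    marker_id: str
    theta_by_genotype: dict      # class code -> CRIParams
    class_sizes: dict            # class code -> n_j
    loglik: float
    quad_total: float            # sum_i (y_i - mu_{g(i)})' Sinv (...)
    included: np.ndarray         # boolean mask of individuals used
    dropped_classes: list = field(default_factory=list)
    psi_used: SADParams | None = None


@dataclass
class SubTestResult:
    lrt: float
    df: int
    p_value: float
    converged: bool = True


@dataclass
class MappingResult:
    marker_id: str
    lrt: float
    df: int
    p_value: float
    p_fdr: float = np.nan
    significant: bool = False
    theta_null: CRIParams | None = None
    theta_by_genotype: dict | None = None
    psi_hat: SADParams | None = None
    subtest_independent: SubTestResult | None = None
    subtest_interaction: SubTestResult | None = None
    chromosome: str | None = None
    position: float | None = None
    n_used: int = 0
    failed: bool = False


@dataclass
class EffectCurvePair:
    """Per-marker genetic-effect curves: time-indexed genetic standard
    deviations for each trait, their independent-growth variants, and the
    dynamic cross-trait genetic correlation."""

    marker_id: str
    times: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    independent_g1: np.ndarray
    independent_g2: np.ndarray
    dynamic_correlation: np.ndarray


# ---------------------------------------------------------------------------
# SAD(1) covariance and likelihood
# ---------------------------------------------------------------------------

def _sad1_block(phi, nu, T):
    """Within-trait covariance block: Cov(y(s), y(t)) for s <= t equals
    nu^2 phi^{t-s} (1 - phi^{2s}) / (1 - phi^2), with the phi -> 1 limit
    nu^2 s taken by continuity (1-indexed s)."""
    s = np.arange(1, T + 1)
    if abs(1.0 - phi * phi) < 1e-10:
        cum = s.astype(float)
    else:
        cum = (1.0 - phi ** (2 * s)) / (1.0 - phi * phi)
    tt, ss = np.meshgrid(s, s)
    lo = np.minimum(ss, tt)
    lag = np.abs(tt - ss)
    return nu * nu * (phi ** lag) * cum[lo - 1]


def _sad1_cross(phi_h, phi_d, nu_h, nu_d, rho, T):
    """Cross-trait block C[s, t] = Cov(y_1(s), y_2(t)).

    For s <= t: rho nu_1 nu_2 phi_2^{t-s} (1 - (phi_1 phi_2)^s)/(1 - phi_1 phi_2);
    for s > t the carry-over runs through trait 1: phi_1^{s-t} with the
    cumulative factor at min(s, t).  phi_1 phi_2 -> 1 limit by continuity.
    """
    s = np.arange(1, T + 1)
    pp = phi_h * phi_d
    if abs(1.0 - pp) < 1e-10:
        cum = s.astype(float)
    else:
        cum = (1.0 - pp ** s) / (1.0 - pp)
    C = np.empty((T, T))
    for i in range(T):     # index for trait 1 time s = i+1
        for j in range(T):  # trait 2 time t = j+1
            if i <= j:
                C[i, j] = rho * nu_h * nu_d * (phi_d ** (j - i)) * cum[i]
            else:
                C[i, j] = rho * nu_h * nu_d * (phi_h ** (i - j)) * cum[j]
    return C


def sad1_covariance(psi: SADParams, T: int) -> np.ndarray:
    """Closed-form 2T x 2T covariance of the stacked (height; diameter)
    residual vector under the bivariate SAD(1) process."""
    if T < 2:
        raise InvalidInputError("T must be >= 2")
    S1 = _sad1_block(psi.phi_h, psi.nu_h, T)
    S2 = _sad1_block(psi.phi_d, psi.nu_d, T)
    C = _sad1_cross(psi.phi_h, psi.phi_d, psi.nu_h, psi.nu_d, psi.rho, T)
    top = np.hstack([S1, C])
    bot = np.hstack([C.T, S2])
    return np.vstack([top, bot])


class GLSContext:
    """Cached factorization of one SAD(1) covariance, reused across a scan."""

    def __init__(self, psi: SADParams, T: int):
        self.psi = psi
        self.T = T
        self.sigma = sad1_covariance(psi, T)
        try:
            self.chol = np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError as e:
            raise InvalidInputError(f"SAD(1) covariance not PD for psi={psi}") from e
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(self.chol))))
        self.sinv = cho_solve((self.chol, True), np.eye(2 * T))

    def whiten(self, X: np.ndarray) -> np.ndarray:
        """Rows of X mapped through L^{-1} (X may be (2T,) or (n, 2T))."""
        return solve_triangular(self.chol, np.atleast_2d(X).T, lower=True).T

    def quad(self, r: np.ndarray) -> float:
        z = self.whiten(r)
        return float(np.sum(z * z))


def bivariate_loglik(Y: np.ndarray, mu: np.ndarray, psi: SADParams) -> float:
    """Log-likelihood of n stacked 2T observations under a shared mean curve
    ``mu`` and SAD(1) covariance, via Cholesky factorization."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mu = np.asarray(mu, dtype=float)
    n, d = Y.shape
    if mu.size != d or d % 2 != 0:
        raise InvalidInputError("mean vector length must equal 2T")
    ctx = GLSContext(psi, d // 2)
    Z = ctx.whiten(Y - mu)
    return float(-0.5 * n * (d * math.log(2 * math.pi) + ctx.logdet)
                 - 0.5 * np.sum(Z * Z))


# ---------------------------------------------------------------------------
# SAD(1) parameter estimation
# ---------------------------------------------------------------------------

def _moment_sad(R: np.ndarray, T: int) -> SADParams:
    """Moment estimator: phi from the lag-1 regression of residuals, nu from
    the innovation sd, rho from the contemporaneous innovation correlation."""
    Rh, Rd = R[:, :T], R[:, T:]

    def one(Rt):
        num = float(np.sum(Rt[:, 1:] * Rt[:, :-1]))
        den = float(np.sum(Rt[:, :-1] ** 2))
        phi = num / den if den > 0 else 0.0
        phi = float(np.clip(phi, -0.98, 0.98))
        innov = np.column_stack([Rt[:, 0], Rt[:, 1:] - phi * Rt[:, :-1]])
        nu = float(max(np.std(innov), 1e-6))
        return phi, nu, innov

    phi_h, nu_h, eh = one(Rh)
    phi_d, nu_d, ed = one(Rd)
    num = float(np.sum(eh * ed))
    den = math.sqrt(float(np.sum(eh * eh)) * float(np.sum(ed * ed)))
    rho = float(np.clip(num / den if den > 0 else 0.0, -0.99, 0.99))
    return SADParams(phi_h, phi_d, nu_h, nu_d, rho)


def _psi_pack(psi: SADParams) -> np.ndarray:
    return np.array([psi.phi_h, psi.phi_d, math.log(psi.nu_h),
                     math.log(psi.nu_d), math.atanh(psi.rho)])


def _psi_unpack(x) -> SADParams:
    return SADParams(float(np.clip(x[0], -0.999, 0.999)),
                     float(np.clip(x[1], -0.999, 0.999)),
                     float(np.exp(np.clip(x[2], -20, 20))),
                     float(np.exp(np.clip(x[3], -20, 20))),
                     float(np.tanh(x[4])))


def estimate_sad_params(R: np.ndarray, T: int, refine: bool = True,
                        maxiter: int = 300) -> SADParams:
    """Estimate SAD(1) parameters from a residual matrix (n, 2T): moment
    start, then a Nelder-Mead refinement of the exact Gaussian likelihood."""
    psi0 = _moment_sad(R, T)
    if not refine:
        return psi0
    n = R.shape[0]

    def nll(x):
        psi = _psi_unpack(x)
        try:
            ctx = GLSContext(psi, T)
        except InvalidInputError:
            return 1e30
        Z = ctx.whiten(R)
        return 0.5 * n * ctx.logdet + 0.5 * float(np.sum(Z * Z))

    res = minimize(nll, _psi_pack(psi0), method="Nelder-Mead",
                   options={"maxiter": maxiter, "fatol": 1e-8, "xatol": 1e-6})
    return _psi_unpack(res.x) if res.fun < nll(_psi_pack(psi0)) else psi0


# ---------------------------------------------------------------------------
# null and alternative fits
# ---------------------------------------------------------------------------

def _floored_init(ybar: np.ndarray, T: int) -> tuple:
    """Fixed initial state for the growth ODE from a (class) mean vector.

    Trait measurements are positive, but a noisy class mean can dip below
    zero at the youngest age; the ODE's starting point is floored at a small
    positive fraction of the trait's scale so the logistic dynamics stay in
    their positive domain (the fit target itself is left untouched).
    """
    floor_h = 1e-3 * max(float(np.max(np.abs(ybar[:T]))), 1.0)
    floor_d = 1e-3 * max(float(np.max(np.abs(ybar[T:]))), 1.0)
    return max(float(ybar[0]), floor_h), max(float(ybar[T]), floor_d)


def _fit_mean_curve(ybar: np.ndarray, sinv: np.ndarray, times: np.ndarray,
                    theta0: np.ndarray, step: float, maxiter: int = 2500):
    """GLS fit of the coupled-system mean curve to one (class) mean vector,
    starting the compiled simplex from ``theta0``."""
    T = times.size
    h0, d0 = _floored_init(ybar, T)
    x, f, _ = nm_minimize_gls(theta0, ybar, sinv, times, h0, d0, step,
                              maxiter, 1e-12)
    return x, f, (h0, d0)


def fit_null(phen: PhenotypeSet, step: float = DEFAULT_RK4_STEP,
             outer_iters: int = 2, psi_init: SADParams | None = None) -> NullFit:
    """Pooled maximum-likelihood fit: coupled-growth mean curve (simplex over
    the six parameters, RK4 mean) with profiled SAD(1) covariance, iterated a
    small fixed number of outer rounds."""
    if phen.n < 2:
        raise InvalidInputError("need at least 2 individuals")
    Y = phen.stacked()
    T = phen.T
    ybar = Y.mean(axis=0)

    # ordinary least-squares start for the mean curve (clipped to the
    # positive domain the public fitter requires; only the start uses this)
    floor = 1e-3 * max(float(np.max(np.abs(ybar))), 1.0)
    cfit = fit_cri(np.maximum(ybar[:T], floor), np.maximum(ybar[T:], floor),
                   phen.times, step=step, n_starts=6)
    theta = cfit.params.to_array()
    psi = psi_init

    for _ in range(outer_iters):
        mu = _mean_from_theta(theta, phen.times, ybar, step)
        psi = estimate_sad_params(Y - mu, T)
        ctx = GLSContext(psi, T)
        theta, _, _ = _fit_mean_curve(ybar, ctx.sinv, phen.times, theta, step)

    mu = _mean_from_theta(theta, phen.times, ybar, step)
    ctx = GLSContext(psi, T)
    Z = ctx.whiten(Y - mu)
    quads = np.sum(Z * Z, axis=1)
    loglik = (-0.5 * phen.n * (2 * T * math.log(2 * math.pi) + ctx.logdet)
              - 0.5 * float(np.sum(quads)))
    h0, d0 = _floored_init(ybar, T)
    init = TraitState(h0, d0, float(phen.times[0]))
    return NullFit(theta=CRIParams.from_array(theta), psi=psi, loglik=loglik,
                   mu=mu, init=init, quad_by_individual=quads)


def _mean_from_theta(theta, times, ybar, step):
    T = times.size
    h0, d0 = _floored_init(ybar, T)
    traj = cri_rk4(np.asarray(theta, float), h0, d0, times, step)
    return np.concatenate([traj[:, 0], traj[:, 1]])


def fit_alternative(phen: PhenotypeSet, marker: MarkerGenotypes,
                    ctx: GLSContext, theta_init: np.ndarray,
                    step: float = DEFAULT_RK4_STEP,
                    min_class_size: int = 2,
                    maxiter: int = 2500,
                    reestimate_psi: bool = False) -> AlternativeFit:
    """Genotype-specific fit at one marker with the covariance held fixed.

    Classes with fewer than ``min_class_size`` individuals are dropped with a
    warning; genotypes are observed, so the likelihood factorizes into one
    GLS curve fit per class mean.  With ``reestimate_psi`` the SAD(1)
    parameters are re-estimated from the class-specific residuals and the
    class fits run once more under the updated covariance (by default the
    null fit's covariance is reused, which stabilizes small-class fits).
    """
    Y = phen.stacked()
    T = phen.T
    codes = marker.codes
    present = [j for j in range(marker.n_classes) if np.sum(codes == j) > 0]
    kept, dropped = [], []
    for j in present:
        (kept if np.sum(codes == j) >= min_class_size else dropped).append(j)
    if len(kept) < 2:
        raise DegenerateMarkerError(
            f"marker {marker.marker_id}: fewer than two usable genotype classes")
    if dropped:
        warnings.warn(f"marker {marker.marker_id}: dropped classes {dropped} "
                      f"(fewer than {min_class_size} individuals)", stacklevel=2)

    included = np.isin(codes, kept)

    def one_pass(cx):
        theta_by, sizes = {}, {}
        quad_total = 0.0
        resid = []
        for j in kept:
            Yj = Y[codes == j]
            ybar_j = Yj.mean(axis=0)
            x, f, (h0, d0) = _fit_mean_curve(ybar_j, cx.sinv, phen.times,
                                             theta_init, step, maxiter)
            theta_by[j] = CRIParams.from_array(x)
            sizes[j] = Yj.shape[0]
            traj = cri_rk4(x, h0, d0, phen.times, step)
            mu_j = np.concatenate([traj[:, 0], traj[:, 1]])
            resid.append(Yj - mu_j)
            # within-class scatter + fitted-mean offset
            Zj = cx.whiten(Yj - ybar_j)
            quad_total += float(np.sum(Zj * Zj)) + Yj.shape[0] * f
        return theta_by, sizes, quad_total, np.vstack(resid)

    theta_by, sizes, quad_total, resid = one_pass(ctx)
    if reestimate_psi:
        psi_alt = estimate_sad_params(resid, T)
        ctx = GLSContext(psi_alt, T)
        theta_by, sizes, quad_total, _ = one_pass(ctx)

    n_used = int(included.sum())
    loglik = (-0.5 * n_used * (2 * T * math.log(2 * math.pi) + ctx.logdet)
              - 0.5 * quad_total)
    return AlternativeFit(marker_id=marker.marker_id, theta_by_genotype=theta_by,
                          class_sizes=sizes, loglik=loglik, quad_total=quad_total,
                          included=included, dropped_classes=dropped,
                          psi_used=ctx.psi)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def lrt_scan(phen: PhenotypeSet, markers: list, alpha: float = 0.05,
             step: float = DEFAULT_RK4_STEP, null_fit: NullFit | None = None,
             lrt_threshold: float | None = None,
             calibration: str = "genomic_control",
             min_gc_markers: int = 20,
             keep_fits: bool = False) -> list:
    """Likelihood-ratio scan over markers.

    For each marker: LRT = 2(loglik_alt - loglik_null) on the individuals the
    marker retains, chi-square p-value with df = 6(J-1), Benjamini-Hochberg
    FDR across markers, and a Bonferroni genome-wide significance call at
    ``alpha`` (or, if ``lrt_threshold`` is given, a direct cut on the LRT
    statistic, e.g. from :func:`permutation_threshold`).

    With ``calibration='genomic_control'`` (default) the statistics are
    rescaled per degrees-of-freedom group by a genomic-control factor
    before p-values are computed: lambda is the zero-intercept regression
    slope of the group's empirical LRT quantiles on the chi-square quantiles
    over the 0.2-0.9 band (a quantile-band variant of the classic median
    ratio; the band is robust to a small number of true signals in the top
    decile), clipped at >= 1.  The shared covariance is estimated from the
    same data, and its sampling error inflates every marker's quadratic
    form by a common dataset-level factor; the scan-wide quantile ratio
    absorbs it.  Groups with fewer than ``min_gc_markers`` markers are left
    uncalibrated; ``calibration='none'`` disables the adjustment.

    Failed markers are flagged, not fatal.  Results are sorted by genome
    position when every marker carries one.
    """
    if calibration not in ("genomic_control", "none"):
        raise InvalidInputError("calibration must be genomic_control or none")
    if len(markers) == 0:
        return []
    if null_fit is None:
        null_fit = fit_null(phen, step=step)
    ctx = GLSContext(null_fit.psi, phen.T)
    theta0 = null_fit.theta.to_array()
    qnull = null_fit.quad_by_individual

    results = []
    for marker in markers:
        try:
            alt = fit_alternative(phen, marker, ctx, theta0, step=step)
        except DegenerateMarkerError:
            results.append(MappingResult(marker_id=marker.marker_id, lrt=np.nan,
                                         df=0, p_value=np.nan, failed=True,
                                         chromosome=marker.chromosome,
                                         position=marker.position))
            continue
        qn = float(np.sum(qnull[alt.included]))
        lrt = max(qn - alt.quad_total, 0.0)
        df = 6 * (len(alt.theta_by_genotype) - 1)
        results.append(MappingResult(
            marker_id=marker.marker_id, lrt=lrt, df=df, p_value=np.nan,
            theta_null=null_fit.theta,
            theta_by_genotype=alt.theta_by_genotype if keep_fits else None,
            psi_hat=null_fit.psi if keep_fits else None,
            chromosome=marker.chromosome, position=marker.position,
            n_used=int(alt.included.sum())))

    lam = {}
    if calibration == "genomic_control":
        probs = np.linspace(0.2, 0.9, 15)
        for df in {r.df for r in results if not r.failed}:
            group = np.array([r.lrt for r in results
                              if not r.failed and r.df == df])
            if group.size >= min_gc_markers:
                eq = np.quantile(group, probs)
                tq = stats.chi2.ppf(probs, df)
                lam[df] = max(1.0, float(np.sum(eq * tq) / np.sum(tq * tq)))
    for r in results:
        if not r.failed:
            r.p_value = float(stats.chi2.sf(r.lrt / lam.get(r.df, 1.0), r.df))

    ok = [r for r in results if not r.failed]
    if ok:
        praw = np.array([r.p_value for r in ok])
        p_fdr = multipletests(praw, method="fdr_bh")[1]
        m = len(ok)
        for r, pf in zip(ok, p_fdr):
            r.p_fdr = float(pf)
            if lrt_threshold is not None:
                r.significant = bool(r.lrt >= lrt_threshold)
            else:
                r.significant = bool(r.p_value <= alpha / m)
    if all(r.position is not None for r in results):
        results.sort(key=lambda r: (r.chromosome or "", r.position))
    return results


def permutation_threshold(phen: PhenotypeSet, markers: list, n_perm: int = 100,
                          alpha: float = 0.05, seed: int = 0,
                          step: float = DEFAULT_RK4_STEP) -> float:
    """Genome-wide LRT threshold from label permutations: the (1 - alpha)
    quantile of the per-permutation maximum LRT across markers."""
    rng = np.random.default_rng(seed)
    null_fit = fit_null(phen, step=step)
    maxes = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(phen.n)
        pmarkers = [MarkerGenotypes(m.marker_id, m.segregation, m.codes[perm])
                    for m in markers]
        res = lrt_scan(phen, pmarkers, step=step, null_fit=null_fit)
        maxes[b] = np.nanmax([r.lrt for r in res if not r.failed])
    return float(np.quantile(maxes, 1.0 - alpha))


# ---------------------------------------------------------------------------
# sub-hypothesis tests
# ---------------------------------------------------------------------------

def subhypothesis_tests(phen: PhenotypeSet, marker: MarkerGenotypes,
                        null_fit: NullFit, step: float = DEFAULT_RK4_STEP,
                        maxiter: int = 4000) -> tuple:
    """Test which part of the parameter set a significant marker perturbs.

    Two nested constrained refits against the free genotype-specific fit:
    (1) independence parameters (alpha_H, K_H, alpha_D, K_D) shared across
    classes, betas free, df = 4(J-1); (2) interaction parameters (beta_HD,
    beta_DH) shared, the rest free, df = 2(J-1).

    Returns ``(independent_test, interaction_test)``.
    """
    ctx = GLSContext(null_fit.psi, phen.T)
    theta0 = null_fit.theta.to_array()
    alt = fit_alternative(phen, marker, ctx, theta0, step=step)
    J = len(alt.theta_by_genotype)
    kept = sorted(alt.theta_by_genotype)
    Y = phen.stacked()
    T = phen.T
    times = phen.times
    ybars = {j: Y[marker.codes == j].mean(axis=0) for j in kept}
    sizes = alt.class_sizes

    def class_quads(thetas):
        """sum_j n_j (ybar_j - mu(theta_j))' Sinv (ybar_j - mu(theta_j))"""
        q = 0.0
        for j, th in zip(kept, thetas):
            if th[0] <= 0 or th[1] <= 0 or th[3] <= 0 or th[4] <= 0:
                return 1e30
            ybar = ybars[j]
            h0, d0 = _floored_init(ybar, T)
            traj = cri_rk4(th, h0, d0, times, step)
            if not np.isfinite(traj).all():
                return 1e30
            r = ybar - np.concatenate([traj[:, 0], traj[:, 1]])
            q += sizes[j] * float(r @ ctx.sinv @ r)
        return q

    # free-fit offset part of the quadratic form (class scatter, constant here)
    free_offset = alt.quad_total - class_quads(
        [alt.theta_by_genotype[j].to_array() for j in kept])

    def run(constrained_idx):
        """NM over [shared params at constrained_idx] + per-class free rest."""
        free_idx = [i for i in range(6) if i not in constrained_idx]
        th_free = [alt.theta_by_genotype[j].to_array() for j in kept]
        shared0 = np.mean([t[constrained_idx] for t in th_free], axis=0)
        x0 = np.concatenate([shared0] + [t[free_idx] for t in th_free])

        def unpack(x):
            shared = x[:len(constrained_idx)]
            out = []
            for jj in range(J):
                th = np.empty(6)
                th[constrained_idx] = shared
                th[free_idx] = x[len(constrained_idx) + jj * len(free_idx):
                                 len(constrained_idx) + (jj + 1) * len(free_idx)]
                out.append(th)
            return out

        res = minimize(lambda x: class_quads(unpack(x)), x0,
                       method="Nelder-Mead",
                       options={"maxiter": maxiter, "fatol": 1e-10, "xatol": 1e-8})
        q_constr = res.fun + free_offset
        lrt = max(q_constr - alt.quad_total, 0.0)
        df = len(constrained_idx) * (J - 1)
        return SubTestResult(lrt=lrt, df=df,
                             p_value=float(stats.chi2.sf(lrt, df)),
                             converged=bool(res.success or res.fun < 1e29))

    ind_test = run([0, 1, 3, 4])
    int_test = run([2, 5])
    return ind_test, int_test


# ---------------------------------------------------------------------------
# genetic effect curves
# ---------------------------------------------------------------------------

def genetic_effect_curves(theta_by_genotype: dict, freqs, times,
                          init: TraitState, marker_id: str = "",
                          step: float = DEFAULT_RK4_STEP,
                          uncoupled_independent: bool = False) -> EffectCurvePair:
    """Time-indexed genetic standard deviations and the dynamic genetic
    correlation at one marker.

    g_trait(t) = sqrt( sum_j w_j (mu_j(t) - mubar(t))^2 ) over the genotype
    class mean curves solved by RK4 under each Theta_j from the shared
    initial state.  The independent variants replace each class curve by its
    self-regulated component accumulated along the coupled trajectory (or,
    with ``uncoupled_independent``, by re-solving the uncoupled logistic).
    """
    keys = sorted(theta_by_genotype)
    w = np.asarray(freqs, dtype=float)
    if not math.isclose(w.sum(), 1.0, rel_tol=1e-6):
        raise InvalidInputError("class frequencies must sum to 1")
    t = np.asarray(times, dtype=float)
    if len(keys) < 2:
        warnings.warn("single genotype class: effect curves are zero", stacklevel=2)
        z = np.zeros_like(t)
        return EffectCurvePair(marker_id, t, z, z.copy(), z.copy(), z.copy(), z.copy())

    curves_h, curves_d, ind_h, ind_d = [], [], [], []
    for j in keys:
        params = theta_by_genotype[j]
        traj = integrate_cri(params, init, t, step=step)
        curves_h.append(traj.height)
        curves_d.append(traj.diameter)
        if uncoupled_independent:
            p0 = CRIParams(params.alpha_h, params.k_h, 0.0,
                           params.alpha_d, params.k_d, 0.0)
            utraj = integrate_cri(p0, init, t, step=step)
            ind_h.append(utraj.height)
            ind_d.append(utraj.diameter)
        else:
            dec = decompose_growth(params, traj)
            ind_h.append(init.h + dec.cumulative_independent_h)
            ind_d.append(init.d + dec.cumulative_independent_d)

    def wsd(curves):
        M = np.array(curves)
        mbar = w @ M
        dev = M - mbar
        return np.sqrt(np.clip(w @ (dev ** 2), 0.0, None)), dev

    g1, dev1 = wsd(curves_h)
    g2, dev2 = wsd(curves_d)
    gi1, _ = wsd(ind_h)
    gi2, _ = wsd(ind_d)
    num = w @ (dev1 * dev2)
    den = g1 * g2
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / den, 0.0)
    return EffectCurvePair(marker_id, t, g1, g2, gi1, gi2, corr)
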