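"""Bivariate functional clustering of per-SNP genetic-effect curves.

Genome-wide SNPs are grouped into modules by a Gaussian mixture over whole
curves: each SNP contributes a stacked 2T-vector (height effect curve;
diameter effect curve), each module l has a mean curve built from Legendre
orthogonal polynomial (LOP) expansions of order r per trait, and a single
SAD(1) covariance is shared across modules.  A hybrid EM-simplex algorithm
fits the model: the E-step computes posterior module memberships, the M-step
updates mixture weights exactly (omega_l = mean posterior), the LOP
coefficients by weighted generalized least squares, and the covariance
parameters by a short Nelder-Mead move on the expected complete-data
likelihood.  The number of modules is chosen by AIC/BIC over a grid, and
modules can be subclustered recursively into submodules (labels SM<i>/<parent>),
giving the module -> submodule -> SNP hierarchy used for multilayer network
construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import InvalidInputError
from .mapping import GLSContext, SADParams, _psi_pack, _psi_unpack, estimate_sad_params

DEFAULT_LOP_ORDER = 4


# ---------------------------------------------------------------------------
# Legendre basis
# ---------------------------------------------------------------------------

@dataclass
class LOPBasis:
    """Legendre polynomials P_0..P_r evaluated on an affinely mapped grid."""

    order: int
    t_min: float
    t_max: float
    times: np.ndarray
    matrix: np.ndarray  # (T, order+1)

    def map_times(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return 2.0 * (t - self.t_min) / (self.t_max - self.t_min) - 1.0

    def evaluate(self, times) -> np.ndarray:
        return np.polynomial.legendre.legvander(self.map_times(times), self.order)


def lop_basis(times, order: int) -> LOPBasis:
    """Build the LOP basis on ``times`` mapped to [-1, 1]."""
    t = np.asarray(times, dtype=float)
    if order < 0:
        raise InvalidInputError("order must be >= 0")
    if np.unique(t).size < 2:
        raise InvalidInputError("need at least 2 distinct times")
    if order >= t.size:
        warnings.warn("LOP order >= number of time points: interpolation regime",
                      stacklevel=2)
    x = 2.0 * (t - t.min()) / (t.max() - t.min()) - 1.0
    B = np.polynomial.legendre.legvander(x, order)
    return LOPBasis(order=order, t_min=float(t.min()), t_max=float(t.max()),
                    times=t, matrix=B)


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------

@dataclass
class MixtureModel:
    """Fitted curve mixture: weights, per-module LOP coefficients for both
    traits, shared SAD(1) covariance parameters, and fit criteria."""

    L: int
    omega: np.ndarray          # (L,)
    Phi: np.ndarray            # (L, 2, order+1)
    psi_g: SADParams
    basis: LOPBasis
    loglik: float
    aic: float
    bic: float
    n_params: int
    n_iter: int
    loglik_trace: np.ndarray = field(default=None)

    def mean_curves(self) -> np.ndarray:
        """(L, 2T) model-based module mean curves on the fitting grid."""
        B = self.basis.matrix
        return np.stack([np.concatenate([B @ self.Phi[l, 0], B @ self.Phi[l, 1]])
                         for l in range(self.L)])


@dataclass
class PosteriorMatrix:
    """Posterior module memberships Omega_{l|k} and MAP assignments."""

    omega_matrix: np.ndarray   # (p, L), rows sum to 1
    hard_assignment: np.ndarray  # (p,), ties broken toward the lowest index


def _log_densities(curves, means, ctx: GLSContext) -> np.ndarray:
    """(p, L) log N(g_k; u_l, Sigma) via the cached Cholesky."""
    p, d = curves.shape
    L = means.shape[0]
    const = -0.5 * (d * math.log(2 * math.pi) + ctx.logdet)
    out = np.empty((p, L))
    for l in range(L):
        Z = ctx.whiten(curves - means[l])
        out[:, l] = const - 0.5 * np.sum(Z * Z, axis=1)
    return out


def _gls_coef_operator(basis: LOPBasis, ctx: GLSContext) -> np.ndarray:
    """Operator A with Phi_vec = A @ (weighted mean curve): the GLS projection
    onto the block-diagonal two-trait LOP design."""
    B = basis.matrix
    T, q = B.shape
    X = np.zeros((2 * T, 2 * q))
    X[:T, :q] = B
    X[T:, q:] = B
    Xi = ctx.sinv @ X
    return np.linalg.solve(X.T @ Xi, Xi.T)


def em_fit(curves, times, L: int, order: int = DEFAULT_LOP_ORDER,
           max_iter: int = 500, tol: float = 1e-6, seed: int = 0,
           n_restarts: int = 5, psi_maxiter: int = 80,
           psi_init: SADParams | None = None,
           shared_covariance: bool = True):
    """Fit the L-module curve mixture by EM with k-means initialization.

    Runs ``n_restarts`` seeded EM chains and keeps the best likelihood.
    Returns ``(MixtureModel, PosteriorMatrix)``.  Empty modules (weight below
    1/(10p)) are re-seeded from the worst-fit curve.  With
    ``shared_covariance=False`` each module carries its own SAD(1)
    parameters (``psi_g`` becomes a list of length L) at the cost of
    5(L-1) extra parameters in the criteria.
    """
    G = np.asarray(curves, dtype=float)
    p, d = G.shape
    t = np.asarray(times, dtype=float)
    T = t.size
    if d != 2 * T:
        raise InvalidInputError("curves must be (p, 2T) with the given times")
    if p < L:
        raise InvalidInputError("need at least L curves")
    basis = lop_basis(t, order)

    best = None
    for r in range(n_restarts):
        out = _em_once(G, basis, L, max_iter, tol, seed + 1000 * r,
                       psi_maxiter, psi_init, shared_covariance)
        if best is None or out[0].loglik > best[0].loglik:
            best = out
    return best


def _em_once(G, basis, L, max_iter, tol, seed, psi_maxiter, psi_init,
             shared_covariance=True):
    p, d = G.shape
    T = d // 2

    # --- initialization: k-means hard labels -> first M-step
    if L == 1:
        labels = np.zeros(p, dtype=int)
    else:
        km = KMeans(n_clusters=L, random_state=seed, n_init=3)
        labels = km.fit_predict(G)
    R = np.zeros((p, L))
    R[np.arange(p), labels] = 1.0

    if psi_init is None:
        centers = np.stack([G[labels == l].mean(axis=0) if np.any(labels == l)
                            else G.mean(axis=0) for l in range(L)])
        psi0 = estimate_sad_params(G - centers[labels], T, refine=False)
    else:
        psi0 = psi_init
    psis = [psi0] if shared_covariance else [psi0] * L

    omega = np.full(L, 1.0 / L)
    means = np.zeros((L, d))
    loglik_prev = -np.inf
    trace = []
    n_iter = 0

    def make_ctxs():
        return [GLSContext(ps, T) for ps in psis]

    def densities(ctxs):
        if len(ctxs) == 1:
            return _log_densities(G, means, ctxs[0])
        out = np.empty((p, L))
        for l in range(L):
            out[:, l] = _log_densities(G, means[l:l + 1], ctxs[l])[:, 0]
        return out

    for it in range(max_iter):
        n_iter = it + 1
        ctxs = make_ctxs()

        # --- M-step (uses responsibilities R from previous E-step / init)
        cw = R.sum(axis=0)
        # re-seed empty modules from the worst-fit curve
        if it > 0:
            logf_cur = densities(ctxs)
            for l in range(L):
                if cw[l] < 0.1 or omega[l] < 1.0 / (10.0 * p):
                    worst = int(np.argmin(logsumexp(
                        logf_cur + np.log(np.maximum(omega, 1e-300)), axis=1)))
                    warnings.warn(f"re-seeding empty module {l} from curve {worst}",
                                  stacklevel=2)
                    R[:, l] = 0.0
                    R[worst, :] = 0.0
                    R[worst, l] = 1.0
                    cw = R.sum(axis=0)
        omega = np.maximum(cw, 1e-12) / np.maximum(cw.sum(), 1e-12)

        q = basis.order + 1
        Phi = np.empty((L, 2, q))
        A_shared = _gls_coef_operator(basis, ctxs[0]) if len(ctxs) == 1 else None
        for l in range(L):
            A = A_shared if A_shared is not None else \
                _gls_coef_operator(basis, ctxs[l])
            wsum = max(cw[l], 1e-12)
            gbar = (R[:, l] @ G) / wsum
            coef = A @ gbar
            Phi[l, 0] = coef[:q]
            Phi[l, 1] = coef[q:]
            means[l] = np.concatenate([basis.matrix @ Phi[l, 0],
                                       basis.matrix @ Phi[l, 1]])

        # covariance move: short simplex on the expected complete-data loglik,
        # started at the current psi so the EM ascent property is preserved
        def update_psi(current, S, weight):
            def q_neg(x):
                try:
                    cx = GLSContext(_psi_unpack(x), T)
                except InvalidInputError:
                    return 1e30
                return weight * cx.logdet + float(np.sum(cx.sinv * S))

            res = minimize(q_neg, _psi_pack(current), method="Nelder-Mead",
                           options={"maxiter": psi_maxiter, "fatol": 1e-10})
            return _psi_unpack(res.x) if res.fun <= q_neg(_psi_pack(current)) \
                else current

        if shared_covariance:
            S = np.zeros((d, d))
            for l in range(L):
                Dl = G - means[l]
                S += (Dl * R[:, l][:, None]).T @ Dl
            psis = [update_psi(psis[0], S, p)]
        else:
            new = []
            for l in range(L):
                Dl = G - means[l]
                S_l = (Dl * R[:, l][:, None]).T @ Dl
                new.append(update_psi(psis[l], S_l, max(cw[l], 1e-12)))
            psis = new

        # --- E-step
        logf = densities(make_ctxs())
        logw = logf + np.log(np.maximum(omega, 1e-300))
        norm = logsumexp(logw, axis=1)
        R = np.exp(logw - norm[:, None])
        loglik = float(np.sum(norm))
        trace.append(loglik)
        if abs(loglik - loglik_prev) < tol * (1.0 + abs(loglik)):
            loglik_prev = loglik
            break
        loglik_prev = loglik

    n_cov = 5 if shared_covariance else 5 * L
    n_params = (L - 1) + L * 2 * (basis.order + 1) + n_cov
    aic = -2.0 * loglik_prev + 2.0 * n_params
    bic = -2.0 * loglik_prev + n_params * math.log(p)
    psi_g = psis[0] if shared_covariance else list(psis)
    model = MixtureModel(L=L, omega=omega, Phi=Phi, psi_g=psi_g, basis=basis,
                         loglik=loglik_prev, aic=aic, bic=bic,
                         n_params=n_params, n_iter=n_iter,
                         loglik_trace=np.array(trace))
    hard = np.argmax(R, axis=1)
    return model, PosteriorMatrix(omega_matrix=R, hard_assignment=hard)


def select_num_modules(curves, times, L_range, criterion: str = "BIC",
                       order: int = DEFAULT_LOP_ORDER, seed: int = 0,
                       **em_kwargs):
    """Fit every L in ``L_range`` (seed-per-L deterministic) and return
    ``(best_model, best_posterior, trace)`` minimizing AIC or BIC; ``trace``
    is a list of (L, criterion value, loglik)."""
    L_list = sorted(set(int(L) for L in L_range))
    if not L_list:
        raise InvalidInputError("L_range must be non-empty")
    if criterion.upper() not in ("AIC", "BIC"):
        raise InvalidInputError("criterion must be AIC or BIC")
    best = None
    trace = []
    errors = []
    for L in L_list:
        try:
            model, post = em_fit(curves, times, L, order=order,
                                 seed=seed + 17 * L, **em_kwargs)
        except Exception as e:  # aggregate; a single L may legitimately fail
            errors.append((L, e))
            continue
        crit = model.bic if criterion.upper() == "BIC" else model.aic
        trace.append((L, crit, model.loglik))
        if best is None or crit < best[2]:
            best = (model, post, crit)
    if best is None:
        raise InvalidInputError(f"all mixture fits failed: {errors}")
    return best[0], best[1], trace


# ---------------------------------------------------------------------------
# module tree
# ---------------------------------------------------------------------------

@dataclass
class ModuleNode:
    label: str
    members: np.ndarray            # indices into the curve matrix
    mean_curve: np.ndarray         # (2T,) empirical mean of member curves
    parent: str | None = None
    children: list = field(default_factory=list)
    model: MixtureModel | None = None


@dataclass
class ModuleTree:
    """Hierarchy of modules (M<i>) and submodules (SM<j>/M<i>) over SNPs."""

    nodes: dict
    snp_ids: list
    curves: np.ndarray
    times: np.ndarray

    def children_partition_parent(self, label: str) -> bool:
        node = self.nodes[label]
        if not node.children:
            return True
        merged = np.sort(np.concatenate(
            [self.nodes[c].members for c in node.children]))
        return np.array_equal(merged, np.sort(node.members))


def build_module_tree(curves, times, model: MixtureModel,
                      posterior: PosteriorMatrix,
                      snp_ids=None) -> ModuleTree:
    """Top-level tree from a fitted mixture: one node M<l> per module, with
    MAP member assignment (ties to the lowest module index)."""
    G = np.asarray(curves, dtype=float)
    p = G.shape[0]
    ids = list(snp_ids) if snp_ids is not None else [f"snp{k}" for k in range(p)]
    tree = ModuleTree(nodes={}, snp_ids=ids, curves=G,
                      times=np.asarray(times, float))
    root_members = np.arange(p)
    tree.nodes["root"] = ModuleNode("root", root_members, G.mean(axis=0))
    for l in range(model.L):
        members = np.where(posterior.hard_assignment == l)[0]
        mean = G[members].mean(axis=0) if members.size else model.mean_curves()[l]
        label = f"M{l + 1}"
        tree.nodes[label] = ModuleNode(label, members, mean, parent="root")
        tree.nodes["root"].children.append(label)
    tree.nodes["root"].model = model
    return tree


def subcluster(tree: ModuleTree, label: str, L_range, criterion: str = "BIC",
               order: int = DEFAULT_LOP_ORDER, seed: int = 0,
               **em_kwargs) -> ModuleTree:
    """Split one node into submodules labelled SM<i>/<label> by refitting the
    mixture on its member curves; a node too small for the requested range is
    left unchanged with a warning."""
    node = tree.nodes[label]
    if node.members.size < 2 * min(int(L) for L in L_range):
        warnings.warn(f"node {label} too small to subcluster", stacklevel=2)
        return tree
    sub = tree.curves[node.members]
    model, post, _ = select_num_modules(sub, tree.times, L_range,
                                        criterion=criterion, order=order,
                                        seed=seed, **em_kwargs)
    node.model = model
    node.children = []
    for l in range(model.L):
        members = node.members[post.hard_assignment == l]
        if members.size == 0:
            continue
        child = f"SM{l + 1}/{label}"
        mean = tree.curves[members].mean(axis=0)
        tree.nodes[child] = ModuleNode(child, members, mean, parent=label)
        node.children.append(child)
    return tree


def module_mean_curves(model: MixtureModel = None, curves=None,
                       posterior: PosteriorMatrix = None,
                       model_based: bool = False) -> np.ndarray:
    """(L, 2T) per-module mean effect curves: empirical means of MAP members
    by default, or the model's LOP mean curves with ``model_based``."""
    if model_based:
        if model is None:
            raise InvalidInputError("model_based=True requires a fitted model")
        return model.mean_curves()
    if curves is None or posterior is None:
        raise InvalidInputError("empirical means require curves and posterior")
    G = np.asarray(curves, dtype=float)
    L = posterior.omega_matrix.shape[1]
    out = np.empty((L, G.shape[1]))
    for l in range(L):
        members = posterior.hard_assignment == l
        out[l] = G[members].mean(axis=0) if members.any() else \
            (model.mean_curves()[l] if model is not None else G.mean(axis=0))
    return out
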