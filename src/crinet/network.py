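"""Multilayer epistatic network reconstruction from genetic-effect curves.

Nodes are modules, submodules, or individual SNPs, each carrying a genetic
effect curve over time for one trait.  Reconstruction follows three steps:

1.  **Smoothing and interpolation** -- each node's curve is fit with Legendre
    orthogonal polynomials and evaluated on a dense grid (default 100
    points), which also resolves the case of more nodes than time points.
2.  **Variable selection** -- for each focal node, LASSO on the regression of
    its curve values on all other nodes' curve values picks a sparse
    regulator set (penalty by 5-fold cross-validation with the one-standard-
    error rule, or BIC).
3.  **ODE decomposition** -- the focal node's derivative is decomposed as

        dg_l/dt = G_l0(g_l) + sum_{l' in regulators} G_{l<-l'}(g_l'),

    with each term a low-order Legendre expansion in the corresponding
    node's (value-mapped) state, fit by least squares against the smoothed
    derivative; the focal curve is reconstructed by RK4 as a consistency
    check.  The independent component absorbs the least-squares residual so
    that independent + dependent always reproduces the smoothed derivative
    exactly.

Each regulator contributes a directed, signed, weighted edge l' -> l: weight
is the time-averaged magnitude of the dependent derivative, sign its
time-averaged direction (activation vs inhibition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.linear_model import Lasso, LassoCV, lasso_path

from .clustering import lop_basis
from .errors import InvalidInputError

LAYER_METAGALACTIC = "metagalactic"   # among modules
LAYER_INTERGALACTIC = "intergalactic"  # among submodules of one module
LAYER_LOCAL = "local"                 # among SNPs of one submodule

VARIANT_OVERALL = "overall"
VARIANT_INDEPENDENT = "independent"

DEFAULT_N_DENSE = 100
DEFAULT_SMOOTH_ORDER = 4
DEFAULT_DECOMP_ORDER = 3
EDGE_WEIGHT_FLOOR = 1e-8
SMOOTH_RMSE_TOL = 0.02   # fraction of curve range


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

@dataclass
class SmoothedCurve:
    node_id: str
    times: np.ndarray
    values: np.ndarray
    coef: np.ndarray
    dense_times: np.ndarray
    dense_values: np.ndarray
    dense_deriv: np.ndarray
    rmse: float


def smooth_and_interpolate(node_id: str, values, times,
                           order: int = DEFAULT_SMOOTH_ORDER,
                           n_dense: int = DEFAULT_N_DENSE) -> SmoothedCurve:
    """Least-squares Legendre fit of one effect curve plus dense evaluation
    of the polynomial and its analytic derivative."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if t.size < 3:
        raise InvalidInputError("need at least 3 observed times")
    if order >= t.size:
        raise InvalidInputError(
            f"order {order} >= {t.size} points would interpolate noise exactly")
    basis = lop_basis(t, order)
    coef, *_ = np.linalg.lstsq(basis.matrix, y, rcond=None)
    fitted = basis.matrix @ coef
    rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
    rng_y = float(np.ptp(y))
    if rng_y > 0 and rmse > SMOOTH_RMSE_TOL * rng_y:
        warnings.warn(f"{node_id}: smoothing RMSE {rmse:.3g} exceeds "
                      f"{SMOOTH_RMSE_TOL:.0%} of the curve range", stacklevel=2)
    dense_t = np.linspace(t[0], t[-1], n_dense)
    x = basis.map_times(dense_t)
    dense_v = np.polynomial.legendre.legval(x, coef)
    dcoef = np.polynomial.legendre.legder(coef)
    chain = 2.0 / (basis.t_max - basis.t_min)
    dense_d = np.polynomial.legendre.legval(x, dcoef) * chain
    return SmoothedCurve(node_id=node_id, times=t, values=y, coef=coef,
                         dense_times=dense_t, dense_values=dense_v,
                         dense_deriv=dense_d, rmse=rmse)


# ---------------------------------------------------------------------------
# variable selection
# ---------------------------------------------------------------------------

@dataclass
class RegressionSpec:
    focal_id: str
    intercept: float
    coefficients: dict           # candidate id -> b (on the original scale)
    support: list                # ids with nonzero b, never the focal itself
    residual: np.ndarray


def select_regulators(focal: SmoothedCurve, candidates: list,
                      selector: str = "lasso_pr2", target: str = "derivative",
                      pr2_threshold: float = 0.7, cv: int = 5,
                      max_in_degree: int | None = None,
                      seed: int = 0) -> RegressionSpec:
    """Sparse regulator selection for one focal node.

    With the default ``target='derivative'`` the response is the focal
    node's smoothed derivative -- the left side of the network ODE -- which
    makes selection directional (a regulator's value curve explaining the
    focal's rate of change is not a symmetric relation).  ``target='value'``
    regresses the focal curve's values instead (the static screen
    g_l(t) = a_l + sum b_l' g_l'(t) + e_l(t)).

    ``selector``:

    * ``lasso_pr2`` (default) -- LASSO path screen followed by backward
      elimination of regulators whose partial R^2 (relative reduction of the
      residual sum of squares when the regulator is added last) falls below
      ``pr2_threshold``.  Smooth curves occupy few effective dimensions, so
      chance fits reach sizeable R^2; the partial-R^2 floor is what controls
      false edges.
    * ``cv`` / ``cv1se`` -- cross-validated penalty (minimum, or the
      one-standard-error rule).
    * ``bic`` -- BIC along the path, with the observed time count (not the
      interpolated grid size) as the effective sample size.

    ``max_in_degree`` keeps only the largest standardized-|b| regulators.
    """
    cands = [c for c in candidates if c.node_id != focal.node_id]
    if len(cands) == 0:
        raise InvalidInputError("need at least one candidate regulator")
    if target not in ("derivative", "value"):
        raise InvalidInputError("target must be 'derivative' or 'value'")
    y = focal.dense_deriv if target == "derivative" else focal.dense_values
    X = np.column_stack([c.dense_values for c in cands])
    sd = X.std(axis=0)
    usable = sd > 1e-12
    if not np.any(usable) or y.std() < 1e-12:
        return RegressionSpec(focal.node_id, float(y.mean()), {}, [],
                              y - y.mean())
    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    yc = y - y.mean()
    n = y.size
    n_eff = focal.times.size

    def _path():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return lasso_path(Xs, yc, alphas=60)

    if selector in ("cv", "cv1se"):
        lcv = LassoCV(cv=cv, alphas=60, random_state=seed, max_iter=50000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lcv.fit(Xs, y)
        alpha = lcv.alpha_
        if selector == "cv1se":
            mse_mean = lcv.mse_path_.mean(axis=1)
            mse_se = lcv.mse_path_.std(axis=1) / np.sqrt(lcv.mse_path_.shape[1])
            i_min = int(np.argmin(mse_mean))
            limit = mse_mean[i_min] + mse_se[i_min]
            ok = np.where(mse_mean <= limit)[0]
            # alphas_ are descending: the smallest index is the largest penalty
            alpha = float(lcv.alphas_[ok.min()]) if ok.size else alpha
        model = Lasso(alpha=alpha, max_iter=50000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, y)
        coefs_std = model.coef_
    elif selector == "bic":
        alphas, coefs, _ = _path()
        best_bic, coefs_std = np.inf, np.zeros(Xs.shape[1])
        for k in range(alphas.size):
            c = coefs[:, k]
            rss = float(np.sum((yc - Xs @ c) ** 2))
            df = int(np.sum(c != 0))
            bic = n_eff * np.log(max(rss / n, 1e-300)) + df * np.log(n_eff)
            if bic < best_bic:
                best_bic, coefs_std = bic, c
    elif selector == "lasso_pr2":
        _, coefs, _ = _path()
        active = [i for i in range(Xs.shape[1]) if np.any(coefs[i] != 0)]

        def rss_of(idx):
            if not idx:
                return float(np.sum(yc ** 2))
            beta, *_ = np.linalg.lstsq(Xs[:, idx], yc, rcond=None)
            return float(np.sum((yc - Xs[:, idx] @ beta) ** 2))

        while active:
            r_full = rss_of(active)
            pr2 = {i: (rss_of([j for j in active if j != i]) - r_full)
                   / max(rss_of([j for j in active if j != i]), 1e-300)
                   for i in active}
            worst = min(pr2, key=pr2.get)
            if pr2[worst] < pr2_threshold:
                active.remove(worst)
            else:
                break
        coefs_std = np.zeros(Xs.shape[1])
        if active:
            beta, *_ = np.linalg.lstsq(Xs[:, active], yc, rcond=None)
            coefs_std[active] = beta
    else:
        raise InvalidInputError(f"unknown selector {selector!r}")

    ids = [c.node_id for c, u in zip(cands, usable) if u]
    b = {nid: float(cs / s) for nid, cs, s in
         zip(ids, coefs_std, sd[usable]) if cs != 0.0}
    if max_in_degree is not None and len(b) > max_in_degree:
        keep = sorted(b, key=lambda k: -abs(b[k] * sd[usable][ids.index(k)]))
        b = {k: b[k] for k in keep[:max_in_degree]}
    support = sorted(b)
    Xfull = np.column_stack([c.dense_values for c in cands])
    pred = sum(b.get(c.node_id, 0.0) * Xfull[:, i] for i, c in enumerate(cands))
    intercept = float((y - pred).mean())
    return RegressionSpec(focal.node_id, intercept, b, support,
                          y - pred - intercept)


# ---------------------------------------------------------------------------
# ODE decomposition
# ---------------------------------------------------------------------------

@dataclass
class ODEDecomposition:
    """Decomposition of one node's derivative into an independent term and
    per-regulator dependent terms on the dense grid.  The independent term
    absorbs the least-squares residual, so conservation

        independent_deriv + sum(dependent_derivs) == smoothed derivative

    holds exactly at every grid point.  Curves are cumulative trapezoid
    integrals, offset so the independent curve starts at the first value.
    """

    focal_id: str
    regulators: list
    dense_times: np.ndarray
    independent_deriv: np.ndarray
    dependent_derivs: dict       # regulator id -> derivative curve
    independent_curve: np.ndarray
    dependent_curves: dict
    net_curve: np.ndarray        # smoothed focal values on the dense grid
    reconstructed: np.ndarray    # RK4 reconstruction from the first value
    reconstruction_rmse: float
    theta_own: np.ndarray = None
    theta_from: dict = field(default_factory=dict)
    regulator_states: dict = field(default_factory=dict)
    ridge_fallback: bool = False


def _map_state(values: np.ndarray) -> np.ndarray:
    """Map a node's values to [-1, 1] over their range."""
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return np.zeros_like(values)
    return 2.0 * (values - lo) / (hi - lo) - 1.0


def _state_basis(values: np.ndarray, order: int, with_const: bool) -> np.ndarray:
    """Legendre columns in a node's value, mapped to [-1, 1] over its range."""
    V = np.polynomial.legendre.legvander(_map_state(values), order)
    return V if with_const else V[:, 1:]


def _cumint(t, y):
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))
    return out


def fit_ode_decomposition(focal: SmoothedCurve, spec: RegressionSpec,
                          regulators: dict,
                          order: int = DEFAULT_DECOMP_ORDER,
                          cond_limit: float = 1e10) -> ODEDecomposition:
    """Fit the network ODE for one focal node.

    The independent term G_l0 is a Legendre expansion in the focal node's own
    (value-mapped) state; each dependent term G_{l<-l'} is a Legendre
    expansion (without constant, which belongs to G_l0) in the regulator's
    state.  Coefficients come from least squares against the smoothed focal
    derivative; an ill-conditioned design falls back to a small ridge.
    """
    reg_ids = [r for r in spec.support if r in regulators]
    t = focal.dense_times
    y = focal.dense_deriv
    own = _state_basis(focal.dense_values, order, with_const=True)
    blocks = [own]
    for rid in reg_ids:
        blocks.append(_state_basis(regulators[rid].dense_values, order,
                                   with_const=False))
    X = np.hstack(blocks)

    ridge = False
    cond = np.linalg.cond(X)
    if cond > cond_limit:
        ridge = True
        warnings.warn(f"{focal.node_id}: design condition {cond:.2g} > "
                      f"{cond_limit:.0g}; ridge fallback", stacklevel=2)
        lam = 1e-8 * np.trace(X.T @ X) / X.shape[1]
        beta = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    q_own = order + 1
    theta_own = beta[:q_own]
    dep_derivs, theta_from, reg_states = {}, {}, {}
    pos = q_own
    dep_sum = np.zeros_like(y)
    for rid in reg_ids:
        th = beta[pos:pos + order]
        pos += order
        comp = _state_basis(regulators[rid].dense_values, order,
                            with_const=False) @ th
        dep_derivs[rid] = comp
        theta_from[rid] = th
        reg_states[rid] = _map_state(regulators[rid].dense_values)
        dep_sum += comp
    ind_deriv = y - dep_sum   # own term + residual: conservation by construction

    ind_curve = focal.dense_values[0] + _cumint(t, ind_deriv)
    dep_curves = {rid: _cumint(t, d) for rid, d in dep_derivs.items()}

    # RK4 reconstruction of the focal curve from the time-interpolated RHS
    recon = _rk4_reconstruct(t, y, focal.dense_values[0])
    rmse = float(np.sqrt(np.mean((recon - focal.dense_values) ** 2)))
    return ODEDecomposition(focal_id=focal.node_id, regulators=reg_ids,
                            dense_times=t, independent_deriv=ind_deriv,
                            dependent_derivs=dep_derivs,
                            independent_curve=ind_curve,
                            dependent_curves=dep_curves,
                            net_curve=focal.dense_values.copy(),
                            reconstructed=recon, reconstruction_rmse=rmse,
                            theta_own=theta_own, theta_from=theta_from,
                            regulator_states=reg_states, ridge_fallback=ridge)


def _rk4_reconstruct(t, deriv, y0):
    """Classic RK4 on dy/dt = f(t) with f linearly interpolated between the
    dense grid nodes."""
    def f(tt):
        return float(np.interp(tt, t, deriv))

    out = np.empty_like(deriv)
    out[0] = y0
    y = y0
    for k in range(t.size - 1):
        h = t[k + 1] - t[k]
        k1 = f(t[k])
        k2 = f(t[k] + 0.5 * h)
        k3 = k2
        k4 = f(t[k + 1])
        y = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        out[k + 1] = y
    return out


# ---------------------------------------------------------------------------
# edges and networks
# ---------------------------------------------------------------------------

@dataclass
class Edge:
    source: str
    target: str
    sign: int          # +1 activation, -1 inhibition
    weight: float      # >= 0


def edge_from_decomposition(dec: ODEDecomposition,
                            weight_floor: float = EDGE_WEIGHT_FLOOR) -> list:
    """Directed edges into the focal node.

    Weight is the time-averaged |dependent derivative|.  Sign is the
    response direction: the time-averaged slope of G_{l<-l'} with respect to
    the regulator's state (positive slope = the regulator promotes the
    focal's rate of change = activation).  For a linear dependence
    c * g_l'(t) this is exactly sign(c), and unlike the sign of the
    component's time average it does not hinge on where the regulator's
    curve sits relative to zero.  Components below ``weight_floor``
    contribute no edge.
    """
    edges = []
    for rid, comp in dec.dependent_derivs.items():
        weight = float(np.mean(np.abs(comp)))
        if weight < weight_floor:
            continue
        th = dec.theta_from[rid]
        # G_{l<-l'}(x) = sum_m th[m-1] P_m(x); slope along the trajectory
        coef = np.concatenate([[0.0], th])
        dcoef = np.polynomial.legendre.legder(coef)
        x = dec.regulator_states[rid]
        slope = float(np.mean(np.polynomial.legendre.legval(x, dcoef)))
        sign = 1 if slope >= 0 else -1
        edges.append(Edge(source=rid, target=dec.focal_id, sign=sign,
                          weight=weight))
    return edges


@dataclass
class EpistaticNetwork:
    layer: str
    trait: str
    variant: str
    graph: nx.DiGraph
    decompositions: dict
    failures: list = field(default_factory=list)

    @property
    def edges(self) -> list:
        return [Edge(u, v, d["sign"], d["weight"])
                for u, v, d in self.graph.edges(data=True)]


def build_layer_network(node_curves: dict, times, trait: str,
                        variant: str = VARIANT_OVERALL,
                        layer: str = LAYER_METAGALACTIC,
                        qtl_nodes=None,
                        smooth_order: int = DEFAULT_SMOOTH_ORDER,
                        decomp_order: int = DEFAULT_DECOMP_ORDER,
                        n_dense: int = DEFAULT_N_DENSE,
                        selector: str = "lasso_pr2",
                        target: str = "derivative",
                        pr2_threshold: float = 0.7,
                        max_in_degree: int | None = None,
                        weight_floor: float = EDGE_WEIGHT_FLOOR,
                        fixed_support: dict | None = None,
                        seed: int = 0) -> EpistaticNetwork:
    """Run selection + decomposition + edge extraction with every node as
    focal, assembling one directed signed weighted network.

    ``node_curves`` maps node id -> effect curve at ``times`` (use
    independent-effect curves with ``variant='independent'``).
    ``fixed_support`` maps focal id -> regulator id list and bypasses
    selection for those nodes — e.g. to build the independent-effect
    network on the support selected from the overall curves instead of
    re-running selection.  Per-node failures are recorded, not fatal.
    """
    if len(node_curves) < 2:
        raise InvalidInputError("need at least 2 nodes")
    qtl_nodes = set(qtl_nodes or ())
    smoothed = {nid: smooth_and_interpolate(nid, vals, times,
                                            order=smooth_order,
                                            n_dense=n_dense)
                for nid, vals in node_curves.items()}
    G = nx.DiGraph()
    for nid in node_curves:
        G.add_node(nid, qtl=nid in qtl_nodes)
    decomps, failures = {}, []
    for nid, focal in smoothed.items():
        cands = [s for s in smoothed.values() if s.node_id != nid]
        try:
            if fixed_support is not None and nid in fixed_support:
                support = sorted(r for r in fixed_support[nid]
                                 if r in smoothed and r != nid)
                spec = RegressionSpec(nid, 0.0,
                                      {r: 1.0 for r in support}, support,
                                      np.zeros_like(focal.dense_values))
            else:
                spec = select_regulators(focal, cands, selector=selector,
                                         target=target,
                                         pr2_threshold=pr2_threshold,
                                         max_in_degree=max_in_degree,
                                         seed=seed)
            dec = fit_ode_decomposition(focal, spec, smoothed,
                                        order=decomp_order)
        except Exception as e:
            failures.append((nid, repr(e)))
            continue
        decomps[nid] = dec
        for e in edge_from_decomposition(dec, weight_floor=weight_floor):
            G.add_edge(e.source, e.target, sign=e.sign, weight=e.weight)
    return EpistaticNetwork(layer=layer, trait=trait, variant=variant,
                            graph=G, decompositions=decomps, failures=failures)


def degree_distribution(net: EpistaticNetwork):
    """Per-node outgoing/incoming link counts plus histogram tables."""
    import pandas as pd
    nodes = list(net.graph.nodes)
    out_deg = dict(net.graph.out_degree())
    in_deg = dict(net.graph.in_degree())
    per_node = pd.DataFrame({"node": nodes,
                             "out_degree": [out_deg[n] for n in nodes],
                             "in_degree": [in_deg[n] for n in nodes]})
    out_hist = per_node["out_degree"].value_counts().sort_index()
    in_hist = per_node["in_degree"].value_counts().sort_index()
    return per_node, out_hist, in_hist


def deconstruct_node_effect(dec: ODEDecomposition):
    """Tidy per-time report of one node's net effect curve, its independent
    component, and each incoming dependent component."""
    import pandas as pd
    data = {"time": dec.dense_times,
            "net": dec.net_curve,
            "independent": dec.independent_curve}
    for rid, curve in dec.dependent_curves.items():
        data[f"dependent_{rid}"] = curve
    return pd.DataFrame(data)


def positive_edge_fraction(net: EpistaticNetwork) -> float:
    """Fraction of links that are activations (positive epistasis)."""
    signs = [d["sign"] for _, _, d in net.graph.edges(data=True)]
    return float(np.mean([s > 0 for s in signs])) if signs else float("nan")
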