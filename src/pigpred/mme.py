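"""REML variance components and BLUP solving for all model families.

One engine covers the pedigree animal/repeatability models, GBLUP,
ssGBLUP and GFBLUP.  Variance components are estimated by AI-REML with
guaranteed-ascent EM-REML fallback steps; models with a single random
term besides the residual use an exact spectral (eigendecomposition)
path which profiles the variance ratio in one dimension.  BLUP
solutions come from Henderson's mixed-model equations when a term's
covariance inverse is available (pedigree A^-1, single-step H^-1
parts -- dense H is never formed), and from the equivalent
variance-space (GLS) form otherwise, which also handles rank-deficient
genomic covariances such as a small feature matrix G_f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp

from .core import DataError, GenotypePanel, NumericalError, RelationshipMatrix
from .relmat import HInverseParts, g_matrix

log = logging.getLogger(__name__)


class RemlNonConvergence(NumericalError):
    """REML hit the iteration cap; carries the log-likelihood trace."""

    def __init__(self, max_iter: int, trace: list[float]):
        self.trace = list(trace)
        super().__init__(f"REML did not converge in {max_iter} iterations; "
                         f"last log-likelihoods {trace[-3:]}")


# ---------------------------------------------------------------------------
# model specification


@dataclass
class RandomTerm:
    """One random effect: incidence Z, and a covariance K or its inverse.

    Exactly one of ``covariance`` (dense K over the term's levels) or
    ``inv_parts`` (single-step H^-1 parts) must be supplied; identity
    covariance is expressed by ``covariance=None`` with
    ``identity=True``.
    """

    label: str
    Z: np.ndarray
    level_ids: list
    covariance: np.ndarray | None = None
    inv_parts: HInverseParts | None = None
    identity: bool = False

    def K(self) -> np.ndarray:
        if self.identity:
            return np.eye(len(self.level_ids))
        if self.covariance is not None:
            return self.covariance
        # dense H from the assembled inverse; used for variance
        # estimation only (solving goes through the MME parts)
        return np.linalg.inv(self.inv_parts.assemble())

    def ZKZt(self) -> np.ndarray:
        if self.identity:
            return self.Z @ self.Z.T
        return self.Z @ self.K() @ self.Z.T


def incidence(record_levels, level_ids=None):
    """0/1 incidence matrix mapping records to term levels."""
    record_levels = list(record_levels)
    if level_ids is None:
        level_ids = sorted(set(record_levels))
    pos = {a: i for i, a in enumerate(level_ids)}
    Z = np.zeros((len(record_levels), len(level_ids)))
    for r, lev in enumerate(record_levels):
        Z[r, pos[lev]] = 1.0
    return Z, list(level_ids)


def genomic_term(label: str, record_ids, relationship: RelationshipMatrix) -> RandomTerm:
    Z, ids = incidence(record_ids, list(relationship.ids))
    return RandomTerm(label=label, Z=Z, level_ids=ids,
                      covariance=relationship.values)


def identity_term(label: str, record_levels, level_ids=None) -> RandomTerm:
    Z, ids = incidence(record_levels, level_ids)
    return RandomTerm(label=label, Z=Z, level_ids=ids, identity=True)


@dataclass
class ModelSpec:
    """Response, fixed design and random terms for one mixed model."""

    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise DataError("X rows must match response length")
        for t in self.terms:
            if t.Z.shape[0] != self.y.size:
                raise DataError(f"term {t.label!r}: Z rows must match response")


def intercept_model(y, terms) -> ModelSpec:
    y = np.asarray(y, dtype=float).ravel()
    return ModelSpec(y=y, X=np.ones((y.size, 1)), terms=terms)


@dataclass
class VarianceComponents:
    """REML estimates with the convergence trace."""

    sigma2: dict[str, float]  # per random-term label
    sigma2_e: float
    loglik: float
    trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    def ratio(self, label: str) -> float:
        """lambda = sigma2_e / sigma2_label (MME shrinkage)."""
        return self.sigma2_e / self.sigma2[label]

    def h2(self, label: str = "g") -> float:
        tot = sum(self.sigma2.values()) + self.sigma2_e
        return self.sigma2[label] / tot


@dataclass
class BlupSolution:
    """Fixed-effect estimates and random-effect predictions per term."""

    beta: np.ndarray
    u: dict[str, np.ndarray]
    level_ids: dict[str, list]
    pev: dict[str, np.ndarray] | None = None

    def series(self, label: str):
        import pandas as pd

        return pd.Series(self.u[label], index=self.level_ids[label])

    def total(self, labels) -> np.ndarray:
        """Sum predictions over terms sharing one level space (GFBLUP f+r)."""
        out = self.u[labels[0]].copy()
        for lab in labels[1:]:
            if self.level_ids[lab] != self.level_ids[labels[0]]:
                raise DataError("terms do not share a level space")
            out = out + self.u[lab]
        return out


# ---------------------------------------------------------------------------
# REML


def reml(model: ModelSpec, init: dict | None = None, max_iter: int = 200,
         ll_tol: float = 1e-8, par_tol: float = 1e-6,
         use_ai: bool = True) -> VarianceComponents:
    """REML estimates for the model's variance components.

    A single random term (plus residual) is handled by an exact
    spectral profile over the variance ratio; multi-term models run
    AI-REML, falling back to an EM step whenever the AI proposal leaves
    the parameter space or decreases the restricted likelihood (the EM
    step never does).  Variances are floored at ``1e-8 * var(y)``.
    """
    n, p = model.X.shape
    if n < p + 2:
        raise DataError("need at least p + 2 records for REML")
    if len(model.terms) == 1 and use_ai:
        return _reml_spectral(model)
    return _reml_ai(model, init, max_iter, ll_tol, par_tol, use_ai)


def _restricted_ll(y, X, V):
    n, p = X.shape
    c, low = sla.cho_factor(V, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi_y = sla.cho_solve((c, low), y)
    Vi_X = sla.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise NumericalError("X'V^-1X not positive definite (aliased fixed effects?)")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    yPy = float(y @ Py)
    ll = -0.5 * (logdet_v + logdet_x + yPy)
    return ll, Py, Vi_X, XtViX


def _reml_spectral(model: ModelSpec) -> VarianceComponents:
    """Exact one-dimensional REML for y = Xb + u + e, u ~ N(0, S sig_u^2).

    Eigendecomposes S = Z K Z' once, rotates the data, and profiles the
    restricted likelihood over the ratio lambda = sig_u^2 / sig_e^2.
    """
    term = model.terms[0]
    S = term.ZKZt()
    d, U = np.linalg.eigh(0.5 * (S + S.T))
    d = np.clip(d, 0.0, None)
    y = U.T @ model.y
    X = U.T @ model.X
    n, p = X.shape

    def neg_profile(log_lam: float) -> float:
        lam = 10.0 ** log_lam
        w = 1.0 / (lam * d + 1.0)
        XtWX = (X * w[:, None]).T @ X
        XtWy = (X * w[:, None]).T @ y
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        r = y - X @ beta
        rss = float(r @ (w * r))
        sig_e = rss / (n - p)
        ll = -0.5 * (np.sum(np.log(lam * d + 1.0)) + logdet_x
                     + (n - p) * np.log(sig_e) + (n - p))
        return -ll

    grid = np.linspace(-6.0, 6.0, 61)
    vals = [neg_profile(g) for g in grid]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = sopt.minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded",
                               options={"xatol": 1e-10})
    lam = 10.0 ** float(res.x)
    w = 1.0 / (lam * d + 1.0)
    XtWX = (X * w[:, None]).T @ X
    beta = np.linalg.solve(XtWX, (X * w[:, None]).T @ y)
    r = y - X @ beta
    sig_e = float(r @ (w * r)) / (n - p)
    sig_u = lam * sig_e
    ll = -float(res.fun) - 0.5 * (n - p) * np.log(2.0 * np.pi)
    floor = 1e-8 * float(np.var(model.y))
    return VarianceComponents(sigma2={term.label: max(sig_u, floor)},
                              sigma2_e=max(sig_e, floor),
                              loglik=ll, trace=[ll], iterations=int(res.nfev),
                              converged=True)


def _reml_ai(model, init, max_iter, ll_tol, par_tol, use_ai) -> VarianceComponents:
    y, X = model.y, model.X
    n, p = X.shape
    terms = model.terms
    S_list = [t.ZKZt() for t in terms]
    q_list = [len(t.level_ids) for t in terms]
    var_y = float(np.var(y))
    floor = 1e-8 * var_y

    k = len(terms)
    theta = np.empty(k + 1)
    if init:
        for i, t in enumerate(terms):
            theta[i] = init.get(t.label, var_y / (k + 1))
        theta[k] = init.get("residual", var_y / (k + 1))
    else:
        theta[:] = var_y / (k + 1)

    def build_V(th):
        V = th[k] * np.eye(n)
        for i in range(k):
            V += th[i] * S_list[i]
        return V

    ll, Py, _, _ = _restricted_ll(y, X, build_V(theta))
    trace = [ll]
    converged = False
    it = 0
    qs = np.array(q_list + [n], dtype=float)
    for it in range(1, max_iter + 1):
        V = build_V(theta)
        c, low = sla.cho_factor(V, lower=True)
        Vi = sla.cho_solve((c, low), np.eye(n))
        Vi_X = Vi @ X
        XtViX = X.T @ Vi_X
        P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
        Py = P @ y

        ySPy = np.empty(k + 1)
        trPS = np.empty(k + 1)
        T = np.empty((n, k + 1))
        for i in range(k):
            SPy = S_list[i] @ Py
            T[:, i] = SPy
            ySPy[i] = float(Py @ SPy)
            trPS[i] = float(np.sum(P * S_list[i]))
        T[:, k] = Py
        ySPy[k] = float(Py @ Py)
        trPS[k] = float(np.trace(P))
        score = -0.5 * (trPS - ySPy)

        # components pinned at the floor with a negative gradient are fixed
        # at the boundary; they re-enter if the gradient turns positive
        free = (theta > 10.0 * floor) | (score > 0.0)
        if not free.any():
            converged = True
            break

        stepped = False
        if use_ai:
            PT = P @ T
            AI = 0.5 * (T.T @ PT)
            try:
                delta = np.zeros(k + 1)
                delta[free] = np.linalg.solve(AI[np.ix_(free, free)],
                                              score[free])
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                # step-halve toward the current point; floor variances the
                # AI update pushes below zero instead of rejecting the step
                for frac in (1.0, 0.5, 0.25, 0.1):
                    prop = np.maximum(theta + frac * delta, floor)
                    try:
                        ll_new, *_ = _restricted_ll(y, X, build_V(prop))
                    except (np.linalg.LinAlgError, NumericalError):
                        continue
                    if ll_new >= ll - 1e-12:
                        theta_new, ll_next, stepped = prop, ll_new, True
                        break
        if not stepped:
            # EM-REML step: monotone in the restricted likelihood
            theta_new = theta.copy()
            upd = theta + theta ** 2 / qs * (ySPy - trPS)
            theta_new[free] = upd[free]
            theta_new = np.maximum(theta_new, floor)
            ll_next, *_ = _restricted_ll(y, X, build_V(theta_new))

        dll = ll_next - ll
        dpar = 0.0
        if free.any():
            dpar = float(np.max(np.abs(theta_new - theta)[free]
                                / np.maximum(np.abs(theta), floor)[free]))
        theta, ll = theta_new, ll_next
        trace.append(ll)
        grad_small = float(np.max(np.abs(score[free]))) < 1e-4 * (1.0 + abs(ll))
        if abs(dll) < ll_tol * (1.0 + abs(ll)) and (dpar < par_tol or grad_small):
            converged = True
            break
    if not converged and it >= max_iter:
        raise RemlNonConvergence(max_iter, trace)
    sigma2 = {t.label: float(theta[i]) for i, t in enumerate(terms)}
    return VarianceComponents(sigma2=sigma2, sigma2_e=float(theta[k]),
                              loglik=ll, trace=trace, iterations=it,
                              converged=converged)


# ---------------------------------------------------------------------------
# BLUP solving


def solve_blup(model: ModelSpec, vc: VarianceComponents,
               compute_pev: bool = False) -> BlupSolution:
    """Best linear unbiased predictions given variance components.

    Uses Henderson's MME when every term carries an invertible (or
    inverse-form) covariance -- the single-step term plugs its H^-1
    parts straight into the equations without forming dense H -- and
    the equivalent GLS/variance-space computation otherwise (needed for
    rank-deficient dense covariances such as a feature G_f).
    """
    for t in model.terms:
        if vc.sigma2.get(t.label, 0.0) <= 0.0:
            raise DataError(f"variance for term {t.label!r} must be positive")
    if any(t.inv_parts is not None for t in model.terms):
        return _blup_mme(model, vc, compute_pev)
    return _blup_gls(model, vc, compute_pev)


def _blup_gls(model, vc, compute_pev) -> BlupSolution:
    y, X = model.y, model.X
    n = y.size
    V = vc.sigma2_e * np.eye(n)
    for t in model.terms:
        V += vc.sigma2[t.label] * t.ZKZt()
    c, low = sla.cho_factor(V, lower=True)
    Vi_y = sla.cho_solve((c, low), y)
    Vi_X = sla.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular fixed-effect equations (aliased levels)") from exc
    Py = Vi_y - Vi_X @ np.linalg.solve(XtViX, X.T @ Vi_y)
    u, ids, pev = {}, {}, {}
    if compute_pev:
        Vi = sla.cho_solve((c, low), np.eye(n))
        P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
    for t in model.terms:
        s2 = vc.sigma2[t.label]
        KZt = t.Z.T if t.identity else t.K() @ t.Z.T
        u[t.label] = s2 * (KZt @ Py)
        ids[t.label] = list(t.level_ids)
        if compute_pev:
            ZK = KZt.T
            K = np.eye(len(t.level_ids)) if t.identity else t.K()
            pev[t.label] = np.diag(s2 * K - s2 ** 2 * (KZt @ P @ ZK))
    return BlupSolution(beta=beta, u=u, level_ids=ids,
                        pev=pev if compute_pev else None)


def _blup_mme(model, vc, compute_pev) -> BlupSolution:
    y, X = model.y, model.X
    n, p = X.shape
    blocks_Z = []
    kinvs = []
    for t in model.terms:
        blocks_Z.append(t.Z)
        lam = vc.sigma2_e / vc.sigma2[t.label]
        if t.inv_parts is not None:
            kinvs.append(lam * t.inv_parts.assemble())
        elif t.identity:
            kinvs.append(lam * np.eye(len(t.level_ids)))
        else:
            try:
                kinvs.append(lam * np.linalg.inv(t.covariance))
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    f"covariance of term {t.label!r} is singular; "
                    "use the GLS path or blend the matrix") from exc
    Zfull = np.hstack(blocks_Z)
    W = np.hstack([X, Zfull])
    C = W.T @ W
    off = p
    for t, Ki in zip(model.terms, kinvs):
        q = len(t.level_ids)
        C[off:off + q, off:off + q] += Ki
        off += q
    rhs = W.T @ y
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular mixed-model equations (aliased effects)") from exc
    beta = sol[:p]
    u, ids, pev = {}, {}, {}
    if compute_pev:
        Cinv = np.linalg.inv(C)
    off = p
    for t in model.terms:
        q = len(t.level_ids)
        u[t.label] = sol[off:off + q]
        ids[t.label] = list(t.level_ids)
        if compute_pev:
            pev[t.label] = vc.sigma2_e * np.diag(Cinv)[off:off + q]
        off += q
    return BlupSolution(beta=beta, u=u, level_ids=ids,
                        pev=pev if compute_pev else None)


# ---------------------------------------------------------------------------
# GFBLUP


def fit_gfblup(y_c: np.ndarray, record_ids, feature_markers, panel: GenotypePanel,
               X: np.ndarray | None = None, vc: VarianceComponents | None = None):
    """Genomic-feature BLUP with feature (f) and remainder (r) effects.

    ``G_f`` and ``G_r`` are built exactly like G but from the feature
    marker set and its complement.  If the feature covers every marker
    the model degenerates to GBLUP (sigma2_r fixed at zero by removing
    the term); an empty feature set is an error directing the caller to
    GBLUP.  Returns ``(solution, vc, ids)`` where the total genomic
    prediction is ``solution.total(["f", "r"])``.
    """
    y_c = np.asarray(y_c, dtype=float).ravel()
    feature = [m for m in panel.marker_ids if m in set(feature_markers)]
    if not feature:
        raise DataError("empty feature set: fit GBLUP instead")
    rest = [m for m in panel.marker_ids if m not in set(feature)]
    X = X if X is not None else np.ones((y_c.size, 1))
    if not rest:
        G = g_matrix(panel, label_kind="G")
        term = genomic_term("f", record_ids, G)
        model = ModelSpec(y=y_c, X=X, terms=[term])
        vc = vc or reml(model)
        sol = solve_blup(model, vc)
        sol.u["r"] = np.zeros_like(sol.u["f"])
        sol.level_ids["r"] = list(sol.level_ids["f"])
        vc.sigma2.setdefault("r", 0.0)
        return sol, vc, list(G.ids)
    Gf = g_matrix(panel.subset_markers(feature), label_kind="G")
    Gr = g_matrix(panel.subset_markers(rest), label_kind="G")
    tf = genomic_term("f", record_ids, Gf)
    tr = genomic_term("r", record_ids, Gr)
    model = ModelSpec(y=y_c, X=X, terms=[tf, tr])
    vc = vc or reml(model)
    sol = solve_blup(model, vc)
    return sol, vc, list(Gf.ids)
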