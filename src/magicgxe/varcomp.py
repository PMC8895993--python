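"""REML variance partitioning of multi-environment plot data.

The plot-level model for one trait is

    y = 1 mu + Z_G u_G + Z_E u_E + Z_{E:G} u_{E:G} + f_E(x, y) + e,

with independent random effects within each factor (identity covariance;
kinship is deliberately not used here), a tensor-product spline field
surface nested within environment sharing a single variance, and i.i.d.
residuals.  Variance components are estimated by average-information REML
with an EM fallback and step halving, working throughout in the
mixed-model-equations parameterization so each iteration costs one
factorization of a (small) absorbed coefficient matrix: the largest
random-effect block with a diagonal Gram matrix (normally the line-by-
environment block) is absorbed analytically.

Identities used (W = [X Z], C = W'W + diag(0, lambda_i I), lambda_i =
s2_e / s2_i):

    s2_e * P           = I - W C^{-1} W'
    log|V| + log|X'V^{-1}X| = (n - p - q) log s2_e + sum_i q_i log s2_i + log|C|
    tr(P Z_i Z_i')     = (q_i - lambda_i tr(C^{-1}_ii)) / s2_i
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .splines import environment_spline_block

log = logging.getLogger(__name__)

__all__ = [
    "Design",
    "VarianceComponents",
    "build_design",
    "fit_reml",
    "variance_proportions",
]


@dataclass
class Design:
    """Model matrices for one trait: fixed effects and named random terms."""

    y: np.ndarray
    X: np.ndarray  # fixed effects (intercept, or environment dummies)
    random: dict  # name -> scipy.sparse or dense (n, q_i) incidence matrix
    n_dropped: int = 0
    dropped_columns: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass
class VarianceComponents:
    estimates: dict  # term -> variance (residual under key "residual")
    std_errors: dict
    loglik: float
    converged: bool
    n_iter: int
    meta: dict = field(default_factory=dict)

    def proportions(self, include: list | None = None) -> dict:
        return variance_proportions(self, include=include)


def _incidence(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def build_design(
    table: pd.DataFrame,
    trait: str,
    knots: tuple[int, int] = (6, 6),
    spline: bool = True,
    env_fixed: bool = False,
) -> Design:
    """Build response and model matrices from a plot-level phenotype table.

    Rows with a missing trait value are dropped (counted).  The
    line-by-environment incidence is the Khatri-Rao expansion restricted to
    observed combinations: a line absent from an environment contributes no
    column (logged).  With ``env_fixed`` the environment enters the fixed
    part as dummies instead of a random term.
    """
    if trait not in table.columns:
        raise ValueError(f"trait {trait!r} not in table")
    t = table.dropna(subset=[trait]).reset_index(drop=True)
    n_dropped = len(table) - len(t)
    if n_dropped:
        log.info("build_design: dropped %d rows with missing %s", n_dropped, trait)
    envs = pd.unique(t["environment"])
    lines = pd.unique(t["line"])
    if len(envs) < 2:
        raise ValueError("need at least 2 environments")
    if len(lines) < 2:
        raise ValueError("need at least 2 lines")

    line_code = pd.Categorical(t["line"], categories=lines).codes
    env_code = pd.Categorical(t["environment"], categories=envs).codes
    Z_G = _incidence(line_code, len(lines))
    Z_E = _incidence(env_code, len(envs))

    combo = env_code.astype(np.int64) * len(lines) + line_code
    observed = np.unique(combo)
    full = len(envs) * len(lines)
    dropped_cols = full - len(observed)
    if dropped_cols:
        log.info("build_design: %d absent line-environment combinations dropped from Z_EG", dropped_cols)
    combo_code = np.searchsorted(observed, combo)
    Z_EG = _incidence(combo_code, len(observed))

    y = t[trait].to_numpy(dtype=float)
    if env_fixed:
        X = Z_E.toarray()
        random = {"G": Z_G, "GxE": Z_EG}
    else:
        X = np.ones((len(t), 1))
        random = {"G": Z_G, "E": Z_E, "GxE": Z_EG}
    if spline:
        B = environment_spline_block(
            t["environment"].to_numpy(), t["x"].to_numpy(), t["y"].to_numpy(), knots
        )
        random["spline"] = B
    return Design(
        y=y,
        X=X,
        random=random,
        n_dropped=n_dropped,
        dropped_columns={"GxE": dropped_cols},
        meta={"environments": list(envs), "lines": list(lines), "table_index": t.index},
    )


# ---------------------------------------------------------------------------
# REML engine


class _Absorbed:
    """Precomputed cross-products with one diagonal-Gram block absorbed."""

    def __init__(self, X, random: dict):
        names = list(random)
        # absorb the largest random block whose Gram matrix is diagonal
        absorb = None
        best = -1
        for name in names:
            Z = random[name]
            g = (Z.T @ Z) if sp.issparse(Z) else Z.T @ Z
            g = g.toarray() if sp.issparse(g) else np.atleast_2d(g)
            if np.allclose(g, np.diag(np.diag(g))) and Z.shape[1] > best:
                absorb, best = name, Z.shape[1]
        self.absorb = absorb
        self.dense_names = [n for n in names if n != absorb]
        mats = [np.asarray(X, dtype=float)] + [
            (random[n].toarray() if sp.issparse(random[n]) else np.asarray(random[n], float))
            for n in self.dense_names
        ]
        self.W1 = np.hstack(mats)
        self.p_fix = X.shape[1]
        self.slices = {}
        col = X.shape[1]
        for n in self.dense_names:
            q = random[n].shape[1]
            self.slices[n] = slice(col, col + q)
            col += q
        self.p1 = col
        self.A11 = self.W1.T @ self.W1
        if absorb is not None:
            Z2 = random[absorb]
            Z2d = Z2.toarray() if sp.issparse(Z2) else np.asarray(Z2, float)
            self.Z2 = sp.csr_matrix(Z2d)
            self.d2 = np.asarray((self.Z2.multiply(self.Z2)).sum(axis=0)).ravel()
            self.A12 = self.W1.T @ Z2d
            self.q2 = Z2d.shape[1]
        else:
            self.Z2 = None
            self.q2 = 0

    def prepare_y(self, y):
        self.y = np.asarray(y, dtype=float)
        self.a1y = self.W1.T @ self.y
        self.a2y = self.Z2.T @ self.y if self.Z2 is not None else None
        self.yy = float(self.y @ self.y)
        self.n = len(self.y)


class _State:
    """One evaluation of the absorbed mixed-model equations."""

    def __init__(self, ab: _Absorbed, variances: dict, ve: float):
        self.ab = ab
        self.v = variances
        self.ve = ve
        lam = {n: ve / variances[n] for n in variances}
        S = ab.A11.copy()
        for n, sl in ab.slices.items():
            S[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += lam[n]
        if ab.Z2 is not None:
            self.D2 = ab.d2 + lam[ab.absorb]
            S -= (ab.A12 / self.D2) @ ab.A12.T
            rhs = ab.a1y - ab.A12 @ (ab.a2y / self.D2)
        else:
            self.D2 = None
            rhs = ab.a1y
        self.lam = lam
        self.L = sla.cholesky(S, lower=True)
        self.theta1 = sla.cho_solve((self.L, True), rhs)
        if ab.Z2 is not None:
            self.u2 = (ab.a2y - ab.A12.T @ self.theta1) / self.D2
        else:
            self.u2 = None
        quad = ab.yy - ab.a1y @ self.theta1
        if self.u2 is not None:
            quad -= ab.a2y @ self.u2
        self.quad = float(quad)  # y' (y - W theta) = ve * y'Py
        self.logdetC = 2.0 * np.log(np.diag(self.L)).sum() + (
            np.log(self.D2).sum() if self.D2 is not None else 0.0
        )

    def loglik(self) -> float:
        ab = self.ab
        q_tot = sum(z.stop - z.start for z in ab.slices.values()) + ab.q2
        ll = -0.5 * (
            (ab.n - ab.p_fix - q_tot) * np.log(self.ve)
            + sum((ab.slices[n].stop - ab.slices[n].start) * np.log(self.v[n]) for n in ab.dense_names)
            + (ab.q2 * np.log(self.v[ab.absorb]) if ab.absorb else 0.0)
            + self.logdetC
            + self.quad / self.ve
        )
        return float(ll)

    def block_traces(self) -> dict:
        """tr(C^{-1}_ii) for every random block."""
        ab = self.ab
        Sinv = sla.cho_solve((self.L, True), np.eye(ab.p1))
        tr = {n: np.trace(Sinv[sl, sl]) for n, sl in ab.slices.items()}
        if ab.Z2 is not None:
            T = sla.solve_triangular(self.L, ab.A12, lower=True)
            tr[ab.absorb] = float(np.sum(1.0 / self.D2) + np.sum((T / self.D2) ** 2))
        return tr

    def u_block(self, name) -> np.ndarray:
        if name == self.ab.absorb:
            return self.u2
        return self.theta1[self.ab.slices[name]]

    def residual(self) -> np.ndarray:
        ab = self.ab
        r = self.y_minus_fit()
        return r

    def y_minus_fit(self) -> np.ndarray:
        ab = self.ab
        r = ab.y - ab.W1 @ self.theta1
        if self.u2 is not None:
            r = r - ab.Z2 @ self.u2
        return r

    def solve_mme(self, f: np.ndarray) -> np.ndarray:
        """Return W C^{-1} W' f for an arbitrary n-vector f."""
        ab = self.ab
        a1 = ab.W1.T @ f
        if ab.Z2 is not None:
            a2 = ab.Z2.T @ f
            rhs = a1 - ab.A12 @ (a2 / self.D2)
            th = sla.cho_solve((self.L, True), rhs)
            u = (a2 - ab.A12.T @ th) / self.D2
            return ab.W1 @ th + ab.Z2 @ u
        th = sla.cho_solve((self.L, True), a1)
        return ab.W1 @ th


def fit_reml(
    design: Design,
    max_iter: int = 200,
    tol: float = 1e-8,
    verbose: bool = False,
) -> VarianceComponents:
    """Average-information REML with EM fallback and step halving.

    The restricted likelihood is non-decreasing across accepted steps;
    components hitting the lower boundary are clamped at a small floor and
    reported as 0.  Non-convergence within ``max_iter`` returns the last
    iterate with ``converged=False``.
    """
    names = list(design.random)
    ab = _Absorbed(design.X, design.random)
    ab.prepare_y(design.y)
    n, p = ab.n, ab.p_fix
    q_tot = sum(design.random[n_].shape[1] for n_ in names)
    if n - p - 0 < 5:
        raise ValueError("need at least 5 residual degrees of freedom")

    vy = float(np.var(design.y)) or 1.0
    floor = 1e-8 * vy
    k = len(names)
    v = {n_: vy / (k + 1) for n_ in names}
    ve = vy / (k + 1)
    st = _State(ab, v, ve)
    ll = st.loglik()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = {n_: design.random[n_].shape[1] for n_ in names}
        tr = st.block_traces()
        rtilde = st.y_minus_fit() / st.ve  # = P y
        # scores
        score = np.empty(k + 1)
        for i, n_ in enumerate(names):
            Z = design.random[n_]
            ztr = Z.T @ rtilde
            ztr = np.asarray(ztr).ravel()
            trPZZ = (q[n_] - st.lam[n_] * tr[n_]) / st.v[n_]
            score[i] = -0.5 * (trPZZ - ztr @ ztr)
        lam_tr = sum(st.lam[n_] * tr[n_] for n_ in names)
        trP = (n - ab.p1 - ab.q2 + lam_tr) / st.ve
        score[k] = -0.5 * (trP - rtilde @ rtilde)
        # average information
        fs = []
        for n_ in names:
            Z = design.random[n_]
            fs.append(np.asarray(Z @ (Z.T @ rtilde)).ravel())
        fs.append(rtilde)
        Pf = [(f - st.solve_mme(f)) / st.ve for f in fs]
        AI = 0.5 * np.array([[fi @ Pfj for Pfj in Pf] for fi in fs])

        theta = np.array([st.v[n_] for n_ in names] + [st.ve])
        try:
            delta = np.linalg.solve(AI + 1e-12 * np.eye(k + 1), score)
        except np.linalg.LinAlgError:
            delta = score * theta**2 * 2 / np.r_[[q[n_] for n_ in names], n]

        accepted = False
        alpha = 1.0
        for _ in range(12):
            cand = np.maximum(theta + alpha * delta, floor)
            v_new = {n_: cand[i] for i, n_ in enumerate(names)}
            try:
                st_new = _State(ab, v_new, cand[-1])
                ll_new = st_new.loglik()
            except np.linalg.LinAlgError:
                alpha /= 2
                continue
            if ll_new >= ll - 1e-12:
                accepted = True
                break
            alpha /= 2
        if not accepted:
            # EM fallback (guaranteed ascent)
            v_new = {}
            for n_ in names:
                u = st.u_block(n_)
                v_new[n_] = max((u @ u + st.ve * tr[n_]) / q[n_], floor)
            ve_new = st.quad / (n - p)
            st_new = _State(ab, v_new, max(ve_new, floor))
            ll_new = st_new.loglik()
        if verbose:
            log.info("REML iter %d: ll=%.6f", it, ll_new)
        dll = ll_new - ll
        st, ll = st_new, ll_new
        if abs(dll) / (abs(ll) + 1.0) < tol:
            converged = True
            break

    # standard errors from the inverse AI matrix at the optimum
    try:
        cov = np.linalg.pinv(AI)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except Exception:  # pragma: no cover
        ses = np.full(k + 1, np.nan)

    # boundary clamp: components negligible relative to the total are
    # reported as exactly 0 (the optimum sits on the boundary to within
    # the optimizer's resolution)
    total = sum(st.v[n_] for n_ in names) + st.ve
    estimates = {n_: (0.0 if st.v[n_] <= max(floor * 1.01, 1e-3 * total) else float(st.v[n_])) for n_ in names}
    estimates["residual"] = float(st.ve)
    std_errors = {n_: float(ses[i]) for i, n_ in enumerate(names)}
    std_errors["residual"] = float(ses[-1])
    if not converged:
        log.warning("fit_reml: no convergence in %d iterations", max_iter)
    return VarianceComponents(
        estimates=estimates,
        std_errors=std_errors,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        meta={"n": n, "n_dropped": design.n_dropped},
    )


_ABSORB_CACHE: dict = {}


def reml_loglik(design: Design, variances: dict, residual: float) -> float:
    """Restricted log-likelihood at given component values (up to a constant).

    Exposed for grid searches and optimality spot checks; the absorbed
    cross-products are cached per Design instance so dense grids only pay
    for one factorization per evaluation.
    """
    key = id(design)
    if _ABSORB_CACHE.get("key") != key:
        ab = _Absorbed(design.X, design.random)
        ab.prepare_y(design.y)
        _ABSORB_CACHE["key"] = key
        _ABSORB_CACHE["ab"] = ab
    return _State(_ABSORB_CACHE["ab"], variances, residual).loglik()


def variance_proportions(vc: VarianceComponents, include: list | None = None) -> dict:
    """Each included component divided by the included total.

    By default the spline component is excluded from the denominator and
    all other components (including environment and residual) are included;
    the choice is recorded in the result under ``"_included"``.
    """
    if include is None:
        include = [k for k in vc.estimates if k != "spline"]
    total = sum(vc.estimates[k] for k in include)
    if total <= 0:
        raise ZeroDivisionError("all included variance components are zero")
    out = {k: vc.estimates[k] / total for k in include}
    out["_included"] = list(include)
    return out
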