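"""Bayesian per-environment G-matrix estimation.

Within one environment the t-trait plot observations follow

    Y = Z U + f(x, y) + E,

with line effects vec(U) ~ N(0, G (x) I_r), residuals vec(E) ~ N(0,
R (x) I_n), and a tensor-product spline field surface per trait sharing a
single variance.  G and R are the genetic and residual variance-covariance
matrices of the (mean-scaled) traits.

The sampler is a conditionally conjugate Gibbs sampler.  G and R carry a
parameter-expanded hierarchical inverse-Wishart prior (inverse-Wishart
conditional on per-trait auxiliary scales, the scales inverse-gamma) whose
implied marginal on each standard deviation is half-t(nu, A_k) — a fully
specified approximation to a separation-strategy prior with half-t
standard deviations; the correlation margins differ from an
LKJ(1)-uniform prior only weakly (see the methods note).  The spline
variance also carries a half-t prior via the same expansion.

Traits are mean-scaled (divided by their grand mean across all
environments, then centered) before analysis, which makes them unitless;
genetic variances on this scale are mean-scaled evolvabilities, not
heritabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .splines import tensor_basis

log = logging.getLogger(__name__)

__all__ = [
    "ScaledTraits",
    "GMatrixPosterior",
    "CorrelationDifference",
    "mean_scale",
    "fit_gmatrix",
    "diagnostics",
    "correlation_difference",
    "collinearity_check",
]


@dataclass
class ScaledTraits:
    """Mean-scaled, centered trait table plus the record to invert it."""

    table: pd.DataFrame
    traits: list
    grand_means: dict  # trait -> grand mean across all environments
    centers: dict  # trait -> mean of the scaled ratio removed by centering

    def inverse(self) -> pd.DataFrame:
        out = self.table.copy()
        for tr in self.traits:
            out[tr] = (out[tr] + self.centers[tr]) * self.grand_means[tr]
        return out


def mean_scale(table: pd.DataFrame, traits: list, center: str = "global") -> ScaledTraits:
    """Scale each trait by its grand mean across all environments, then center.

    ``center="global"`` removes one overall mean per trait (default);
    ``center="environment"`` removes per-environment means instead.
    """
    out = table.copy()
    gm, centers = {}, {}
    for tr in traits:
        m = float(table[tr].mean())
        if abs(m) < 1e-12:
            raise ValueError(f"trait {tr!r} has zero grand mean; cannot mean-scale")
        ratio = table[tr] / m
        if center == "global":
            c = float(ratio.mean())
            out[tr] = ratio - c
        elif center == "environment":
            c = ratio.groupby(table["environment"]).transform("mean")
            out[tr] = ratio - c
            c = float(np.nan)
        else:
            raise ValueError("center must be 'global' or 'environment'")
        gm[tr], centers[tr] = m, c
    return ScaledTraits(table=out, traits=list(traits), grand_means=gm, centers=centers)


@dataclass
class GMatrixPosterior:
    """Pooled post-burn-in MCMC draws of (G, R, spline variance)."""

    G: np.ndarray  # (n_draws, t, t)
    R: np.ndarray  # (n_draws, t, t)
    spline_var: np.ndarray  # (n_draws,)
    chain: np.ndarray  # (n_draws,) chain label
    traits: list
    environment: object = None
    n_rejected: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.G.shape[0]

    def median_G(self) -> np.ndarray:
        return np.median(self.G, axis=0)

    def median_R(self) -> np.ndarray:
        return np.median(self.R, axis=0)

    def correlations(self) -> np.ndarray:
        """Genetic correlations per draw, shape (n_draws, t, t)."""
        sd = np.sqrt(np.einsum("dii->di", self.G))
        return self.G / (sd[:, :, None] * sd[:, None, :])


@dataclass
class CorrelationDifference:
    trait_pair: tuple
    environments: tuple
    differences: np.ndarray  # per matched draw, r_A - r_B
    interval: tuple  # (2.5%, 97.5%)
    significant: bool
    cov_sign_agreement: tuple  # fraction of draws with positive covariance in A, B


def collinearity_check(table: pd.DataFrame, traits: list, warn_above: float = 1e3) -> float:
    """Condition number of the phenotypic correlation matrix of the traits.

    A very large condition number signals (near-)collinear traits — e.g. a
    trait defined as a function of two others — which destabilizes the
    multivariate model; such traits should be dropped before fitting.
    """
    C = table[traits].dropna().corr().to_numpy()
    cond = float(np.linalg.cond(C))
    if cond > warn_above:
        warnings.warn(
            f"phenotypic correlation matrix is near-singular (condition number {cond:.3g}); "
            "consider dropping a derived or redundant trait",
            stacklevel=2,
        )
    return cond


# ---------------------------------------------------------------------------
# Gibbs sampler


def _hw_prior_draw(rng, t, nu, A):
    """One draw of (G, a) from the hierarchical inverse-Wishart prior."""
    a = 1.0 / rng.gamma(0.5, 1.0 / (1.0 / A**2))
    scale = 2.0 * nu * np.diag(1.0 / a)
    G = stats.invwishart.rvs(df=nu + t - 1, scale=scale, random_state=rng)
    return np.atleast_2d(G), a


def _sample_cov(rng, t, nu, a, df_data, S_data):
    """Inverse-Wishart conditional for a covariance under the expanded prior."""
    df = nu + t - 1 + df_data
    scale = 2.0 * nu * np.diag(1.0 / a) + S_data
    scale = (scale + scale.T) / 2
    return np.atleast_2d(stats.invwishart.rvs(df=df, scale=scale, random_state=rng))


def _sample_aux(rng, t, nu, A, Sigma_inv):
    """Auxiliary scales a_k | Sigma ~ IG((nu+t)/2, nu*(Sigma^-1)_kk + A_k^-2)."""
    shape = 0.5 * (nu + t)
    rate = nu * np.diag(Sigma_inv) + 1.0 / A**2
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def fit_gmatrix(
    scaled: ScaledTraits | pd.DataFrame,
    environment=None,
    traits: list | None = None,
    chains: int = 4,
    burnin: int = 1500,
    draws: int = 3500,
    seed: int = 0,
    knots: tuple[int, int] = (5, 5),
    spline: bool = True,
    nu: float = 3.0,
    prior_scale: np.ndarray | None = None,
    keep_line_effects: bool = False,
) -> GMatrixPosterior:
    """Gibbs sampler for the multivariate line-effects model in one environment.

    ``scaled`` is a mean-scaled phenotype table (or any plot-level table);
    rows with any missing trait value are dropped (complete case, logged).
    Prior scales A_k default to the observed phenotypic standard deviation
    per trait.  Draws from all chains are pooled post burn-in with chain
    labels retained for convergence diagnostics.  Draws failing a Cholesky
    check (numerically non-PSD) are resampled and counted.
    """
    table = scaled.table if isinstance(scaled, ScaledTraits) else scaled
    if traits is None:
        traits = scaled.traits if isinstance(scaled, ScaledTraits) else None
    if traits is None:
        raise ValueError("traits must be given")
    t = len(traits)
    if t < 2:
        raise ValueError("need at least 2 traits for a G-matrix")
    if environment is not None:
        table = table[table["environment"] == environment]
    complete = table.dropna(subset=list(traits))
    n_drop = len(table) - len(complete)
    if n_drop:
        log.info("fit_gmatrix: dropped %d incomplete rows (complete-case)", n_drop)
    table = complete.reset_index(drop=True)

    n = len(table)
    if n:
        lines = pd.unique(table["line"])
        code = pd.Categorical(table["line"], categories=lines).codes
        r = len(lines)
        Y = table[list(traits)].to_numpy(dtype=float)
        if spline and n > 0:
            B = tensor_basis(table["x"].to_numpy(), table["y"].to_numpy(), knots)
        else:
            B = np.zeros((n, 0))
    else:
        r, code, Y, B = 0, np.zeros(0, dtype=int), np.zeros((0, t)), np.zeros((0, 0))
    q = B.shape[1]

    if prior_scale is None:
        A = Y.std(axis=0) if n else np.ones(t)
        A = np.where(A > 1e-12, A, 1.0)
    else:
        A = np.asarray(prior_scale, dtype=float)
    A_spline = float(np.mean(A))
    nu_s = nu

    counts = np.bincount(code, minlength=r).astype(float) if r else np.zeros(0)
    BtB = B.T @ B if q else np.zeros((0, 0))

    all_G, all_R, all_sv, all_chain = [], [], [], []
    all_U = [] if keep_line_effects else None
    n_rejected = 0

    for chain_id in range(chains):
        rng = substream(seed, "gmatrix", chain_id)
        # init
        if n:
            vinit = np.maximum(Y.var(axis=0), 1e-8)
            G = np.diag(vinit / 2)
            R = np.diag(vinit / 2)
        else:
            G, _ = _hw_prior_draw(rng, t, nu, A)
            R, _ = _hw_prior_draw(rng, t, nu, A)
        aG = np.full(t, 1.0)
        aR = np.full(t, 1.0)
        U = np.zeros((r, t))
        C = np.zeros((q, t))
        sv = 1.0
        a_sv = 1.0

        for it in range(burnin + draws):
            if n:
                Rinv = np.linalg.inv(R)
                Ginv = np.linalg.inv(G)
                # line effects: conjugate MVN per line, grouped by replicate count
                resid_wo_U = Y - B @ C
                sums = np.zeros((r, t))
                np.add.at(sums, code, resid_wo_U)
                for m_count in np.unique(counts):
                    sel = counts == m_count
                    prec = Ginv + m_count * Rinv
                    cov = np.linalg.inv(prec)
                    cp = np.linalg.cholesky(cov)
                    mean = sums[sel] @ Rinv @ cov  # rows: (cov Rinv s_l)'
                    U[sel] = mean + rng.standard_normal((int(sel.sum()), t)) @ cp.T
                # spline coefficients: joint MVN over q*t
                if q:
                    resid_wo_C = Y - U[code]
                    Prec = np.kron(Rinv, BtB) + np.eye(q * t) / sv
                    rhs = (B.T @ resid_wo_C @ Rinv).T.ravel()  # vec by trait-major
                    Lp = np.linalg.cholesky(Prec)
                    mean = np.linalg.solve(Lp.T, np.linalg.solve(Lp, rhs))
                    draw = mean + np.linalg.solve(Lp.T, rng.standard_normal(q * t))
                    C = draw.reshape(t, q).T
                    ssc = float(np.sum(C**2))
                    sv = 1.0 / rng.gamma(0.5 * (nu_s + q * t), 1.0 / (nu_s / a_sv + 0.5 * ssc))
                else:
                    sv = 1.0 / rng.gamma(0.5 * nu_s, 1.0 / (nu_s / a_sv))
                a_sv = 1.0 / rng.gamma(0.5 * (nu_s + 1), 1.0 / (nu_s / sv + 1.0 / A_spline**2))
                # covariances
                for _try in range(10):
                    Gc = _sample_cov(rng, t, nu, aG, r, U.T @ U)
                    try:
                        np.linalg.cholesky(Gc)
                        break
                    except np.linalg.LinAlgError:
                        n_rejected += 1
                G = Gc
                E = Y - U[code] - (B @ C if q else 0.0)
                for _try in range(10):
                    Rc = _sample_cov(rng, t, nu, aR, n, E.T @ E)
                    try:
                        np.linalg.cholesky(Rc)
                        break
                    except np.linalg.LinAlgError:
                        n_rejected += 1
                R = Rc
            else:
                # prior-predictive mode: Gibbs over (G, a), (R, a), spline scale
                G = _sample_cov(rng, t, nu, aG, 0, np.zeros((t, t)))
                R = _sample_cov(rng, t, nu, aR, 0, np.zeros((t, t)))
                sv = 1.0 / rng.gamma(0.5 * nu_s, 1.0 / (nu_s / a_sv))
                a_sv = 1.0 / rng.gamma(0.5 * (nu_s + 1), 1.0 / (nu_s / sv + 1.0 / A_spline**2))
            aG = _sample_aux(rng, t, nu, A, np.linalg.inv(G))
            aR = _sample_aux(rng, t, nu, A, np.linalg.inv(R))

            if it >= burnin:
                all_G.append(G.copy())
                all_R.append(R.copy())
                all_sv.append(sv)
                all_chain.append(chain_id)
                if keep_line_effects:
                    all_U.append(U.copy())

    post = GMatrixPosterior(
        G=np.array(all_G),
        R=np.array(all_R),
        spline_var=np.array(all_sv),
        chain=np.array(all_chain),
        traits=list(traits),
        environment=environment,
        n_rejected=n_rejected,
        meta={
            "n_obs": n,
            "n_lines": r,
            "chains": chains,
            "burnin": burnin,
            "draws": draws,
            "nu": nu,
            "prior_scale": A.tolist(),
            "dropped_rows": n_drop,
        },
    )
    if keep_line_effects:
        post.meta["U_draws"] = np.array(all_U)
    if n_rejected:
        log.info("fit_gmatrix: %d non-PSD draws resampled", n_rejected)
    return post


# ---------------------------------------------------------------------------
# diagnostics and comparisons


def diagnostics(post: GMatrixPosterior) -> pd.DataFrame:
    """Split-chain rank-normalized Rhat and bulk ESS per SD/correlation parameter.

    Uses the rank-normalized split-Rhat and bulk effective sample size of
    Vehtari et al. as implemented in ArviZ.  With a single chain Rhat is
    undefined (NaN, with a warning); ESS is still computed.  Parameters
    with Rhat > 1.01 trigger a warning.
    """
    import arviz as az

    t = len(post.traits)
    chains = np.unique(post.chain)
    per_chain = min(np.sum(post.chain == c) for c in chains)
    params = {}
    sds = np.sqrt(np.einsum("dii->di", post.G))
    cors = post.correlations()
    for i, tr in enumerate(post.traits):
        params[f"sd_{tr}"] = sds[:, i]
    for i in range(t):
        for j in range(i + 1, t):
            params[f"cor_{post.traits[i]}_{post.traits[j]}"] = cors[:, i, j]
    params["sd_spline"] = np.sqrt(post.spline_var)

    stacked = {
        k: np.stack([v[post.chain == c][:per_chain] for c in chains]) for k, v in params.items()
    }
    idata = az.from_dict(posterior=stacked)
    rows = []
    single = len(chains) < 2
    if single:
        warnings.warn("single chain: split-Rhat undefined; reporting NaN", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata) if not single else None
        ess = az.ess(idata, method="bulk")
    for k in params:
        r_ = float(rhat[k].values) if rhat is not None else np.nan
        e_ = float(ess[k].values)
        rows.append((k, r_, e_))
    out = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk"])
    bad = out[out["rhat"] > 1.01]
    if len(bad):
        warnings.warn(
            f"{len(bad)} parameters with split-Rhat > 1.01: {', '.join(bad['parameter'])}",
            stacklevel=2,
        )
    return out


def correlation_difference(
    postA: GMatrixPosterior,
    postB: GMatrixPosterior,
    trait_i,
    trait_j,
    seed: int = 0,
) -> CorrelationDifference:
    """Draw-wise difference of genetic correlations between two environments.

    Posteriors with unequal draw counts are matched by a seeded subsample
    of the longer one.  The pair is flagged significant when the 2.5-97.5%
    interval of the differences excludes zero.  Also reports the fraction
    of draws with positive genetic covariance in each environment (the
    sign-switch diagnostic).
    """
    ti = postA.traits.index(trait_i) if not isinstance(trait_i, int) else trait_i
    tj = postA.traits.index(trait_j) if not isinstance(trait_j, int) else trait_j
    if not (0 <= ti < len(postA.traits) and 0 <= tj < len(postA.traits)):
        raise ValueError("trait index out of range")
    nA, nB = postA.n_draws, postB.n_draws
    n = min(nA, nB)
    rng = substream(seed, "corr_diff")
    iA = np.sort(rng.choice(nA, size=n, replace=False)) if nA > n else np.arange(nA)
    iB = np.sort(rng.choice(nB, size=n, replace=False)) if nB > n else np.arange(nB)
    cA = postA.correlations()[iA, ti, tj]
    cB = postB.correlations()[iB, ti, tj]
    diff = cA - cB
    lo, hi = np.quantile(diff, [0.025, 0.975])
    covA = postA.G[iA, ti, tj]
    covB = postB.G[iB, ti, tj]
    return CorrelationDifference(
        trait_pair=(postA.traits[ti], postA.traits[tj]),
        environments=(postA.environment, postB.environment),
        differences=diff,
        interval=(float(lo), float(hi)),
        significant=bool(lo > 0 or hi < 0),
        cov_sign_agreement=(float((covA > 0).mean()), float((covB > 0).mean())),
    )
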