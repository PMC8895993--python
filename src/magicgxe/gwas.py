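"""Mixed-model GWAS for genotype-by-environment interaction.

Markers are founder-ancestry probability blocks: at marker m the predictor
is the n x f matrix of probabilities that each observation's line inherited
from each of the f founders.  Three parameterizations of GxE are scanned:

* deviation — two contrasting environments, environment coded -1/+1, test
  of founder-specific deviations between environments (H0: beta_{E:m} = 0);
* plasticity — all environments, the environment covariate is the mean
  phenotype of each environment, test of founder-specific slopes on
  environment quality;
* Finlay-Wilkinson — two-stage: per-line regression slopes of environment
  means on mean grain yield (environment quality index), then a line-level
  mixed-model association of the slopes on founder probabilities.

Polygenic background: additive effects with covariance proportional to a
(leave-one-chromosome-out) kinship K, an environment-scaled additive
deviation term, and an i.i.d. nonadditive term.  Variance ratios are
selected on a grid of variance proportions by maximum likelihood (per
marker, or once at the no-marker null fit — faster and the mode used for
permutations).  Fixed effects are fit by minimum-norm least squares after
whitening, so the founder-probability sum-to-one collinearity needs no
arbitrary reference founder; the test is a Wald chi-square on the
interaction block with degrees of freedom equal to its projected rank.

Significance is exclusively the permutation family-wise threshold: the
level-q quantile of the distribution of genome-wide minimum p-values over
phenotype permutations (lines within environment, or whole slope vectors
for the Finlay-Wilkinson scan).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from ._rng import substream
from .genotypes import KinshipMatrix
from .simulate import DHPopulation

log = logging.getLogger(__name__)

__all__ = [
    "GWASScan",
    "FWSlopes",
    "DegenerateEnvironmentError",
    "deviation_scan",
    "plasticity_scan",
    "fw_slopes",
    "fw_scan",
    "permutation_thresholds",
    "founder_representation",
]


class DegenerateEnvironmentError(ValueError):
    """All environment means equal: the interaction design is collinear."""


@dataclass
class FWSlopes:
    """Per-line Finlay-Wilkinson sensitivity slopes."""

    slopes: pd.Series  # index: line id; NaN where < 2 environments
    n_envs: pd.Series
    index_means: pd.Series  # environment-quality index (per environment)


@dataclass
class GWASScan:
    results: pd.DataFrame  # marker, chrom, pos, p, df, flags
    beta_main: np.ndarray | None  # (m, f) founder effect vectors
    beta_interaction: np.ndarray | None  # (m, f) deviation/slope effects
    ratios: dict  # variance ratios used (per chromosome)
    model: str
    thresholds: dict = field(default_factory=dict)
    prepared: object | None = None

    def min_p(self) -> float:
        return float(np.nanmin(self.results["p"].to_numpy()))


def _orth(A: np.ndarray, against: np.ndarray | None = None, rtol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of col(A) projected off col(against).

    The rank cut-off is relative to the PRE-projection scale of A, so a
    block that is numerically annihilated by the projection (fully
    collinear with ``against``) yields an empty basis rather than
    rescaled round-off directions.
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        return np.zeros((A.shape[0], 0))
    ref = np.linalg.norm(A)
    if against is not None and against.shape[1]:
        A = A - against @ (against.T @ A)
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((A.shape[0], 0))
    return U[:, s > rtol * max(s[0], ref)]


# ---------------------------------------------------------------------------
# core scan machinery


class _ChromContext:
    """Whitened quantities for one chromosome's covariance structure."""

    def __init__(self, structs: list[np.ndarray], ratios: np.ndarray, X0: np.ndarray, y: np.ndarray):
        n = len(y)
        V0 = np.eye(n)
        for h, S in zip(ratios, structs):
            if h > 0:
                V0 = V0 + h * S
        self.L = sla.cholesky(V0, lower=True)
        self.logdetV0 = 2.0 * np.log(np.diag(self.L)).sum()
        self.X0t = sla.solve_triangular(self.L, X0, lower=True)
        self.yt = sla.solve_triangular(self.L, y, lower=True)
        self.Q0 = _orth(self.X0t)
        self.ratios = ratios

    def whiten(self, M: np.ndarray) -> np.ndarray:
        return sla.solve_triangular(self.L, M, lower=True)


def _ratio_grid(n_terms: int, step: float) -> list[np.ndarray]:
    """Grid over variance proportions of the random terms (residual gets the rest).

    Proportions pi_k run over multiples of ``step`` with sum <= 1 - step;
    ratios to the residual variance are pi_k / (1 - sum pi).
    """
    levels = np.arange(0.0, 1.0 + 1e-9, step)
    cells = [np.zeros(0)]
    for _ in range(n_terms):
        cells = [np.r_[c, l] for c in cells for l in levels if c.sum() + l <= 1.0 - step + 1e-9]
    return [c / (1.0 - c.sum()) for c in cells]


def _marker_stats(ctx: _ChromContext, Xnuis: np.ndarray, Xtest: np.ndarray):
    """Whitened projections for one marker.

    ``Q_red`` spans the base design plus the marker's nuisance block;
    ``dQ`` spans the additional directions contributed by the tested block
    (its projected rank is the Wald degrees of freedom).
    """
    Qm = _orth(ctx.whiten(Xnuis), against=ctx.Q0) if Xnuis.shape[1] else np.zeros((len(ctx.yt), 0))
    Q_red = np.hstack([ctx.Q0, Qm])
    dQ = _orth(ctx.whiten(Xtest), against=Q_red)
    return Q_red, dQ


def _pvalue(yt: np.ndarray, Q_red: np.ndarray, dQ: np.ndarray, n: int):
    yy = yt @ yt
    rss_red = yy - np.sum((Q_red.T @ yt) ** 2)
    extra = np.sum((dQ.T @ yt) ** 2)
    rss_full = rss_red - extra
    rank_full = Q_red.shape[1] + dQ.shape[1]
    df = dQ.shape[1]
    if df == 0:
        return np.nan, 0, rss_full, rank_full
    s2 = rss_full / (n - rank_full)
    wald = extra / s2
    p = float(stats.chi2.sf(wald, df))
    return max(p, np.finfo(float).tiny), df, rss_full, rank_full


class PreparedScan:
    """Scan state reusable on permuted responses.

    Holds the covariance structures, the ratio grid, and lazily cached
    whitened per-marker bases per grid cell, so a permutation rerun — refit
    of the variance ratios at the no-marker null followed by the marker
    p-values — costs one re-whitening per cell plus two matrix-vector
    products per marker.
    """

    def __init__(
        self,
        model: str,
        y: np.ndarray,
        X0: np.ndarray,
        structs_by_chrom: dict,
        marker_blocks,
        marker_chrom: list,
        grid,
        env: np.ndarray | None,
        line_of_obs: np.ndarray,
    ):
        self.model = model
        self.y = y
        self.X0 = X0
        self.structs_by_chrom = structs_by_chrom
        self.marker_blocks = marker_blocks
        self.marker_chrom = marker_chrom
        self.grid = grid  # list of ratio vectors to refit over (None: frozen)
        self.env = env
        self.line_of_obs = line_of_obs
        self._cell_cache = {}  # (chrom_key, cell_index) -> (_ChromContext, [(Q_red, dQ)])
        self.contexts = {}  # chrom_key -> context used for the observed scan
        self.entries = []  # (row, chrom_key, Q_red, dQ) for the observed scan

    def _cell(self, ck, ci):
        key = (ck, ci)
        if key not in self._cell_cache:
            ctx = _ChromContext(self.structs_by_chrom[ck], self.grid[ci], self.X0, self.y)
            bases = []
            for mi, mc in enumerate(self.marker_chrom):
                if mc == ck:
                    Xnuis, Xtest = self.marker_blocks(mi)
                    bases.append(_marker_stats(ctx, Xnuis, Xtest))
                else:
                    bases.append(None)
            self._cell_cache[key] = (ctx, bases)
        return self._cell_cache[key]

    def pvalues(self, y: np.ndarray | None = None, refit: bool = True) -> np.ndarray:
        """Marker p-values for a (permuted) response.

        With ``refit`` (and a ratio grid available) the variance ratios are
        re-selected per chromosome at the no-marker null for this response,
        mirroring a full scan rerun; otherwise the observed-scan whitening
        is reused.
        """
        ys = self.y if y is None else np.asarray(y, dtype=float)
        n = len(ys)
        out = np.full(len(self.marker_chrom), np.nan)
        if not refit or self.grid is None:
            yts = {k: c.whiten(ys) for k, c in self.contexts.items()}
            for i, (_, ck, Q_red, dQ) in enumerate(self.entries):
                out[i], *_ = _pvalue(yts[ck], Q_red, dQ, n)
            return out
        for ck in self.structs_by_chrom:
            best_ci, best_ll = None, -np.inf
            for ci in range(len(self.grid)):
                ctx, _ = self._cell(ck, ci)
                yt = ctx.whiten(ys)
                rss = yt @ yt - np.sum((ctx.Q0.T @ yt) ** 2)
                ll = -0.5 * (n * np.log(rss / n) + ctx.logdetV0)
                if ll > best_ll:
                    best_ci, best_ll = ci, ll
            ctx, bases = self._cell(ck, best_ci)
            yt = ctx.whiten(ys)
            for mi, mc in enumerate(self.marker_chrom):
                if mc == ck:
                    Q_red, dQ = bases[mi]
                    out[mi], *_ = _pvalue(yt, Q_red, dQ, n)
        return out

    def permuted_response(self, rng: np.random.Generator) -> np.ndarray:
        """Permute phenotypes among lines within each environment.

        Line groups of equal size exchange their full plot-value vectors;
        for the slope model (no environment) the whole vector is permuted
        among lines.
        """
        y = self.y.copy()
        env = self.env if self.env is not None else np.zeros(len(y), dtype=int)
        for e in np.unique(env):
            sel = np.flatnonzero(env == e)
            lines_here = self.line_of_obs[sel]
            groups = {}
            for i, l in zip(sel, lines_here):
                groups.setdefault(l, []).append(i)
            by_size = {}
            for l, idx in groups.items():
                by_size.setdefault(len(idx), []).append(np.array(idx))
            for size, glist in by_size.items():
                perm = rng.permutation(len(glist))
                vals = [self.y[g] for g in glist]
                for g, j in zip(glist, perm):
                    y[g] = vals[j]
        return y


def _run_scan(
    model: str,
    y: np.ndarray,
    X0: np.ndarray,
    structs_by_chrom: dict,
    markers: pd.DataFrame,
    marker_blocks,  # mi -> (X_nuisance, X_tested)
    env: np.ndarray | None,
    line_of_obs: np.ndarray,
    mode,
    grid_step: float,
) -> GWASScan:
    n = len(y)
    chrom_keys = list(structs_by_chrom)
    n_terms = len(structs_by_chrom[chrom_keys[0]])
    marker_chrom = [
        markers["chrom"].iloc[mi] if len(chrom_keys) > 1 else chrom_keys[0]
        for mi in range(len(markers))
    ]

    refit_grid = None if isinstance(mode, dict) else _ratio_grid(n_terms, grid_step)
    prepared = PreparedScan(
        model, y, X0, structs_by_chrom, marker_blocks, marker_chrom, refit_grid, env, line_of_obs
    )

    if isinstance(mode, dict):
        ratio_sets = {k: np.asarray(mode["ratios"], dtype=float) for k in chrom_keys}
        per_marker_grid = False
    elif mode == "null":
        ratio_sets = {}
        for k in chrom_keys:
            best, best_ll = None, -np.inf
            for cell in refit_grid:
                ctx = _ChromContext(structs_by_chrom[k], cell, X0, y)
                rss = ctx.yt @ ctx.yt - np.sum((ctx.Q0.T @ ctx.yt) ** 2)
                ll = -0.5 * (n * np.log(rss / n) + ctx.logdetV0)
                if ll > best_ll:
                    best, best_ll = cell, ll
            ratio_sets[k] = best
        per_marker_grid = False
    elif mode == "grid":
        grid = refit_grid
        ratio_sets = None
        per_marker_grid = True
    else:
        raise ValueError(f"unknown ratio mode {mode!r}")

    rows = []
    beta_main_all, beta_int_all = [], []

    if not per_marker_grid:
        contexts = {k: _ChromContext(structs_by_chrom[k], ratio_sets[k], X0, y) for k in chrom_keys}
        prepared.contexts = contexts
        for mi in range(len(markers)):
            ck = markers["chrom"].iloc[mi] if len(chrom_keys) > 1 else chrom_keys[0]
            ctx = contexts[ck]
            Xnuis, Xtest = marker_blocks(mi)
            Q_red, dQ = _marker_stats(ctx, Xnuis, Xtest)
            p, df, rss_full, rank_full = _pvalue(ctx.yt, Q_red, dQ, n)
            bm, bi = _effects(ctx, Xnuis, Xtest)
            flags = [] if df > 0 else ["rank0_interaction"]
            rows.append((markers["marker"].iloc[mi], ck, markers["pos"].iloc[mi], p, df, flags))
            beta_main_all.append(bm)
            beta_int_all.append(bi)
            prepared.entries.append((rows[-1], ck, Q_red, dQ))
        used = {k: contexts[k].ratios for k in contexts}
    else:
        # per-marker grid search; prepared scan is frozen at each marker's best cell
        ctx_cache = {}
        for k in chrom_keys:
            ctx_cache[k] = [(_ChromContext(structs_by_chrom[k], cell, X0, y), cell) for cell in grid]
        prepared.contexts = {}
        for mi in range(len(markers)):
            ck = markers["chrom"].iloc[mi] if len(chrom_keys) > 1 else chrom_keys[0]
            Xnuis, Xtest = marker_blocks(mi)
            best = None
            for ci, (ctx, cell) in enumerate(ctx_cache[ck]):
                Q_red, dQ = _marker_stats(ctx, Xnuis, Xtest)
                p, df, rss_full, rank_full = _pvalue(ctx.yt, Q_red, dQ, n)
                ll = -0.5 * (n * np.log(max(rss_full, 1e-300) / n) + ctx.logdetV0)
                if best is None or ll > best[0]:
                    best = (ll, p, df, ctx, Q_red, dQ, cell, ci)
            ll, p, df, ctx, Q_red, dQ, cell, ci = best
            bm, bi = _effects(ctx, Xnuis, Xtest)
            flags = [] if df > 0 else ["rank0_interaction"]
            rows.append((markers["marker"].iloc[mi], ck, markers["pos"].iloc[mi], p, df, flags))
            beta_main_all.append(bm)
            beta_int_all.append(bi)
            key = (ck, ci)
            prepared.contexts[key] = ctx
            prepared.entries.append((rows[-1], key, Q_red, dQ))
        used = {"grid_step": grid_step}

    res = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "p", "df", "flags"])
    return GWASScan(
        results=res,
        beta_main=np.array(beta_main_all) if beta_main_all and beta_main_all[0] is not None else None,
        beta_interaction=np.array(beta_int_all) if beta_int_all else None,
        ratios={str(k): np.asarray(v).tolist() for k, v in used.items()},
        model=model,
        prepared=prepared,
    )


def _effects(ctx: _ChromContext, Xnuis: np.ndarray, Xtest: np.ndarray):
    """Minimum-norm GLS estimates of the founder effect vectors."""
    F = np.hstack([ctx.X0t, ctx.whiten(Xnuis), ctx.whiten(Xtest)])
    beta = np.linalg.pinv(F, rcond=1e-9) @ ctx.yt
    p0 = ctx.X0t.shape[1]
    fn = Xnuis.shape[1]
    bm = beta[p0 : p0 + fn] if fn else None
    bi = beta[p0 + fn :]
    return bm, bi


# ---------------------------------------------------------------------------
# public scans


def _align(table: pd.DataFrame, trait: str, pop: DHPopulation):
    t = table.dropna(subset=[trait]).reset_index(drop=True)
    line_index = {l: i for i, l in enumerate(pop.lines)}
    known = t["line"].map(line_index)
    if known.isna().any():
        t = t[known.notna()].reset_index(drop=True)
    lidx = t["line"].map(line_index).to_numpy(dtype=int)
    return t, lidx


def _kinship_for(kinship, chrom, lidx: np.ndarray) -> np.ndarray:
    k = kinship[chrom] if isinstance(kinship, dict) else kinship
    K = k.regularized() if isinstance(k, KinshipMatrix) else np.asarray(k)
    return K[np.ix_(lidx, lidx)]


def deviation_scan(
    table: pd.DataFrame,
    pop: DHPopulation,
    kinship,
    trait: str,
    env_pair: tuple | None = None,
    markers: np.ndarray | None = None,
    mode="grid",
    grid_step: float = 0.1,
    include_nonadditive: bool = True,
) -> GWASScan:
    """Main-plus-deviation GxE scan across exactly two environments.

    The environment covariate w is +1 for the first and -1 for the second
    environment of ``env_pair``; the tested block is the w-scaled founder
    probability matrix (founder effect differences between environments).
    """
    envs = pd.unique(table["environment"]) if env_pair is None else list(env_pair)
    if len(envs) != 2:
        raise ValueError("deviation scan requires exactly 2 environments")
    sub = table[table["environment"].isin(envs)]
    t, lidx = _align(sub, trait, pop)
    y = t[trait].to_numpy(dtype=float)
    w = np.where(t["environment"].to_numpy() == envs[0], 1.0, -1.0)
    X0 = np.column_stack([np.ones(len(t)), w])
    return _gxe_scan_common(
        "deviation", t, lidx, y, w, X0, pop, kinship, markers, mode, grid_step, include_nonadditive
    )


def plasticity_scan(
    table: pd.DataFrame,
    pop: DHPopulation,
    kinship,
    trait: str,
    markers: np.ndarray | None = None,
    mode="grid",
    grid_step: float = 0.1,
    include_nonadditive: bool = True,
) -> GWASScan:
    """Plasticity GxE scan: founder-specific slopes on environment quality.

    The environment covariate w is the mean phenotype of each observation's
    environment (computed from the unpermuted data and held fixed), and the
    per-environment means enter the fixed part as environment dummies.
    """
    t, lidx = _align(table, trait, pop)
    envs = pd.unique(t["environment"])
    if len(envs) < 3:
        raise ValueError("plasticity scan requires at least 3 environments")
    y = t[trait].to_numpy(dtype=float)
    env_means = t.groupby("environment")[trait].mean()
    if env_means.std() < 1e-12:
        raise DegenerateEnvironmentError(
            "all environment means are equal: the plasticity interaction is collinear with the main founder block"
        )
    w = t["environment"].map(env_means).to_numpy(dtype=float)
    X0 = pd.get_dummies(t["environment"]).to_numpy(dtype=float)
    return _gxe_scan_common(
        "plasticity", t, lidx, y, w, X0, pop, kinship, markers, mode, grid_step, include_nonadditive
    )


def _gxe_scan_common(
    model, t, lidx, y, w, X0, pop, kinship, markers, mode, grid_step, include_nonadditive
):
    n = len(t)
    Zrows = np.arange(n)
    uniq_lines, line_code = np.unique(lidx, return_inverse=True)
    Z = np.zeros((n, len(uniq_lines)))
    Z[Zrows, line_code] = 1.0
    wZ = Z * w[:, None]

    marker_idx = np.arange(pop.panel.n_markers) if markers is None else np.asarray(markers)
    mmap = pop.panel.marker_map().iloc[marker_idx].reset_index(drop=True)
    chroms = pd.unique(mmap["chrom"])

    structs_by_chrom = {}
    for c in chroms:
        Ksub = _kinship_for(kinship, c, lidx)
        structs = [Ksub, (w[:, None] * Ksub) * w[None, :]]
        if include_nonadditive:
            structs.append(Z @ Z.T)
        structs_by_chrom[c] = structs

    probs = pop.founder_probs

    def marker_blocks(mi):
        Xm = probs[marker_idx[mi]][lidx].astype(float)
        return Xm, Xm * w[:, None]

    env = t["environment"].to_numpy()
    return _run_scan(model, y, X0, structs_by_chrom, mmap, marker_blocks, env, lidx, mode, grid_step)


def fw_slopes(table: pd.DataFrame, trait: str, index_trait: str = "trait_1") -> FWSlopes:
    """Finlay-Wilkinson slopes: line environment means regressed on the
    all-line environment means of the index trait (environment quality).

    Slopes are defined only for lines observed in >= 2 environments.
    """
    idx_means = table.groupby("environment")[index_trait].mean()
    if idx_means.isna().any():
        raise ValueError("index trait missing in some environment")
    line_env = table.groupby(["line", "environment"])[trait].mean().reset_index()
    slopes, counts = {}, {}
    for l, grp in line_env.groupby("line"):
        g = grp.dropna(subset=[trait])
        counts[l] = len(g)
        if len(g) < 2:
            slopes[l] = np.nan
            continue
        x = idx_means.loc[g["environment"]].to_numpy(dtype=float)
        yv = g[trait].to_numpy(dtype=float)
        xc = x - x.mean()
        denom = xc @ xc
        slopes[l] = float(xc @ (yv - yv.mean()) / denom) if denom > 0 else np.nan
    return FWSlopes(
        slopes=pd.Series(slopes), n_envs=pd.Series(counts), index_means=idx_means
    )


def fw_scan(
    slopes: FWSlopes,
    pop: DHPopulation,
    kinship,
    markers: np.ndarray | None = None,
    mode="grid",
    grid_step: float = 0.1,
    prob_threshold: float = 0.8,
    min_hard_carriers: int = 2,
    min_expected_support: float = 3.0,
) -> GWASScan:
    """Line-level mixed-model association of Finlay-Wilkinson slopes.

    Model: s = X_m beta_s + u_s + e with u_s ~ K.  Markers where a founder
    has fewer than ``min_hard_carriers`` lines at probability above
    ``prob_threshold``, or fewer than ``min_expected_support`` expected
    carriers among lines with slopes, are flagged ``low_founder_support``
    (the underrepresented-founder artifact) regardless of p-value.
    """
    s = slopes.slopes.dropna()
    if len(s) == 0:
        raise ValueError("all slopes are missing")
    line_index = {l: i for i, l in enumerate(pop.lines)}
    lidx = np.array([line_index[l] for l in s.index if l in line_index])
    y = s.loc[[l for l in s.index if l in line_index]].to_numpy(dtype=float)

    marker_idx = np.arange(pop.panel.n_markers) if markers is None else np.asarray(markers)
    mmap = pop.panel.marker_map().iloc[marker_idx].reset_index(drop=True)
    chroms = pd.unique(mmap["chrom"])
    structs_by_chrom = {c: [_kinship_for(kinship, c, lidx)] for c in chroms}
    X0 = np.ones((len(y), 1))
    probs = pop.founder_probs

    # the tested block is the whole founder-probability block (H0: beta_s = 0)
    def marker_blocks(mi):
        Xm = probs[marker_idx[mi]][lidx].astype(float)
        return np.zeros((len(y), 0)), Xm

    scan = _run_scan("fw", y, X0, structs_by_chrom, mmap, marker_blocks, None, lidx, mode, grid_step)
    P = probs[marker_idx][:, lidx, :].astype(float)  # (m, r_obs, f)
    hard = (P > prob_threshold).sum(axis=1)  # (m, f)
    expected = P.sum(axis=1)
    low = (hard < min_hard_carriers) | (expected < min_expected_support)
    flags = scan.results["flags"].tolist()
    for mi in range(len(flags)):
        if low[mi].any():
            flags[mi] = list(flags[mi]) + ["low_founder_support"]
    scan.results["flags"] = flags
    return scan


def permutation_thresholds(
    scan: GWASScan,
    n_perm: int = 100,
    levels: tuple = (0.05, 0.10),
    seed: int = 0,
) -> dict:
    """Family-wise significance thresholds from phenotype permutations.

    Each permutation respects the model's exchangeable unit (line groups
    within environment for the deviation/plasticity scans; the whole slope
    vector among lines for the Finlay-Wilkinson scan), the genome-wide
    minimum p-value is recorded, and the level-q threshold is the q-quantile
    (inverted-CDF, i.e. the ceil(q*n_perm)-th order statistic) of those
    minima.  Variance ratios are held at the observed-data fit.  A failed
    permutation is retried on the next substream (logged).
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    prepared: PreparedScan = scan.prepared
    minima = []
    attempt = 0
    while len(minima) < n_perm:
        rng = substream(seed, "perm", attempt)
        attempt += 1
        try:
            yp = prepared.permuted_response(rng)
            p = prepared.pvalues(yp)
            minima.append(np.nanmin(p))
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("permutation %d failed (%s); retrying with next substream", attempt, exc)
            if attempt > n_perm * 3:
                raise
    minima = np.array(minima)
    thresholds = {
        level: float(np.quantile(minima, level, method="inverted_cdf")) for level in levels
    }
    scan.thresholds = thresholds
    scan.thresholds["minima"] = minima
    return thresholds


def founder_representation(
    probs: np.ndarray, threshold_prob: float = 0.8, min_expected: float = 5.0
):
    """Per marker x founder: expected carriers, hard carriers, and flags.

    ``expected`` sums the founder probabilities over lines; ``hard`` counts
    lines whose probability exceeds ``threshold_prob``.  Founders with
    fewer than ``min_expected`` expected carriers are flagged — markers
    driven by such founders are prone to artifactual effect estimates.
    """
    P = np.asarray(probs, dtype=float)
    expected = P.sum(axis=1)
    hard = (P > threshold_prob).sum(axis=1)
    flags = expected < min_expected
    return {"expected": expected, "hard": hard, "flagged": flags}
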