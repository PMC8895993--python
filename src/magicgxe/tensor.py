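"""Covariance-tensor eigenanalysis of a set of G-matrices.

The m per-environment genetic covariance matrices (t traits each) are
vectorized with a Frobenius-isometric weighting (off-diagonals times
sqrt(2)), and their v x v sample covariance matrix S (v = t(t+1)/2,
divisor m - 1) is eigen-decomposed.  The eigenvectors map back to
orthonormal symmetric matrices — eigentensors — describing independent
axes of coordinated change among the G-matrices; at most m - 1 eigenvalues
are nonzero because S is a covariance of m centered points.

Uncertainty is propagated by projecting matched MCMC draws of the
G-matrices onto the fixed observed eigentensors; significance is assessed
against a null built by shuffling phenotypic records among environments
and refitting the G-matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .gmatrix import GMatrixPosterior, fit_gmatrix

log = logging.getLogger(__name__)

__all__ = [
    "CovarianceTensor",
    "TensorNull",
    "vech_weighted",
    "unvech_weighted",
    "build_tensor",
    "project",
    "element_contributions",
    "tensor_uncertainty",
    "randomization_null",
]

EIG_TOL = 1e-10  # eigenvalues below EIG_TOL * lambda_1 are treated as zero


@dataclass
class CovarianceTensor:
    S: np.ndarray  # (v, v) covariance among vectorized G-matrices
    eigenvalues: np.ndarray  # (v,) descending
    eigentensors: np.ndarray  # (v, t, t) orthonormal under Frobenius inner product
    variance_fractions: np.ndarray  # eigenvalues / sum
    m: int
    t: int

    def n_nonzero(self, tol: float = EIG_TOL) -> int:
        lam1 = self.eigenvalues[0] if self.eigenvalues[0] > 0 else 1.0
        return int(np.sum(self.eigenvalues > tol * lam1))


@dataclass
class TensorNull:
    observed_fractions: np.ndarray  # (n_samples, v) posterior variance fractions
    null_fractions: np.ndarray  # (n_shuffles, v) shuffle variance fractions
    significant: np.ndarray  # (v,) flags
    quantiles: dict = field(default_factory=dict)


def _vech_indices(t: int):
    rows, cols = [], []
    for i in range(t):
        for j in range(i, t):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


def vech_weighted(G: np.ndarray) -> np.ndarray:
    """Half-vectorization with off-diagonals scaled by sqrt(2).

    Row-major upper-triangle order; the Euclidean norm of the result equals
    the Frobenius norm of G, so distances between vectors equal Frobenius
    distances between matrices.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G must be symmetric (within 1e-8)")
    r, c = _vech_indices(G.shape[0])
    w = np.where(r == c, 1.0, np.sqrt(2.0))
    return G[r, c] * w


def unvech_weighted(v: np.ndarray, t: int) -> np.ndarray:
    """Inverse of :func:`vech_weighted`."""
    r, c = _vech_indices(t)
    w = np.where(r == c, 1.0, 1.0 / np.sqrt(2.0))
    G = np.zeros((t, t))
    G[r, c] = v * w
    G[c, r] = G[r, c]
    return G


def build_tensor(Gs) -> CovarianceTensor:
    """Eigen-decompose the covariance of a set of (posterior-median) G-matrices.

    S is the sample covariance (divisor m - 1) of the weighted-vech
    vectors; eigentensors are returned with the sign convention that their
    largest-magnitude element is positive, eigenvalues in descending order
    (ties broken by first occurrence).
    """
    Gs = [np.asarray(G, dtype=float) for G in Gs]
    m = len(Gs)
    if m < 2:
        raise ValueError("need at least 2 matrices")
    t = Gs[0].shape[0]
    if any(G.shape != (t, t) for G in Gs):
        raise ValueError("all matrices must share the same trait count")
    V = np.stack([vech_weighted(G) for G in Gs])  # (m, v)
    S = np.cov(V, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    lam, vec = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam = np.maximum(lam[order], 0.0)
    vec = vec[:, order]
    ets = []
    for k in range(vec.shape[1]):
        E = unvech_weighted(vec[:, k], t)
        flat = E.ravel()
        if flat[np.argmax(np.abs(flat))] < 0:
            E = -E
        ets.append(E)
    total = lam.sum()
    fracs = lam / total if total > 0 else np.zeros_like(lam)
    return CovarianceTensor(
        S=S, eigenvalues=lam, eigentensors=np.array(ets), variance_fractions=fracs, m=m, t=t
    )


def project(G: np.ndarray, eigentensor: np.ndarray) -> float:
    """Frobenius inner product <G, E> — the coordinate of G on the eigentensor."""
    G = np.asarray(G, dtype=float)
    E = np.asarray(eigentensor, dtype=float)
    if G.shape != E.shape:
        raise ValueError("dimension mismatch")
    return float(np.sum(G * E))


def element_contributions(tensor: CovarianceTensor, k: int) -> np.ndarray:
    """Sign-free element contributions to the k-th eigentensor, max-normalized."""
    if not 0 <= k < len(tensor.eigentensors):
        raise ValueError("eigentensor index out of range")
    A = np.abs(tensor.eigentensors[k])
    mx = A.max()
    return A / mx if mx > 0 else A


def tensor_uncertainty(
    posteriors: list[GMatrixPosterior],
    tensor: CovarianceTensor | None = None,
    n_samples: int = 500,
    seed: int = 0,
    refit_axes: bool = False,
):
    """Propagate G-matrix posterior uncertainty through the eigenanalysis.

    For each of ``n_samples`` matched posterior draws (one G per
    environment), the variance fractions explained along the FIXED observed
    eigentensors are recomputed, together with each environment's
    coordinate on each eigentensor.  With ``refit_axes`` the eigentensors
    are instead re-derived per draw (fractions are then sorted eigenvalue
    shares and no longer attach to fixed axes).
    """
    if tensor is None:
        tensor = build_tensor([p.median_G() for p in posteriors])
    n_min = min(p.n_draws for p in posteriors)
    n_samples = min(n_samples, n_min)
    rng = substream(seed, "tensor_uncertainty")
    idx = [
        np.sort(rng.choice(p.n_draws, size=n_samples, replace=False)) for p in posteriors
    ]
    v = len(tensor.eigentensors)
    fracs = np.empty((n_samples, v))
    lams = np.empty((n_samples, v))
    coords = np.empty((n_samples, len(posteriors), v))
    for s in range(n_samples):
        Gs = [p.G[idx[e][s]] for e, p in enumerate(posteriors)]
        if refit_axes:
            tt = build_tensor(Gs)
            fracs[s] = tt.variance_fractions
            lams[s] = tt.eigenvalues
            axes = tt.eigentensors
        else:
            V = np.stack([vech_weighted(G) for G in Gs])
            S = np.atleast_2d(np.cov(V, rowvar=False, ddof=1))
            W = np.stack([vech_weighted(E) for E in tensor.eigentensors])
            lams[s] = np.einsum("kv,vw,kw->k", W, S, W)
            tot = np.trace(S)
            fracs[s] = lams[s] / tot if tot > 0 else 0.0
            axes = tensor.eigentensors
        for e, G in enumerate(Gs):
            for k in range(v):
                coords[s, e, k] = project(G, axes[k])
    return {"fractions": fracs, "eigenvalues": lams, "coordinates": coords, "tensor": tensor}


def _shuffle_environments(table: pd.DataFrame, rng, min_lines: int = 10) -> pd.DataFrame:
    """Shuffle environment labels among line-by-environment records.

    Lines keep their identities; the multiset of environment labels (hence
    per-environment record counts) is preserved.  Reshuffles (logged) if a
    pseudo-environment ends up with fewer than ``min_lines`` distinct lines.
    """
    keys = table[["line", "environment"]].drop_duplicates().reset_index(drop=True)
    for attempt in range(50):
        perm = rng.permutation(len(keys))
        new_env = keys["environment"].to_numpy()[perm]
        assigned = keys.assign(new_environment=new_env)
        ok = True
        for e, grp in assigned.groupby("new_environment"):
            if grp["line"].nunique() < min_lines:
                ok = False
                break
        if ok:
            merged = table.merge(assigned, on=["line", "environment"], how="left")
            merged["environment"] = merged.pop("new_environment")
            return merged
        log.info("environment shuffle left a small pseudo-environment; reshuffling")
    raise RuntimeError("could not produce a valid environment shuffle")


def randomization_null(
    table: pd.DataFrame,
    traits: list,
    n_shuffles: int = 20,
    seed: int = 0,
    n_posterior_samples: int = 200,
    alpha: float = 0.05,
    min_lines: int = 10,
    fit_kwargs: dict | None = None,
    posteriors: list[GMatrixPosterior] | None = None,
) -> TensorNull:
    """Shuffle-among-environments significance test for the eigentensors.

    Each shuffle permutes environment labels over line-by-environment
    records, refits the per-environment G-matrix posteriors (at the —
    typically reduced — MCMC budget in ``fit_kwargs``), and builds the
    covariance tensor on matched posterior draws of the refit matrices,
    recording the variance explained (sorted eigenvalues) per eigentensor.
    The observed side does the same on matched posterior draws of the real
    G-matrices, so both distributions carry identical MCMC noise and the
    identical selection effect of ranking eigentensors.  The k-th
    eigentensor is flagged significant when the ``alpha`` quantile of the
    observed k-th variance-explained exceeds the ``1 - alpha`` quantile of
    the null distribution (conservative overlap rule); shuffling
    homogenizes the per-environment matrices, so genuine environmental
    structure collapses the null eigenvalues.
    """
    if n_shuffles < 10:
        raise ValueError("need at least 10 shuffles")
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("chains", 2)
    fit_kwargs.setdefault("burnin", 150)
    fit_kwargs.setdefault("draws", 300)
    if fit_kwargs["burnin"] < 500:
        log.warning(
            "randomization_null: reduced MCMC budget (burnin=%d, draws=%d) per shuffle",
            fit_kwargs["burnin"],
            fit_kwargs["draws"],
        )
    envs = list(pd.unique(table["environment"]))

    if posteriors is None:
        posteriors = [
            fit_gmatrix(table, environment=e, traits=traits, seed=seed + 1000 + i, **fit_kwargs)
            for i, e in enumerate(envs)
        ]
    tensor = build_tensor([p.median_G() for p in posteriors])
    obs = tensor_uncertainty(
        posteriors, tensor, n_samples=n_posterior_samples, seed=seed, refit_axes=True
    )

    v = len(tensor.eigentensors)
    per_shuffle = max(n_posterior_samples // n_shuffles, 10)
    null_lams, null_fracs = [], []
    for s in range(n_shuffles):
        rng = substream(seed, "shuffle", s)
        shuffled = _shuffle_environments(table, rng, min_lines=min_lines)
        posts = [
            fit_gmatrix(
                shuffled, environment=e, traits=traits, seed=seed + 2000 + s * len(envs) + i, **fit_kwargs
            )
            for i, e in enumerate(envs)
        ]
        nn = tensor_uncertainty(posts, tensor, n_samples=per_shuffle, seed=seed + s, refit_axes=True)
        null_lams.append(nn["eigenvalues"])
        null_fracs.append(nn["fractions"])
    null_lams = np.vstack(null_lams)
    null_fracs = np.vstack(null_fracs)

    lo_obs = np.quantile(obs["eigenvalues"], alpha, axis=0)
    hi_null = np.quantile(null_lams, 1 - alpha, axis=0)
    significant = lo_obs > hi_null
    return TensorNull(
        observed_fractions=obs["fractions"],
        null_fractions=null_fracs,
        significant=significant,
        quantiles={
            "observed_low": lo_obs,
            "null_high": hi_null,
            "alpha": alpha,
            "observed_eigenvalues": obs["eigenvalues"],
            "null_eigenvalues": null_lams,
        },
    )
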