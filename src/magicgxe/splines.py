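"""Tensor-product B-spline bases for field-trial spatial adjustment.

A smooth surface over the (row, column) plot grid of each environment is
modelled as a tensor product of marginal cubic B-splines, fit as a random
effect with an identity penalty on the coefficients.  The same basis is
used by the univariate variance-component model and the multivariate
G-matrix sampler.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["marginal_basis", "tensor_basis", "environment_spline_block"]


def marginal_basis(x: np.ndarray, n_knots: int = 6) -> np.ndarray:
    """Cubic B-spline design matrix for one coordinate.

    ``n_knots`` evenly spaced knots span the observed range (boundary knots
    repeated for the cubic order), giving ``n_knots + 2`` basis columns.
    Degenerate coordinates (a single distinct value) yield a single
    constant column.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.ones((x.size, 1))
    inner = np.linspace(lo, hi, max(int(n_knots), 2))
    t = np.r_[[lo] * 3, inner, [hi] * 3]
    return BSpline.design_matrix(x, t, k=3, extrapolate=False).toarray()


def tensor_basis(x: np.ndarray, y: np.ndarray, knots: tuple[int, int] = (6, 6)) -> np.ndarray:
    """Row-wise tensor product of the marginal bases in x and y, centered.

    Columns are centered so the surface cannot absorb the environment mean;
    all-zero columns (possible after centering a degenerate margin) are
    dropped.
    """
    bx = marginal_basis(x, knots[0])
    by = marginal_basis(y, knots[1])
    tb = (bx[:, :, None] * by[:, None, :]).reshape(len(bx), -1)
    tb = tb - tb.mean(axis=0)
    keep = np.linalg.norm(tb, axis=0) > 1e-10
    return tb[:, keep]


def environment_spline_block(
    env: np.ndarray, x: np.ndarray, y: np.ndarray, knots: tuple[int, int] = (6, 6)
) -> np.ndarray:
    """Block-diagonal tensor basis, one block per environment.

    Returns an (n, q) dense matrix where rows of one environment are zero
    outside that environment's block — the incidence matrix of the field
    surface nested within environment.
    """
    env = np.asarray(env)
    blocks = []
    n = len(env)
    for e in pd_unique(env):
        mask = env == e
        b = tensor_basis(np.asarray(x)[mask], np.asarray(y)[mask], knots)
        blocks.append((mask, b))
    q = sum(b.shape[1] for _, b in blocks)
    out = np.zeros((n, q))
    col = 0
    for mask, b in blocks:
        out[mask, col : col + b.shape[1]] = b
        col += b.shape[1]
    return out


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance (stable, no sorting)."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]
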