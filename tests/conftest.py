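"""Shared fixtures: small MAGIC populations and model-consistent simulators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from magicgxe import simulate as sim
from magicgxe.genotypes import loco_kinship


@pytest.fixture(scope="session")
def small_panel():
    return sim.simulate_founders(n_founders=8, n_chrom=2, markers_per_chrom=25, seed=11)


@pytest.fixture(scope="session")
def small_pop(small_panel):
    return sim.simulate_dh_lines(small_panel, n_lines=40, expected_block_cM=25, seed=11)


@pytest.fixture(scope="session")
def gwas_pop():
    """150 lines, 16 founders, sparse low-LD markers on 2 chromosomes."""
    panel = sim.simulate_founders(n_founders=16, n_chrom=2, markers_per_chrom=60, seed=5)
    return sim.simulate_dh_lines(panel, n_lines=150, expected_block_cM=1.0, seed=5)


@pytest.fixture(scope="session")
def gwas_kinship(gwas_pop):
    mm = gwas_pop.panel.marker_map()
    return {
        c: loco_kinship(gwas_pop.genotypes, mm, c, lines=gwas_pop.lines)
        for c in gwas_pop.panel.chromosomes
    }


def model_consistent_table(
    pop,
    kinship_chol: np.ndarray,
    env_w: dict,
    vg1: float,
    veg1: float,
    vg2: float,
    ve: float,
    rng: np.random.Generator,
    plots: int = 2,
    marker_effect=None,
):
    """Phenotypes drawn from the GWAS mixed model's own covariance.

    y = mu_e + g1 + w_e * d + g2 + eps with g1, d ~ N(0, v K), g2 iid,
    eps iid — the exact null (or, with ``marker_effect`` = (Xm_line,
    beta_env_by_founder), a single-QTL alternative) for the association
    scans.
    """
    r = pop.n_lines
    g1 = kinship_chol @ rng.normal(size=r) * np.sqrt(vg1)
    d = kinship_chol @ rng.normal(size=r) * np.sqrt(veg1)
    g2 = rng.normal(size=r) * np.sqrt(vg2)
    rows = []
    for ei, (e, w) in enumerate(env_w.items()):
        qtl = np.zeros(r)
        if marker_effect is not None:
            Xm, beta = marker_effect
            qtl = Xm @ beta[ei]
        for p in range(plots):
            noise = rng.normal(size=r) * np.sqrt(ve)
            for l in range(r):
                rows.append(
                    (pop.lines[l], e, p + 1, 0, 0, w * 0.5 + g1[l] + w * d[l] + g2[l] + qtl[l] + noise[l])
                )
    return pd.DataFrame(rows, columns=["line", "environment", "plot", "x", "y", "trait_1"])


@pytest.fixture(scope="session")
def psd_cor5():
    """A 5-trait correlation matrix with +/-0.5 off-diagonals (PSD)."""
    t = 5
    base = np.full((t, t), 0.5)
    np.fill_diagonal(base, 1.0)
    s = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
    return base * np.outer(s, s)
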