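"""Genomic relationship matrices from homozygous-line genotypes.

Kinship is estimated with the VanRaden genomic relationship matrix
K = M M' / (2 * sum_j p_j (1 - p_j)), where M is the allele-count matrix
column-centered at twice the sample allele frequency p_j.  Doubled-haploid
lines are coded {0, 2} so p_j is counts / (2 r).  Markers can first be
thinned for linkage disequilibrium with a greedy windowed prune, and a
leave-one-chromosome-out (LOCO) kinship excludes the tested chromosome to
avoid proximal contamination in association scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["KinshipMatrix", "ld_prune", "vanraden_kinship", "loco_kinship"]

RIDGE = 1e-8  # diagonal ridge applied before any factorization


@dataclass
class KinshipMatrix:
    values: np.ndarray  # (r, r) symmetric
    lines: list
    excluded_chromosome: object | None = None

    def regularized(self) -> np.ndarray:
        """Kinship with the documented ridge on the diagonal (PSD, Cholesky-safe)."""
        log.debug("adding ridge %.1e to kinship diagonal", RIDGE)
        return self.values + RIDGE * np.eye(len(self.lines))

    def validate(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


def _polymorphic_mask(genotypes: np.ndarray) -> np.ndarray:
    return genotypes.std(axis=0) > 0


def ld_prune(
    genotypes: np.ndarray,
    marker_map: pd.DataFrame,
    window_kb: float = 50.0,
    step: int = 5,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Greedy windowed LD prune; returns retained marker indices.

    Within each window of ``window_kb`` kilobases (closed interval in bp,
    anchored at successive retained positions and advanced ``step`` markers
    at a time) the later marker of any retained pair with squared Pearson
    correlation above the threshold is dropped.  Monomorphic markers are
    dropped up front (logged) — they carry no LD information.  The result
    is deterministic given the input order.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    m = genotypes.shape[1]
    if len(marker_map) != m:
        raise ValueError("marker map length does not match genotype columns")
    chrom = marker_map["chrom"].to_numpy()
    pos = marker_map["pos"].to_numpy()
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if not (np.diff(p) >= 0).all():
            raise ValueError("markers must be sorted by (chrom, pos)")

    keep = _polymorphic_mask(genotypes).copy()
    n_mono = int((~keep).sum())
    if n_mono:
        log.info("ld_prune: dropping %d monomorphic markers", n_mono)

    window_bp = window_kb * 1000.0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            anchor = idx[start]
            in_win = idx[(pos[idx] >= pos[anchor]) & (pos[idx] <= pos[anchor] + window_bp)]
            live = [i for i in in_win if keep[i]]
            for a_i in range(len(live)):
                a = live[a_i]
                if not keep[a]:
                    continue
                for b in live[a_i + 1 :]:
                    if not keep[b]:
                        continue
                    r = np.corrcoef(genotypes[:, a], genotypes[:, b])[0, 1]
                    if r * r > r2_threshold:
                        keep[b] = False
            start += step
    return np.flatnonzero(keep)


def vanraden_kinship(genotypes: np.ndarray, lines: list | None = None) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from allele counts in {0, 1, 2}."""
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 lines")
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError(
            "all markers are monomorphic: VanRaden denominator 2*sum(p(1-p)) is zero"
        )
    M = X - 2.0 * p
    K = (M @ M.T) / denom
    if lines is None:
        lines = list(range(X.shape[0]))
    log.info("vanraden_kinship: %d lines, %d markers, mean diagonal %.3f", X.shape[0], X.shape[1], np.mean(np.diag(K)))
    return KinshipMatrix(values=K, lines=list(lines))


def loco_kinship(
    genotypes: np.ndarray,
    marker_map: pd.DataFrame,
    chromosome,
    lines: list | None = None,
) -> KinshipMatrix:
    """Kinship from all markers not on ``chromosome`` (leave one chromosome out).

    Markers that are monomorphic within the retained subset are re-filtered
    before the computation (counts logged).
    """
    chrom = marker_map["chrom"].to_numpy()
    uniq = pd.unique(chrom)
    if len(uniq) < 2:
        raise ValueError("LOCO kinship needs at least 2 chromosomes")
    if chromosome not in set(uniq.tolist()):
        raise ValueError(f"unknown chromosome {chromosome!r}")
    mask = chrom != chromosome
    sub = np.asarray(genotypes, dtype=float)[:, mask]
    poly = _polymorphic_mask(sub)
    log.info(
        "loco_kinship: excluding chromosome %s (%d markers); %d polymorphic markers retained",
        chromosome,
        int((~mask).sum()),
        int(poly.sum()),
    )
    k = vanraden_kinship(sub[:, poly], lines=lines)
    k.excluded_chromosome = chromosome
    return k
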