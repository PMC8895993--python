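"""Synthetic MAGIC population and multi-environment trial generator.

Emulates the structure of a 16-founder maize MAGIC doubled-haploid (DH)
population phenotyped in several environments: founder haplotypes, mosaic
DH genomes with exponentially distributed ancestry blocks, founder-ancestry
probabilities per marker, and plot-level phenotypes combining environment
means, environment-specific QTL founder effects, polygenic main and
interaction (GxE) effects, a smooth 2D field surface, and plot residuals.
Every generated component is returned as ground truth so downstream
estimators can be tested for recovery.

The ancestry process is a Markov mosaic — uniform founder choice with
exponential block lengths — not an explicit 8-generation funnel pedigree;
downstream methods consume only genotypes and probabilities, and the block
length scale is a user parameter (1 cM is mapped to 1 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "FounderPanel",
    "DHPopulation",
    "TrialDesign",
    "EffectSpec",
    "SimTruth",
    "simulate_founders",
    "simulate_dh_lines",
    "blur_probabilities",
    "simulate_trial",
    "gaussian_field_surface",
]

BP_PER_CM = 1_000_000  # map scale: 1 cM per Mb


@dataclass
class FounderPanel:
    """Founder haplotypes: biallelic allele indicators at mapped markers."""

    chrom: np.ndarray  # (m,) chromosome id per marker
    pos: np.ndarray  # (m,) bp position, strictly increasing within chrom
    alleles: np.ndarray  # (n_founders, m) 0/1

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def chromosomes(self) -> np.ndarray:
        _, idx = np.unique(self.chrom, return_index=True)
        return self.chrom[np.sort(idx)]

    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(self.n_markers)],
                "chrom": self.chrom,
                "pos": self.pos,
            }
        )

    def validate(self) -> None:
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("founder alleles must be 0/1")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {c}")


@dataclass
class DHPopulation:
    """Doubled-haploid lines as founder mosaics with marker data.

    ``mosaics[line][chrom]`` is a list of (start_bp, end_bp, founder) blocks
    tiling the chromosome; ``genotypes`` counts the alternate allele in
    {0, 2} (DH lines are fully homozygous); ``founder_probs[m, l]`` is the
    probability vector over founders at marker m for line l.
    """

    panel: FounderPanel
    lines: list
    mosaics: list  # per line: dict chrom -> list of (start, end, founder)
    genotypes: np.ndarray  # (r, m) in {0, 2}
    founder_probs: np.ndarray  # (m, r, n_founders)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def validate(self, atol: float = 1e-9) -> None:
        s = self.founder_probs.sum(axis=2)
        if not np.allclose(s, 1.0, atol=atol):
            raise ValueError("founder probability slices must sum to 1")
        if not np.isin(self.genotypes, [0, 2]).all():
            raise ValueError("DH genotypes must be 0 or 2")


@dataclass
class TrialDesign:
    """Layout of a multi-environment trial on rectangular fields."""

    environments: dict  # env id -> environment mean shift
    plots_per_line: int = 2
    field_dims: tuple[int, int] | None = None  # (rows, cols); auto if None
    missing_lines: dict = field(default_factory=dict)  # env -> set of line ids

    def env_ids(self) -> list:
        return list(self.environments)


@dataclass
class EffectSpec:
    """Ground-truth effect sizes for the trial generator.

    ``qtl`` entries are (marker index, effects) with effects shaped
    (n_env, n_founders): founder-specific, environment-specific allele
    effects.  Variances are per-trait generative variances; ``multitrait``
    optionally supplies per-environment (G, R) covariance matrices for t
    traits, in which case line-level trait vectors are drawn with
    covariance G and plot residuals with covariance R.
    """

    qtl: list = field(default_factory=list)
    v_g: float = 0.0
    v_gxe: float = 0.0
    v_e: float = 0.0
    v_spline: float = 0.0
    v_resid: float = 1.0
    fw_slopes: np.ndarray | None = None  # per-line sensitivity multipliers
    multitrait: dict | None = None  # env -> {"G": (t,t), "R": (t,t)}
    polygenic_markers: np.ndarray | None = None  # marker indices backing the polygenic terms
    polygenic_mode: str = "markers"  # "markers": genome-backed effects; "iid": exchangeable line effects

    def validate(self, n_env: int, n_founders: int) -> None:
        for v, name in [
            (self.v_g, "v_g"),
            (self.v_gxe, "v_gxe"),
            (self.v_e, "v_e"),
            (self.v_spline, "v_spline"),
            (self.v_resid, "v_resid"),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be nonnegative")
        for _, eff in self.qtl:
            eff = np.asarray(eff)
            if eff.shape != (n_env, n_founders):
                raise ValueError(
                    f"QTL effect matrix must be (n_env={n_env}, n_founders={n_founders}); got {eff.shape}"
                )
        if self.multitrait is not None:
            tdims = set()
            for env, mats in self.multitrait.items():
                for key in ("G", "R"):
                    m = np.asarray(mats[key])
                    if m.ndim != 2 or m.shape[0] != m.shape[1]:
                        raise ValueError(f"{key} for {env} must be square")
                    if not np.allclose(m, m.T, atol=1e-8):
                        raise ValueError(f"{key} for {env} must be symmetric")
                    if np.linalg.eigvalsh((m + m.T) / 2).min() < -1e-8:
                        raise ValueError(f"{key} for {env} must be PSD")
                    tdims.add(m.shape[0])
            if len(tdims) != 1:
                raise ValueError("multitrait G/R matrices disagree on trait count")


@dataclass
class SimTruth:
    """Realized ground-truth components of a simulated trial."""

    env_means: dict
    line_effects: np.ndarray | None  # (r,) polygenic main effects
    gxe_effects: np.ndarray | None  # (n_env, r) polygenic interaction effects
    qtl_values: np.ndarray | None  # (n_env, r) summed QTL contributions
    field_surfaces: dict  # env -> (rows, cols) surface values
    multitrait_U: dict | None  # env -> (r, t) line trait effects


# ---------------------------------------------------------------------------
# founders


def simulate_founders(
    n_founders: int = 16,
    n_chrom: int = 10,
    markers_per_chrom: int = 200,
    seed: int = 0,
    chrom_length_bp: int | None = None,
) -> FounderPanel:
    """Draw a polymorphic founder panel.

    Allele indicators are Bernoulli draws with marker-specific frequencies;
    markers monomorphic across founders are redrawn so every marker
    segregates.  Deterministic for a fixed seed.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders for polymorphic markers")
    if n_chrom < 2 or markers_per_chrom < 2:
        raise ValueError("need at least 2 chromosomes and 2 markers per chromosome")
    rng = substream(seed, "founders")
    m = n_chrom * markers_per_chrom
    if chrom_length_bp is None:
        chrom_length_bp = 150_000_000  # maize-like 150 cM at 1 cM/Mb
    chrom = np.repeat(np.arange(1, n_chrom + 1), markers_per_chrom)

    def _positions():
        got = np.array([], dtype=np.int64)
        while got.size < markers_per_chrom:
            got = np.unique(np.r_[got, rng.integers(1, chrom_length_bp + 1, markers_per_chrom)])
        return np.sort(rng.choice(got, size=markers_per_chrom, replace=False))

    pos = np.concatenate([_positions() for _ in range(n_chrom)])
    freq = rng.uniform(0.1, 0.9, size=m)
    alleles = (rng.random((n_founders, m)) < freq).astype(np.int8)
    mono = (alleles.sum(axis=0) == 0) | (alleles.sum(axis=0) == n_founders)
    guard = 0
    while mono.any():
        alleles[:, mono] = (rng.random((n_founders, mono.sum())) < freq[mono]).astype(np.int8)
        mono = (alleles.sum(axis=0) == 0) | (alleles.sum(axis=0) == n_founders)
        guard += 1
        if guard > 1000:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not generate polymorphic markers")
    panel = FounderPanel(chrom=chrom, pos=pos, alleles=alleles)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# DH mosaics


def _mosaic_chromosome(rng, length_bp: float, mean_block_bp: float, n_founders: int):
    """Tile one chromosome with exponential blocks, distinct successive founders."""
    blocks = []
    start = 0.0
    founder = int(rng.integers(n_founders))
    while start < length_bp:
        if np.isinf(mean_block_bp):
            blocks.append((0.0, float(length_bp), founder))
            return blocks
        ln = rng.exponential(mean_block_bp)
        end = min(start + ln, length_bp)
        blocks.append((start, end, founder))
        start = end
        if n_founders > 1:
            nxt = int(rng.integers(n_founders - 1))
            founder = nxt if nxt < founder else nxt + 1
    return blocks


def simulate_dh_lines(
    panel: FounderPanel,
    n_lines: int = 344,
    expected_block_cM: float = 30.0,
    seed: int = 0,
) -> DHPopulation:
    """Generate DH lines as founder mosaics over the panel.

    Block lengths are exponential with mean ``expected_block_cM`` (1 cM per
    Mb); successive founders within a chromosome differ, so realized block
    lengths are exactly exponential.  Founder probabilities are one-hot.
    The population is resampled (fresh substream) until every founder is
    represented somewhere in the population.
    """
    if expected_block_cM <= 0:
        raise ValueError("expected_block_cM must be positive")
    nf = panel.n_founders
    mean_bp = expected_block_cM * BP_PER_CM
    chroms = panel.chromosomes
    lengths = {c: panel.pos[panel.chrom == c].max() + 1.0 for c in chroms}

    for attempt in range(100):
        rng = substream(seed, "dh", attempt)
        mosaics = []
        geno = np.empty((n_lines, panel.n_markers), dtype=np.int8)
        anc = np.empty((n_lines, panel.n_markers), dtype=np.int16)
        for l in range(n_lines):
            per_chrom = {}
            for c in chroms:
                per_chrom[c] = _mosaic_chromosome(rng, lengths[c], mean_bp, nf)
            mosaics.append(per_chrom)
            for c in chroms:
                mask = panel.chrom == c
                p = panel.pos[mask]
                founders_here = np.empty(p.size, dtype=np.int16)
                for s, e, f in per_chrom[c]:
                    sel = (p >= s) & (p < e)
                    founders_here[sel] = f
                anc[l, mask] = founders_here
        if len(np.unique(anc)) == nf:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not represent every founder; increase n_lines")

    for l in range(n_lines):
        geno[l] = 2 * panel.alleles[anc[l], np.arange(panel.n_markers)]
    probs = np.zeros((panel.n_markers, n_lines, nf), dtype=np.float32)
    mi = np.arange(panel.n_markers)
    for l in range(n_lines):
        probs[mi, l, anc[l]] = 1.0
    pop = DHPopulation(
        panel=panel,
        lines=[f"L{i:04d}" for i in range(n_lines)],
        mosaics=mosaics,
        genotypes=geno.astype(np.int16) * 1,
        founder_probs=probs,
    )
    return pop


def blur_probabilities(pop: DHPopulation, concentration: float, seed: int = 0) -> DHPopulation:
    """Soften one-hot founder probabilities to emulate imputation uncertainty.

    Each (marker, line) slice is replaced by a Dirichlet draw with
    parameter ``concentration`` on the true founder and 1 elsewhere, so the
    expected mass on the true founder is (c + 1) / (c + n_founders) and
    decreases monotonically as the concentration drops.  For concentration
    above roughly n_founders the argmax is preserved with high probability;
    an infinite concentration returns the probabilities unchanged.
    """
    if not concentration > 0:
        raise ValueError("concentration must be positive")
    if np.isinf(concentration):
        return pop
    rng = substream(seed, "blur")
    m, r, nf = pop.founder_probs.shape
    alpha = np.ones((m, r, nf)) + concentration * pop.founder_probs
    g = rng.standard_gamma(alpha)
    probs = (g / g.sum(axis=2, keepdims=True)).astype(np.float32)
    return replace(pop, founder_probs=probs)


# ---------------------------------------------------------------------------
# field surfaces


def gaussian_field_surface(
    rows: int, cols: int, rng: np.random.Generator, n_bumps: int = 8
) -> np.ndarray:
    """Smooth random surface: sum of Gaussian bumps, centered to mean zero.

    Centering makes the surface orthogonal to the environment mean by
    construction; unit variance over the grid (degenerate surfaces rescaled
    from a tiny norm are avoided by redrawing).
    """
    yy, xx = np.meshgrid(np.arange(cols), np.arange(rows))
    surf = np.zeros((rows, cols))
    for _ in range(n_bumps):
        cx = rng.uniform(0, rows - 1)
        cy = rng.uniform(0, cols - 1)
        amp = rng.normal()
        width = rng.uniform(0.15, 0.4) * max(rows, cols)
        surf += amp * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width**2)))
    surf -= surf.mean()
    sd = surf.std()
    if sd < 1e-9:  # pragma: no cover - essentially impossible
        return gaussian_field_surface(rows, cols, rng, n_bumps)
    return surf / sd


# ---------------------------------------------------------------------------
# trial simulation


def _polygenic(
    rng, pop: DHPopulation, variance: float, markers: np.ndarray | None = None, mode: str = "markers"
) -> np.ndarray:
    """Polygenic line effects standardized to the target sample variance.

    ``mode="markers"`` builds effects from centered genotypes with i.i.d.
    marker weights, so line effects covary approximately with the genomic
    relationship matrix; restricting ``markers`` (e.g. to chromosomes not
    being scanned) gives a background independent of held-out test markers.
    ``mode="iid"`` draws exchangeable normal line effects — exactly the
    assumption of the plot-level variance-component model, with no
    genotype-induced correlation between separate draws.
    """
    r = pop.n_lines
    if variance == 0:
        return np.zeros(r)
    if mode == "iid":
        g = rng.normal(size=r)
        return (g - g.mean()) / g.std() * np.sqrt(variance)
    if mode != "markers":
        raise ValueError(f"unknown polygenic mode {mode!r}")
    geno = pop.genotypes if markers is None else pop.genotypes[:, markers]
    M = geno - geno.mean(axis=0)
    a = rng.normal(size=M.shape[1])
    g = M @ a
    sd = g.std()
    if sd < 1e-12:
        return np.zeros(r)
    return g / sd * np.sqrt(variance)


def _serpentine_coords(n_plots: int, rows: int, cols: int):
    """Assign plots to grid cells row by row, alternating direction."""
    coords = []
    for i in range(n_plots):
        rr = i // cols
        cc = i % cols
        if rr % 2 == 1:
            cc = cols - 1 - cc
        coords.append((rr, cc))
    return coords


def simulate_trial(
    pop: DHPopulation,
    design: TrialDesign,
    effects: EffectSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate plot-level phenotypes for a multi-environment trial.

    Each plot value is the sum of its environment mean, environment-specific
    QTL founder effects, a polygenic line main effect, a polygenic
    line-by-environment effect, the field surface value at the plot's
    coordinates, and an i.i.d. residual.  With ``effects.multitrait`` set,
    line-level trait vectors per environment are drawn with covariance G
    and plot residuals with covariance R instead of the univariate terms.

    Returns the long-format phenotype table (line, environment, plot, x, y,
    trait columns) and the realized ground truth.
    """
    env_ids = design.env_ids()
    nf = pop.panel.n_founders
    effects.validate(len(env_ids), nf)
    r = pop.n_lines
    rng_env = substream(seed, "env")
    rng_g = substream(seed, "polygenic")
    rng_field = substream(seed, "field")
    rng_e = substream(seed, "resid")

    # environment deviations standardized to the exact requested sample
    # variance (ddof=1, matching what REML estimates from few levels)
    if effects.v_e > 0 and len(env_ids) > 1:
        dev = rng_env.normal(size=len(env_ids))
        dev = dev - dev.mean()
        dev = dev / dev.std(ddof=1) * np.sqrt(effects.v_e)
    else:
        dev = np.zeros(len(env_ids))
    env_means = {e: design.environments[e] + dev[i] for i, e in enumerate(env_ids)}

    multitrait = effects.multitrait is not None
    if multitrait:
        t = np.asarray(next(iter(effects.multitrait.values()))["G"]).shape[0]
        trait_cols = [f"trait_{j + 1}" for j in range(t)]
    else:
        t = 1
        trait_cols = ["trait_1"]

    pm = effects.polygenic_markers
    pmode = effects.polygenic_mode
    g_main = None if multitrait else _polygenic(rng_g, pop, effects.v_g, pm, pmode)
    gxe = None
    if not multitrait:
        gxe = np.vstack([_polygenic(rng_g, pop, effects.v_gxe, pm, pmode) for _ in env_ids])

    qtl_vals = None
    if effects.qtl and not multitrait:
        qtl_vals = np.zeros((len(env_ids), r))
        for midx, eff in effects.qtl:
            eff = np.asarray(eff, dtype=float)
            slice_probs = pop.founder_probs[midx].astype(float)  # (r, nf)
            for ei in range(len(env_ids)):
                qtl_vals[ei] += slice_probs @ eff[ei]
    fw = effects.fw_slopes

    # field layout
    rows_out = []
    surfaces = {}
    U_by_env = {} if multitrait else None
    for ei, e in enumerate(env_ids):
        present = [l for l in range(r) if pop.lines[l] not in design.missing_lines.get(e, set())]
        n_plots = len(present) * design.plots_per_line
        if design.field_dims is None:
            cols = int(np.ceil(np.sqrt(n_plots)))
            rows_f = int(np.ceil(n_plots / cols))
        else:
            rows_f, cols = design.field_dims
            if rows_f * cols < n_plots:
                raise ValueError(f"field {rows_f}x{cols} too small for {n_plots} plots in {e}")
        surf = gaussian_field_surface(rows_f, cols, rng_field) * np.sqrt(effects.v_spline)
        surfaces[e] = surf

        if multitrait:
            G = np.asarray(effects.multitrait[e]["G"], dtype=float)
            R = np.asarray(effects.multitrait[e]["R"], dtype=float)
            U = rng_g.multivariate_normal(np.zeros(t), G, size=r, method="eigh")
            U_by_env[e] = U

        order = []
        for p_i in range(design.plots_per_line):
            order += [(l, p_i + 1) for l in present]
        coords = _serpentine_coords(len(order), rows_f, cols)
        for (l, plot_id), (x, y) in zip(order, coords):
            base = env_means[e] + surf[x, y]
            if multitrait:
                resid = rng_e.multivariate_normal(np.zeros(t), R, method="eigh")
                vals = base + U_by_env[e][l] + resid
            else:
                gval = g_main[l]
                if fw is not None:
                    gval = gval * fw[l] + (fw[l] - 1.0) * design.environments[e]
                v = base + gval + gxe[ei, l] + rng_e.normal(0, np.sqrt(effects.v_resid))
                if qtl_vals is not None:
                    v += qtl_vals[ei, l]
                vals = np.array([v])
            rows_out.append((pop.lines[l], e, plot_id, x, y, *vals))

    table = pd.DataFrame(rows_out, columns=["line", "environment", "plot", "x", "y", *trait_cols])
    truth = SimTruth(
        env_means=env_means,
        line_effects=g_main,
        gxe_effects=gxe,
        qtl_values=qtl_vals,
        field_surfaces=surfaces,
        multitrait_U=U_by_env,
    )
    return table, truth
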