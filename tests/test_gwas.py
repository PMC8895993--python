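"""GxE association scans: oracle equivalence, calibration, power, QC flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magicgxe import simulate as sim
from magicgxe.gwas import (
    DegenerateEnvironmentError,
    deviation_scan,
    founder_representation,
    fw_scan,
    fw_slopes,
    permutation_thresholds,
    plasticity_scan,
)

from conftest import model_consistent_table


def _chol(kin):
    return np.linalg.cholesky(kin.regularized())


# ---------------------------------------------------------------------------
# GLS oracle equivalence (dense full-covariance solve, pinv route)


def _gls_oracle_p(y, V, X0, Xnuis, Xtest):
    """Wald p for the tested block via explicit V^-1 and projections."""
    n = len(y)
    Vi = np.linalg.pinv(V)

    def rss_rank(X):
        XtVi = X.T @ Vi
        A = XtVi @ X
        beta = np.linalg.pinv(A) @ (XtVi @ y)
        r = y - X @ beta
        return r @ Vi @ r, np.linalg.matrix_rank(A)

    Xr = np.hstack([X0, Xnuis])
    Xf = np.hstack([X0, Xnuis, Xtest])
    r0, k0 = rss_rank(Xr)
    r1, k1 = rss_rank(Xf)
    df = k1 - k0
    if df == 0:
        return np.nan, 0
    s2 = r1 / (n - k1)
    return float(stats.chi2.sf((r0 - r1) / s2, df)), df


class TestGLSOracle:
    """Scan p-values equal a dense GLS solve at fixed variance components."""

    def test_deviation_scan(self, small_pop, small_panel):
        from magicgxe.genotypes import loco_kinship

        mm = small_panel.marker_map()
        K = {c: loco_kinship(small_pop.genotypes, mm, c, lines=small_pop.lines) for c in (1, 2)}
        design = sim.TrialDesign(environments={"A": 1.0, "B": -1.0}, plots_per_line=1)
        eff = sim.EffectSpec(v_g=0.5, v_gxe=0.3, v_resid=1.0)
        table, _ = sim.simulate_trial(small_pop, design, eff, seed=12)
        ratios = [0.5, 0.3, 0.2]
        scan = deviation_scan(
            table, small_pop, K, "trait_1", env_pair=("A", "B"), markers=np.arange(8), mode={"ratios": ratios}
        )
        lidx = np.array([small_pop.lines.index(l) for l in table["line"]])
        y = table["trait_1"].to_numpy(float)
        w = np.where(table["environment"].to_numpy() == "A", 1.0, -1.0)
        n = len(y)
        uniq, code = np.unique(lidx, return_inverse=True)
        Z = np.zeros((n, len(uniq)))
        Z[np.arange(n), code] = 1.0
        X0 = np.column_stack([np.ones(n), w])
        for mi in range(8):
            chrom = mm["chrom"].iloc[mi]
            Kc = K[chrom].regularized()[np.ix_(lidx, lidx)]
            V = np.eye(n) + ratios[0] * Kc + ratios[1] * (w[:, None] * Kc * w[None, :]) + ratios[2] * (Z @ Z.T)
            Xm = small_pop.founder_probs[mi][lidx].astype(float)
            p, df = _gls_oracle_p(y, V, X0, Xm, Xm * w[:, None])
            got = scan.results["p"].iloc[mi]
            assert scan.results["df"].iloc[mi] == df
            assert abs(np.log10(p) - np.log10(got)) < 1e-6

    def test_plasticity_scan(self, small_pop, small_panel):
        from magicgxe.genotypes import vanraden_kinship

        K = vanraden_kinship(small_pop.genotypes, lines=small_pop.lines)
        design = sim.TrialDesign(
            environments={"A": 1.0, "B": 0.0, "C": -1.0}, plots_per_line=1
        )
        eff = sim.EffectSpec(v_g=0.5, v_gxe=0.3, v_resid=1.0)
        table, _ = sim.simulate_trial(small_pop, design, eff, seed=13)
        ratios = [0.4, 0.2, 0.1]
        scan = plasticity_scan(table, small_pop, K, "trait_1", markers=np.arange(6), mode={"ratios": ratios})
        lidx = np.array([small_pop.lines.index(l) for l in table["line"]])
        y = table["trait_1"].to_numpy(float)
        env = table["environment"].to_numpy()
        means = table.groupby("environment")["trait_1"].mean()
        w = pd.Series(env).map(means).to_numpy()
        n = len(y)
        uniq, code = np.unique(lidx, return_inverse=True)
        Z = np.zeros((n, len(uniq)))
        Z[np.arange(n), code] = 1.0
        X0 = pd.get_dummies(pd.Series(env)).to_numpy(float)
        Kc = K.regularized()[np.ix_(lidx, lidx)]
        V = np.eye(n) + ratios[0] * Kc + ratios[1] * (w[:, None] * Kc * w[None, :]) + ratios[2] * (Z @ Z.T)
        for mi in range(6):
            Xm = small_pop.founder_probs[mi][lidx].astype(float)
            p, df = _gls_oracle_p(y, V, X0, Xm, Xm * w[:, None])
            got = scan.results["p"].iloc[mi]
            assert scan.results["df"].iloc[mi] == df
            assert abs(np.log10(p) - np.log10(got)) < 1e-6

    def test_fw_scan(self, small_pop, small_panel):
        from magicgxe.genotypes import vanraden_kinship

        K = vanraden_kinship(small_pop.genotypes, lines=small_pop.lines)
        rng = np.random.default_rng(3)
        s = pd.Series(rng.normal(1.0, 0.3, small_pop.n_lines), index=small_pop.lines)
        slopes_obj = fw_slopes(
            _slope_table(small_pop, s, rng), "trait_1", "trait_1"
        )
        ratios = [0.6]
        scan = fw_scan(slopes_obj, small_pop, K, markers=np.arange(6), mode={"ratios": ratios})
        sl = slopes_obj.slopes.dropna()
        lidx = np.array([small_pop.lines.index(l) for l in sl.index])
        y = sl.to_numpy(float)
        Kc = K.regularized()[np.ix_(lidx, lidx)]
        V = np.eye(len(y)) + ratios[0] * Kc
        X0 = np.ones((len(y), 1))
        for mi in range(6):
            Xm = small_pop.founder_probs[mi][lidx].astype(float)
            p, df = _gls_oracle_p(y, V, X0, np.zeros((len(y), 0)), Xm)
            got = scan.results["p"].iloc[mi]
            assert scan.results["df"].iloc[mi] == df
            assert abs(np.log10(p) - np.log10(got)) < 1e-6


def _slope_table(pop, slopes, rng, envs=(2.0, 1.0, 0.0, -1.0, -2.0), noise=0.15):
    """Balanced table whose per-line regressions recover the given slopes."""
    rows = []
    for ei, shift in enumerate(envs):
        for l, line in enumerate(pop.lines):
            val = slopes[line] * shift + rng.normal(0, noise)
            rows.append((line, f"E{ei}", 1, 0, 0, val))
    return pd.DataFrame(rows, columns=["line", "environment", "plot", "x", "y", "trait_1"])


# ---------------------------------------------------------------------------
# null calibration


class TestNullCalibration:
    def test_deviation_p_uniform(self, gwas_pop, gwas_kinship):
        pop = gwas_pop
        chr1 = np.flatnonzero(pop.panel.marker_map()["chrom"].to_numpy() == 1)
        Lk = _chol(gwas_kinship[1])
        rng = np.random.default_rng(42)
        table = model_consistent_table(pop, Lk, {"A": 1.0, "B": -1.0}, 0.5, 0.3, 0.2, 1.0, rng)
        scan = deviation_scan(
            table, pop, {1: gwas_kinship[1]}, "trait_1", env_pair=("A", "B"), markers=chr1, mode="null"
        )
        ks = stats.kstest(scan.results["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_plasticity_p_uniform(self, gwas_pop, gwas_kinship):
        pop = gwas_pop
        chr1 = np.flatnonzero(pop.panel.marker_map()["chrom"].to_numpy() == 1)
        Lk = _chol(gwas_kinship[1])
        rng = np.random.default_rng(43)
        env_w = {f"E{i}": w for i, w in enumerate([2.0, 1.0, 0.0, -1.0, -2.0])}
        table = model_consistent_table(pop, Lk, env_w, 0.5, 0.1, 0.2, 1.0, rng)
        scan = plasticity_scan(
            table, pop, {1: gwas_kinship[1]}, "trait_1", markers=chr1, mode="null", grid_step=0.2
        )
        ks = stats.kstest(scan.results["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_fw_p_uniform(self, gwas_pop, gwas_kinship):
        pop = gwas_pop
        chr1 = np.flatnonzero(pop.panel.marker_map()["chrom"].to_numpy() == 1)
        Lk = _chol(gwas_kinship[1])
        rng = np.random.default_rng(44)
        s = pd.Series(1.0 + Lk @ rng.normal(size=pop.n_lines) * 0.3 + rng.normal(size=pop.n_lines) * 0.2,
                      index=pop.lines)
        slopes = fw_slopes(_slope_table(pop, s, rng), "trait_1", "trait_1")
        scan = fw_scan(slopes, pop, {1: gwas_kinship[1]}, markers=chr1, mode="null")
        ks = stats.kstest(scan.results["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# degenerate and structural contracts


class TestContracts:
    def test_plasticity_equal_environment_means_aborts(self, small_pop):
        table = _slope_table(small_pop, pd.Series(0.0, index=small_pop.lines),
                             np.random.default_rng(0), envs=(0.0, 0.0, 0.0), noise=0.0)
        from magicgxe.genotypes import vanraden_kinship

        K = vanraden_kinship(small_pop.genotypes, lines=small_pop.lines)
        with pytest.raises(DegenerateEnvironmentError):
            plasticity_scan(table, small_pop, K, "trait_1", markers=np.arange(4))

    def test_permutation_preserves_environment_means(self, gwas_pop, gwas_kinship):
        pop = gwas_pop
        rng = np.random.default_rng(1)
        Lk = _chol(gwas_kinship[1])
        env_w = {f"E{i}": w for i, w in enumerate([1.0, 0.0, -1.0])}
        table = model_consistent_table(pop, Lk, env_w, 0.3, 0.1, 0.1, 1.0, rng)
        scan = plasticity_scan(
            table, pop, {1: gwas_kinship[1]}, "trait_1", markers=np.arange(4), mode="null", grid_step=0.25
        )
        prep = scan.prepared
        yp = prep.permuted_response(np.random.default_rng(2))
        env = prep.env
        for e in np.unique(env):
            assert np.isclose(yp[env == e].mean(), prep.y[env == e].mean())

    def test_rank_zero_interaction_flagged(self, small_pop):
        """A marker with identical probabilities for every line spans the
        intercept; its interaction block collapses and p is missing."""
        from dataclasses import replace

        from magicgxe.genotypes import vanraden_kinship

        probs = small_pop.founder_probs.copy()
        probs[0] = 1.0 / small_pop.panel.n_founders
        pop = replace(small_pop, founder_probs=probs)
        K = vanraden_kinship(pop.genotypes, lines=pop.lines)
        design = sim.TrialDesign(environments={"A": 0.5, "B": -0.5}, plots_per_line=1)
        table, _ = sim.simulate_trial(pop, design, sim.EffectSpec(v_resid=1.0), seed=3)
        scan = deviation_scan(
            table, pop, K, "trait_1", env_pair=("A", "B"), markers=np.arange(2), mode={"ratios": [0, 0, 0]}
        )
        assert np.isnan(scan.results["p"].iloc[0])
        assert "rank0_interaction" in scan.results["flags"].iloc[0]
        assert np.isfinite(scan.results["p"].iloc[1])

    def test_founder_column_order_irrelevant(self, small_pop):
        from dataclasses import replace

        from magicgxe.genotypes import vanraden_kinship

        K = vanraden_kinship(small_pop.genotypes, lines=small_pop.lines)
        design = sim.TrialDesign(environments={"A": 0.5, "B": -0.5}, plots_per_line=2)
        eff = sim.EffectSpec(v_g=0.5, v_gxe=0.5, v_resid=1.0)
        table, _ = sim.simulate_trial(small_pop, design, eff, seed=4)
        perm = np.random.default_rng(5).permutation(small_pop.panel.n_founders)
        pop2 = replace(small_pop, founder_probs=small_pop.founder_probs[:, :, perm])
        kw = dict(env_pair=("A", "B"), markers=np.arange(6), mode={"ratios": [0.3, 0.2, 0.1]})
        s1 = deviation_scan(table, small_pop, K, "trait_1", **kw)
        s2 = deviation_scan(table, pop2, K, "trait_1", **kw)
        np.testing.assert_allclose(s1.results["p"], s2.results["p"], rtol=1e-8)
        np.testing.assert_allclose(s1.beta_interaction[:, perm], s2.beta_interaction, atol=1e-8)

    def test_alpha_recovers_half_mean_deviation(self, gwas_pop, gwas_kinship):
        """The w coefficient equals half the simulated environment mean gap."""
        pop = gwas_pop
        Lk = _chol(gwas_kinship[1])
        rng = np.random.default_rng(6)
        table = model_consistent_table(pop, Lk, {"A": 1.0, "B": -1.0}, 0.4, 0.2, 0.1, 1.0, rng)
        scan = deviation_scan(
            table, pop, {1: gwas_kinship[1]}, "trait_1", env_pair=("A", "B"),
            markers=np.arange(3), mode="null",
        )
        ctx = next(iter(scan.prepared.contexts.values()))
        coef, *_ = np.linalg.lstsq(ctx.X0t, ctx.yt, rcond=None)
        cov = np.linalg.inv(ctx.X0t.T @ ctx.X0t)
        resid = ctx.yt - ctx.X0t @ coef
        se = np.sqrt(cov[1, 1] * (resid @ resid) / (len(ctx.yt) - 2))
        # generative mu_A - mu_B = 1.0, so alpha = 0.5
        assert abs(coef[1] - 0.5) < 3 * se


# ---------------------------------------------------------------------------
# Finlay-Wilkinson slopes


class TestFWSlopes:
    def test_population_mirror_line_has_slope_one(self, small_pop):
        rng = np.random.default_rng(0)
        s = pd.Series(1.0, index=small_pop.lines)
        table = _slope_table(small_pop, s, rng, noise=0.0)
        slopes = fw_slopes(table, "trait_1", "trait_1")
        np.testing.assert_allclose(slopes.slopes.to_numpy(), 1.0, atol=1e-10)

    def test_constant_line_has_slope_zero(self, small_pop):
        rng = np.random.default_rng(0)
        s = pd.Series(1.0, index=small_pop.lines)
        table = _slope_table(small_pop, s, rng, noise=0.0)
        table.loc[table.line == small_pop.lines[0], "trait_1"] = 7.0
        slopes = fw_slopes(table, "trait_1", "trait_1")
        assert slopes.slopes[small_pop.lines[0]] == pytest.approx(0.0, abs=1e-12)

    def test_mean_slope_identity_balanced(self, small_pop):
        """Balanced complete data, trait = index trait: mean slope is 1."""
        design = sim.TrialDesign(
            environments={f"E{i}": m for i, m in enumerate([2.0, 0.5, -0.5, -2.0])}, plots_per_line=2
        )
        eff = sim.EffectSpec(v_g=1.0, v_gxe=0.7, v_resid=0.8)
        table, _ = sim.simulate_trial(small_pop, design, eff, seed=15)
        slopes = fw_slopes(table, "trait_1", "trait_1")
        assert abs(slopes.slopes.mean() - 1.0) < 1e-10

    def test_line_in_single_environment_has_missing_slope(self, small_pop):
        rng = np.random.default_rng(0)
        s = pd.Series(1.0, index=small_pop.lines)
        table = _slope_table(small_pop, s, rng)
        drop = small_pop.lines[0]
        table = table[~((table.line == drop) & (table.environment != "E0"))]
        slopes = fw_slopes(table, "trait_1", "trait_1")
        assert np.isnan(slopes.slopes[drop])
        assert slopes.n_envs[drop] == 1


# ---------------------------------------------------------------------------
# permutation thresholds


class TestPermutationThresholds:
    def _null_scan(self, gwas_pop, gwas_kinship, seed=0):
        Lk = _chol(gwas_kinship[1])
        rng = np.random.default_rng(seed)
        table = model_consistent_table(
            gwas_pop, Lk, {"A": 1.0, "B": -1.0}, 0.5, 0.3, 0.2, 1.0, rng, plots=1
        )
        chr1 = np.flatnonzero(gwas_pop.panel.marker_map()["chrom"].to_numpy() == 1)[:30]
        return deviation_scan(
            table, gwas_pop, {1: gwas_kinship[1]}, "trait_1", env_pair=("A", "B"),
            markers=chr1, mode="null", grid_step=0.25,
        )

    def test_threshold_is_order_statistic(self, gwas_pop, gwas_kinship):
        scan = self._null_scan(gwas_pop, gwas_kinship)
        thr = permutation_thresholds(scan, n_perm=100, seed=1)
        minima = np.sort(thr["minima"])
        assert thr[0.05] == minima[4]  # 5th order statistic of 100 minima
        assert thr[0.10] == minima[9]
        assert thr[0.05] <= thr[0.10]

    def test_thresholds_deterministic(self, gwas_pop, gwas_kinship):
        scan = self._null_scan(gwas_pop, gwas_kinship)
        t1 = permutation_thresholds(scan, n_perm=25, seed=9)[0.05]
        scan2 = self._null_scan(gwas_pop, gwas_kinship)
        t2 = permutation_thresholds(scan2, n_perm=25, seed=9)[0.05]
        assert t1 == t2

    def test_too_few_permutations_rejected(self, gwas_pop, gwas_kinship):
        scan = self._null_scan(gwas_pop, gwas_kinship)
        with pytest.raises(ValueError):
            permutation_thresholds(scan, n_perm=10)


# ---------------------------------------------------------------------------
# power


@pytest.fixture(scope="module")
def power_pop():
    """8 founders x 200 lines: ~25 expected carriers per founder, so
    founder-specific effects are estimable; single plot per line keeps the
    within-environment permutation exchangeable at observation level."""
    from magicgxe.genotypes import loco_kinship

    panel = sim.simulate_founders(8, 2, 60, seed=55)
    pop = sim.simulate_dh_lines(panel, n_lines=200, expected_block_cM=1.0, seed=55)
    mm = panel.marker_map()
    K = {1: loco_kinship(pop.genotypes, mm, 1, lines=pop.lines)}
    chr1 = np.flatnonzero(mm["chrom"].to_numpy() == 1)[:30]
    return pop, K, chr1


class TestPower:
    def test_deviation_sign_flip_detected(self, power_pop):
        """A founder whose effect flips sign between environments (+-0.5
        phenotypic SD) gives median -log10 p above the permutation 5%
        threshold."""
        pop, K, chr1 = power_pop
        causal = chr1[10]
        Lk = _chol(K[1])
        Xm = pop.founder_probs[causal].astype(float)
        sd_pheno = np.sqrt(0.4 * 2 + 0.2 * 2 + 0.1 + 1.0)  # model variance at K diag ~ 2
        eff = 0.5 * sd_pheno
        beta = np.zeros((2, 8))
        beta[0, 0] = eff
        beta[1, 0] = -eff
        kwargs = dict(env_pair=("A", "B"), markers=chr1, mode="null", grid_step=0.25)
        pvals = []
        thr = None
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            table = model_consistent_table(
                pop, Lk, {"A": 1.0, "B": -1.0}, 0.4, 0.2, 0.1, 1.0, rng,
                plots=1, marker_effect=(Xm, beta),
            )
            scan = deviation_scan(table, pop, K, "trait_1", **kwargs)
            pos = scan.results.index[scan.results["marker"] == f"m{causal}"][0]
            pvals.append(scan.results["p"].iloc[pos])
            if rep == 0:
                thr = permutation_thresholds(scan, n_perm=100, seed=rep)[0.05]
        med = np.median(-np.log10(pvals))
        assert med > -np.log10(thr)

    def test_plasticity_slope_marker_is_top_hit(self, power_pop):
        """A founder-specific slope on environment quality makes its marker
        the genome-wide minimum p in at least 18 of 20 replicates."""
        pop, K, chr1 = power_pop
        causal = chr1[10]
        Lk = _chol(K[1])
        env_w = {f"E{i}": w for i, w in enumerate([2.0, 1.0, 0.0, -1.0, -2.0])}
        Xm = pop.founder_probs[causal].astype(float)
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            beta = np.array([[0.4 * w] + [0.0] * 7 for w in env_w.values()])
            table = model_consistent_table(
                pop, Lk, env_w, 0.3, 0.1, 0.1, 1.0, rng, plots=1, marker_effect=(Xm, beta)
            )
            scan = plasticity_scan(
                table, pop, K, "trait_1", markers=chr1, mode="null", grid_step=0.25
            )
            best = scan.results["p"].idxmin()
            if scan.results["marker"].iloc[best] == f"m{causal}":
                hits += 1
        assert hits >= 18

    def test_fw_slope_shift_detected(self):
        """A founder slope shift of +0.3 with ~50 expected carriers clears
        the permutation 5% threshold in at least 15 of 20 replicates."""
        from magicgxe.genotypes import loco_kinship

        panel = sim.simulate_founders(8, 2, 40, seed=77)
        pop = sim.simulate_dh_lines(panel, n_lines=400, expected_block_cM=1.0, seed=77)
        mm = panel.marker_map()
        chr1 = np.flatnonzero(mm["chrom"].to_numpy() == 1)[:25]
        causal = chr1[5]
        K = {1: loco_kinship(pop.genotypes, mm, 1, lines=pop.lines)}
        Lk = _chol(K[1])
        carriers = pop.founder_probs[causal, :, 0].astype(float)
        assert 30 < carriers.sum() < 70  # ~r/8 expected carriers
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            s_vals = 1.0 + 0.3 * carriers + Lk @ rng.normal(size=pop.n_lines) * 0.15 + rng.normal(size=pop.n_lines) * 0.1
            slopes = fw_slopes(_slope_table(pop, pd.Series(s_vals, index=pop.lines), rng), "trait_1", "trait_1")
            scan = fw_scan(slopes, pop, K, markers=chr1, mode="null")
            thr = permutation_thresholds(scan, n_perm=100, seed=rep)[0.05]
            pos = scan.results.index[scan.results["marker"] == f"m{causal}"][0]
            if scan.results["p"].iloc[pos] < thr:
                hits += 1
        assert hits >= 15


# ---------------------------------------------------------------------------
# founder representation QC


class TestFounderRepresentation:
    def test_one_hot_counts(self):
        probs = np.zeros((1, 10, 4))
        probs[0, :3, 1] = 1.0
        probs[0, 3:, 0] = 1.0
        rep = founder_representation(probs)
        assert rep["expected"][0, 1] == 3
        assert rep["hard"][0, 1] == 3

    def test_uniform_probabilities(self):
        probs = np.full((2, 320, 16), 1 / 16)
        rep = founder_representation(probs)
        np.testing.assert_allclose(rep["expected"], 20.0)
        assert (rep["hard"] == 0).all()
        assert not rep["flagged"].any()

    def test_single_carrier_artifact_flagged(self, small_pop):
        """A founder carried confidently by one line triggers the
        low-support flag on the scan, regardless of p-value."""
        from dataclasses import replace

        from magicgxe.genotypes import vanraden_kinship

        probs = small_pop.founder_probs.copy().astype(np.float32)
        # marker 0: founder 7 carried by exactly one line, others spread
        probs[0] = 0.0
        probs[0, :, 0] = 1.0
        probs[0, 5] = 0.0
        probs[0, 5, 7] = 1.0
        pop = replace(small_pop, founder_probs=probs)
        rep = founder_representation(probs[:1])
        assert rep["flagged"][0, 7]

        K = vanraden_kinship(pop.genotypes, lines=pop.lines)
        rng = np.random.default_rng(1)
        slopes = fw_slopes(
            _slope_table(pop, pd.Series(1.0, index=pop.lines), rng), "trait_1", "trait_1"
        )
        scan = fw_scan(slopes, pop, K, markers=np.arange(2), mode={"ratios": [0.2]})
        assert "low_founder_support" in scan.results["flags"].iloc[0]
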