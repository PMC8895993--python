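# magicgxe

Genotype-by-environment (G×E) interaction analysis for multiparent (MAGIC)
populations of fully homozygous lines phenotyped in replicated
multi-environment field trials — the setting of a 16-founder maize
doubled-haploid population grown as testcross hybrids across five
contrasting environments.

The package covers the full chain a quantitative geneticist needs for such
a study, with a synthetic-data generator providing known ground truth for
every stage:

- **simulate** — founder haplotypes, doubled-haploid mosaic genomes with
  exponential ancestry blocks, founder-probability markers, and
  plot-level multi-environment phenotypes with QTL, polygenic G and G×E,
  smooth field surfaces, and multivariate traits drawn from specified
  per-environment G and R matrices.
- **genotypes** — VanRaden genomic relationships
  K = MM′ / (2Σpⱼ(1−pⱼ)), greedy windowed LD pruning, and
  leave-one-chromosome-out (LOCO) kinship.
- **varcomp** — average-information REML for the plot-level model
  y = Z_G u_G + Z_E u_E + Z_{E:G} u_{E:G} + f_E(x,y) + e
  with a tensor-product spline field surface, and variance proportions.
- **gwas** — three G×E genome scans on founder-probability markers
  (environment-deviation, plasticity on environment quality, and
  Finlay–Wilkinson slope association), mixed-model correction with LOCO
  kinship, permutation family-wise thresholds, and
  founder-representation QC.
- **gmatrix** — Bayesian per-environment genetic variance–covariance
  matrices (Gibbs sampler; half-t priors on standard deviations via a
  hierarchical inverse-Wishart), mean-scaling, split-R̂/ESS diagnostics,
  and credible-interval tests for correlation differences between
  environments.
- **tensor** — eigenanalysis of the covariance tensor of the
  per-environment G-matrices: eigentensors, element contributions,
  environment coordinates, posterior uncertainty, and a
  shuffle-among-environments significance null.

The scientific background, estimation details, priors, and limitations are
documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a small MAGIC trial, partition variance for one trait, and
compare G-matrices across environments:

```python
import numpy as np
from magicgxe import simulate as sim
from magicgxe.varcomp import build_design, fit_reml, variance_proportions

panel = sim.simulate_founders(n_founders=16, n_chrom=2, markers_per_chrom=60, seed=5)
pop = sim.simulate_dh_lines(panel, n_lines=150, expected_block_cM=30, seed=5)
design = sim.TrialDesign(environments={f"env_{i}": 0.0 for i in range(5)},
                         plots_per_line=2)
effects = sim.EffectSpec(v_g=1.0, v_gxe=0.5, v_e=0.5, v_spline=0.3, v_resid=1.0)
table, truth = sim.simulate_trial(pop, design, effects, seed=6)

vc = fit_reml(build_design(table, "trait_1", knots=(4, 4)))
print({k: round(v, 3) for k, v in variance_proportions(vc).items() if k != "_included"})
```

```
{'G': 0.327, 'E': 0.149, 'GxE': 0.212, 'residual': 0.313}
```

The generative shares of the included components are
1.0/3.0 ≈ 0.33 (G), 0.5/3.0 ≈ 0.17 (E and G×E each), and 0.33 (residual):
the fit recovers the simulated architecture at 150 lines, with the G×E
and residual shares off by sampling noise of the expected size.

Eigentensor comparison of per-environment G-matrices:

```python
from magicgxe.gmatrix import fit_gmatrix, mean_scale
from magicgxe.tensor import build_tensor, element_contributions

G = np.array([[1.0, 0.6], [0.6, 0.8]])
envs = {f"env_{i}": 0.0 for i in range(3)}
mt = {e: {"G": G.copy(), "R": np.eye(2) * 0.7} for e in envs}
mt["env_0"]["G"][0, 0] *= 2.0          # one environment doubles a variance
eff = sim.EffectSpec(multitrait=mt)
table, _ = sim.simulate_trial(pop, sim.TrialDesign(environments=envs), eff, seed=7)

posts = [fit_gmatrix(table, environment=e, traits=["trait_1", "trait_2"],
                     chains=2, burnin=200, draws=400, seed=i, spline=False)
         for i, e in enumerate(envs)]
ct = build_tensor([p.median_G() for p in posts])
print("variance fractions:", np.round(ct.variance_fractions, 3))
print("top element of E1:", np.unravel_index(np.argmax(element_contributions(ct, 0)), (2, 2)))
```

```
variance fractions: [0.998 0.002 0.   ]
top element of E1: (0, 0)
```

Three environments give at most two nonzero eigentensors; the first one
absorbs essentially all variation among the G-matrices and points at the
perturbed (1,1) genetic variance.

A `gxe` command-line tool wraps the same functionality
(`gxe simulate`, `gxe kinship`, `gxe varcomp`, `gxe gwas`, `gxe gmatrix`,
`gxe tensor`); run `gxe --help` for options.

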