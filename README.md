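# mixproject

Deconvolution and projection of mixed RNA measurements onto per-cell-type
variational autoencoders trained on a single-cell atlas.

Many single-cell-resolution assays trade RNA precision for extra
modalities: spatial spots capture RNA from several adjacent cells,
patched-neuron extracts carry RNA from surrounding glia, and FISH panels
measure only a few dozen genes.  Given such imprecise measurements
`b_n` and a deeply sequenced single-cell atlas of the same cell types,
this package jointly estimates, for every sample and every atlas cell type
`k`:

* **alpha_{n,k}** — the fraction of RNA that type `k` contributed
  (deconvolution), and
* **x_{n,k}** — the type-`k` expression state inside the mixture
  (projection), constrained to the feasible cell states learned by a
  per-type variational autoencoder.

The model is `b_n = sum_k alpha_{n,k} x_{n,k}` with `alpha` on the simplex.
Estimation runs in three steps: (1) train one Gaussian VAE per atlas cell
type; (2) project each mixture through every VAE, initialize `alpha` by
nonnegative least squares and refine it by maximizing a Gaussian mixture
likelihood with a learned per-sample noise model; (3) freeze `alpha` and
re-optimize all VAEs jointly against the mixtures, with the atlas ELBO as a
regularizer.  An asymmetric mode (encoder reads a marker panel `G_e`,
decoder emits the full gene set `G`) imputes unmeasured genes.  Downstream
tools cover evaluation metrics (Spearman CC, RMSE, Jensen-Shannon distance,
FOSCTTM, SSIM, composite rank scores), spatial neighborhood-motif
permutation tests, k-NN label transfer, zonation scoring, Patch-seq
contamination scores, and a synthetic benchmark generator with known ground
truth.  Model details and conventions are in `docs/methods.md`.

## Worked example

Deconvolve 200 Dirichlet-weighted mixtures of four synthetic cell types
against a 1200-cell atlas (about half a minute on one CPU):

```python
import numpy as np, pandas as pd
from mixproject import simulate, prepare_inputs, deconvolve_pipeline, VAEConfig
from mixproject.deconvolve import AbundanceConfig, predict_cell_type

atlas = simulate.make_atlas(n_types=4, n_genes=300, cells_per_type=300,
                            separation=0.3, seed=7)
mixtures, truth = simulate.make_dirichlet_mixtures(atlas, n=200,
                                                   concentration=1.0, seed=7)
ann = pd.Series(atlas.cell_types, index=atlas.expr.obs_ids)
atlas_s, mixtures_s = prepare_inputs(atlas.expr, ann, mixtures.expr)

cfg = VAEConfig(latent_dim=10, hidden=(64, 32), epochs=200, seed=0)
res = deconvolve_pipeline(atlas_s, mixtures_s, cfg, AbundanceConfig(seed=0))

print(res.abundances.to_frame().head(3).round(3))
rmse = np.sqrt(np.mean((res.abundances.alpha - truth.alpha.values) ** 2))
baseline = np.sqrt(np.mean((0.25 - truth.alpha.values) ** 2))
print(f"alpha RMSE vs truth: {rmse:.3f} (equal-proportion baseline: {baseline:.3f})")
print(predict_cell_type(res.abundances).head(3))
```

prints

```
       type0  type1  type2  type3
dmix0  0.146  0.303  0.195  0.355
dmix1  0.002  0.428  0.000  0.569
dmix2  0.353  0.000  0.468  0.179
alpha RMSE vs truth: 0.096 (equal-proportion baseline: 0.188)
      cell_type  abundance    tie
dmix0     type3   0.355392  False
dmix1     type3   0.569456  False
dmix2     type2   0.468174  False
```

Each row of the abundance table is a mixture's estimated RNA-fraction
vector (rows sum to 1).  The RMSE against the generating fractions is about
half the error of guessing equal proportions; `predict_cell_type` labels
each sample with its dominant type.  Continuing with
`project_pipeline(...)` additionally returns refined per-type expression
profiles with sub-5%-abundance projections masked.

The same workflows are available from the shell:

```bash
mixproject simulate   --outdir out/sim --seed 7 --n-types 4
mixproject deconvolve --outdir out/dec --seed 0 \
    --atlas out/sim/atlas/matrix.mtx --annotations out/sim/annotations.csv \
    --mixtures out/sim/mixtures/matrix.mtx
mixproject motifs     --outdir out/motifs --coords coords.csv --n-perm 100000
```

Subcommands: `simulate`, `deconvolve`, `project`, `impute` (with `--logo`
for leave-one-gene-out benchmarking), `benchmark`, `motifs`.  Every output
directory contains a `manifest.json` (seed, configuration, hash) sufficient
to reproduce the run bit-identically.

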