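# Methods

## The model

A mixed RNA measurement (a spatial spot, a patched-neuron extract, a bulk
sample) is modeled as a weighted linear combination of per-cell-type
expression states:

    b_n = sum_k alpha_{n,k} x_{n,k},   alpha_{n,k} >= 0,  sum_k alpha_{n,k} = 1

where `b_n` is the observed mixture, `alpha_{n,k}` is the RNA fraction
contributed by cell type `k`, and `x_{n,k}` is the (unobserved) expression
state of type `k` inside mixture `n`.  Both `alpha` and `x` are estimated by
anchoring the `x_{n,k}` to generative models of each cell type fitted to a
deeply sequenced single-cell atlas.

Estimation proceeds in three steps.

**Step 1 — per-type variational autoencoders.**  For each atlas cell type
`k` a Gaussian VAE is trained on the atlas cells of that type: encoder
`q(z|s) = N(mu_phi(s), diag sigma2_phi(s))`, decoder
`p(s|z) = N(mu_theta(z), sigma2_theta(z) I)`.  The fitted decoder delimits
the set of feasible expression states for the type and, through the prior,
weighs states by how often they occur in the atlas.  Training maximizes the
ELBO (Gaussian reconstruction minus KL against `N(0, I)`) with Adam, a
decaying learning rate starting at 1e-3, and a linear warmup of the KL
weight from ~0 to 1 over the first quarter of training.  Regularization is
30% dropout on hidden layers plus L2 (1e-4).  The encoder variance is
diagonal over latent dimensions; the decoder variance is a single scalar
per observation, so each projection carries one predicted variance
`sigma2_{n,k}` (this matches the isotropic `sigma^2 I` decoder and keeps
the step-2 noise-model input a 2K-vector).  Batch normalization is not
used: at these layer widths on z-scored inputs it adds train/eval
statistics plumbing without measurable benefit, and dropout + L2 already
provide the regularization.

**Step 2 — projections and RNA fractions.**  Every mixture is projected
onto every type: `x^(0)_{n,k} = mu_theta_k(mu_phi_k(b_n))`, with predicted
variance `sigma2_{n,k} = sigma2_theta_k(mu_phi_k(b_n))`.  Fractions are
initialized by nonnegative least squares on the mixture equation
(duplicate projection columns share weight equally; the result is
renormalized to the simplex) and then refined by maximizing

    sum_n log N( b_n | sum_k x^(0)_{n,k} alpha_{n,k},
                 f_sigma(sigma2_{n,:} (+) alpha_{n,:}) I )

jointly over per-sample logits (`alpha = softmax(logits)`, so the simplex
constraint is structural) and the noise MLP `f_sigma` (two hidden layers of
width 32, softplus output, variance floor).  Optimization is Adam at 1e-3
until the relative objective change over 25 steps falls below 1e-5 (max
5000 steps).  The fitted `alpha` are frozen afterwards.

A property of this maximum-likelihood refinement worth knowing: the
projections `x^(0)_{n,k}` are functions of `b_n` and therefore carry
mixture-dependent bias; the likelihood optimum can sit at fractions
measurably different from the generating ones even when the linear
initialization is nearly unbiased.  Better-trained VAEs shrink this drift.
The acceptance script reports both the final and the linear-init RMSE so
the two stages can be compared.

**Step 3 — joint refinement.**  With `alpha` and `f_sigma` frozen, all K
VAEs are re-optimized together on a composite objective: the mixture
likelihood above (now a function of the VAE parameters), plus the atlas
ELBO of every type, minus the KL of the mixture posteriors.  The atlas
terms keep each VAE identifiable as one cell population.  A variant of
this objective adds the atlas KL with a positive sign where a standard
ELBO subtracts it; the default here is the standard subtractive form and
`RefineConfig(literal_kl_signs=True)` switches to the additive variant.
Because
mixtures are typically far fewer than atlas cells, the atlas terms are
weighted by N/J by default (`balance_terms=False` gives the literal
unweighted sum).  Final projections are
`x_{n,k} = mu_theta_k(mu_phi_k(b_n))` at the refined parameters.
Projections whose fraction falls below 5% (configurable) are masked —
flagged invalid but retained for audit.

**Imputation (asymmetric mode).**  For marker-panel assays the encoder
consumes only the measured subset `G_e` while the decoder emits the full
atlas panel `G`; steps 2-3 evaluate their likelihoods on `G_e` only, and
unmeasured genes are read off the decoder mean.  `leave_one_gene_out`
retrains the asymmetric VAEs once per held-out panel gene and scores the
imputed gene against its measurements (SCC, RMSE, JSD, and SSIM when
spatial coordinates allow rasterization).

## Preprocessing conventions

Counts are library-size normalized per observation to a fixed total
(default 10,000, i.e. TP10K), optionally log1p-transformed, then z-scored
per gene with the sample standard deviation (denominator n-1, so a gene row
[1,2,3] scales to [-1,0,1]); zero-variance genes map to zeros.  Mixtures
must be scaled with the *atlas'* per-gene statistics
(`scale_center(stats=...)`): a shared affine transform commutes with convex
combination, so the mixing equation survives standardization exactly,
which independent per-dataset scaling would destroy.  Relative counts
without log is the default for deconvolution (log1p breaks the linear
mixing relation); the log layer is used for the imputation benchmark,
where Gaussian likelihoods otherwise struggle with the heavy-tailed
coupled-gene factors.  Feature selection takes the union of supplied
markers with the top-2000 genes by variance (deterministic, ties broken by
gene order).

## Evaluation metrics

Per-sample projection metrics against the true contributing cell: mean
Spearman correlation (CC), mean per-item RMSE (`sqrt(||e||^2 / G)` per item,
then averaged), mean Jensen-Shannon distance (natural log, maximum
`sqrt(ln 2)`; vectors with negative entries are shifted by their minimum,
floored at 1e-12 and normalized), and FOSCTTM — for each item, the fraction
of other items whose prediction is closer (squared Euclidean) to the item's
truth than its own prediction; 0 is perfect, 0.5 is random.  SSIM uses the
reference scikit-image implementation on patterns rescaled to [0,1]
(7-pixel window, K1=0.01, K2=0.03).  Methods are compared by the mean of
their per-metric ranks (higher CC/SCC/SSIM better, lower RMSE/JSD/FOSCTTM
better, ties share the average rank).

## Spatial statistics

A cell's neighborhood type is its own label plus the counts of each type
among neighbors within 100 um (query excluded).  Counts are binned 0 / 1 /
2+ per type so the space of neighborhood types is finite; this binning is
one of several defensible discretizations (exact counts or mere presence
would also work) and is the package's documented choice.
The motif test permutes labels within layers (layer composition is
preserved under the null), recomputes neighborhood-type counts per
permutation, and reports `p = (1 + #{perm >= obs}) / (1 + n_perm)` — never
zero, resolution `1/(n_perm+1)`.  A neighborhood type is significant iff
`p < 5e-8` and at least 50 cells carry it (both configurable).

k-NN label transfer takes the majority vote among the k nearest atlas cells
in the shared (projected) feature space; vote ties resolve to the closest
tied neighbor's label.

Zonation scoring normalizes each gene's zone profile to sum 1 (scale
invariance) and measures the Euclidean distance to the nearest one-hot
ideal, e.g. (1,0,0,0,0) for a zone-1 gene over five villus zones.  Smaller
distance = more zone-specific; genes in the top quartile of specificity
(distance below the 25th percentile) are flagged zonated by default; the
quantile and the flagging direction are exposed as parameters
(`quantile=`, `direction=`).

## The synthetic-data generator

`make_atlas` draws counts from a negative-binomial hierarchy: a log-normal
baseline program shared by all types (`program_sd` controls skew), a
fraction `separation` of genes up-regulated `fold`-fold per type, log-normal
library sizes, and gamma-Poisson sampling with per-gene dispersion.
Optional features: coupled gene pairs sharing a mean-one log-normal
per-cell factor (within-type co-expression for imputation benchmarks) and
blended "sibling" type pairs for missing-type experiments.  Pseudo-bulk
mixtures sum one sampled cell per contributing type, with true fractions
defined as the contributing cells' library-size shares; Dirichlet mixtures
take convex combinations of unit-library profiles with known weights.
Spatial tissues place cells uniformly within layer bands and plant motif
instances inside discs of diameter < radius, with instance centers kept
2.2 radii apart so planted neighborhoods stay distinct.  Zonation fixtures
mix near-one-hot and flat zone profiles.

What the generator does *not* emulate: gene-regulatory correlation
structure beyond the explicit coupled pairs, batch effects, ambient RNA,
zero-inflation beyond NB sampling, realistic spatial point-process
clustering, or platform-specific noise.  Passing benchmarks here
demonstrates that the estimation machinery recovers planted structure
under the stated noise model — not performance on any particular real
assay.

## Problem sizes and numerical choices

The test suite and acceptance script run scaled-down configurations chosen
as this package's own benchmark design: hidden layers (64,32) or (48,24),
latent 8-10, 100-400 epochs, atlases of 2-4 types x 200-300 genes x
250-300 cells (the production defaults remain (128,64)/latent 16/dropout
0.30).  Scaled runs use a learning rate of 3e-3 where the 0.99/epoch decay
would otherwise shrink 1e-3 below a useful step size within a few hundred
epochs.  Variance heads are softplus with a 1e-4 floor to keep Gaussian
likelihoods finite; all arithmetic is float64, single-threaded numpy, so
fixed seeds give bit-identical runs.  Degenerate inputs are handled
explicitly: zero-total observations are rejected by name, zero-variance
genes scale to zeros, all-zero projection designs fall back to uniform
fractions with a warning, zero-expression genes are unscorable in zonation,
and exact abundance ties resolve to the first label in canonical order with
a tie flag.

## Known limitations

Gaussian likelihoods on normalized data (no NB/ZINB decoder, no batch
covariates); a single scalar decoder variance per observation; step-2
maximum likelihood can drift from the linear-init fractions when
projections are biased (see above); deconvolution of two nearly balanced,
strongly anti-correlated types from z-scored data is intrinsically
ill-conditioned; the motif test's binned neighborhood types are one of
several defensible discretizations; absolute cell counts per spot and
spatial smoothing priors are out of scope.
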