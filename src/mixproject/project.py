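"""Joint refinement of the per-type VAEs against mixtures (step 3),
low-abundance filtering, and the marker-panel imputation workflow.

With the RNA fractions alpha and the noise model frozen, all K VAEs are
re-optimized together on a composite objective: the Gaussian likelihood of
each mixture under the weighted sum of its per-type projections, plus the
atlas ELBO of every type (reconstruction minus KL), minus the KL of the
mixture posteriors.  The atlas terms act as a regularizer keeping each VAE
identifiable as one cell population while the mixture term pulls the
projections toward explaining the observed mixtures.

Some formulations of this composite objective add the atlas KL with a
positive sign where a standard ELBO subtracts it; the default here is the
standard subtractive form, and ``literal_kl_signs=True`` switches to the
additive variant (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import value_and_grad

from ._nnet import Adam, l2_penalty, make_dropout_masks
from .datatypes import (
    AbundanceMatrix,
    CellAtlas,
    GenePanel,
    MixtureSet,
    ProjectionTensor,
)
from .deconvolve import (
    MixtureNoiseModel,
    _measured_index,
    _mixture_matrix,
    _noise_forward,
    estimate_abundances,
    init_abundances_linear,
    initial_projections,
)
from .vae import VAEBundle, _decode_fn, _encode_fn


@dataclass
class RefineConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    lr_decay: float = 0.99
    patience: int = 10  # early stopping on the composite objective
    balance_terms: bool = True  # weight atlas terms by N/J so neither dominates
    literal_kl_signs: bool = False  # additive variant: atlas KL added, not subtracted
    seed: int = 0


def _composite_loss(
    trees: dict,
    b: np.ndarray,
    midx: np.ndarray,
    alpha: np.ndarray,
    noise_tree: dict,
    atlas_by_type: dict,
    eps_by_type: dict,
    labels: list,
    floor: float,
    noise_floor: float,
    w_atlas: float,
    literal_kl: bool,
    l2: float,
):
    """Negative composite ELBO (to minimize), autograd-differentiable."""
    n = b.shape[0]
    # mixture projections under current parameters
    xs, sigma2_cols, kl_mix = [], [], 0.0
    for lab in labels:
        tree = trees[lab]
        mu_z, var_z = _encode_fn(tree, b, floor)
        mu_x, var_x = _decode_fn(tree, mu_z, floor)
        xs.append(mu_x[:, midx])
        sigma2_cols.append(var_x)  # (n, 1)
        kl_mix = kl_mix + 0.5 * anp.sum(var_z + mu_z**2 - 1.0 - anp.log(var_z))
    x_stack = anp.stack(xs, axis=1)  # n x K x |G_e|
    mix_mean = anp.einsum("nk,nkg->ng", alpha, x_stack)
    sigma2 = anp.concatenate(sigma2_cols, axis=1)  # n x K
    feats = anp.concatenate([sigma2, alpha], axis=1)
    var_b = _noise_forward(noise_tree, feats, noise_floor)  # (n, 1), frozen weights
    ll_mix = -0.5 * anp.sum(anp.log(2 * anp.pi * var_b) + (b - mix_mean) ** 2 / var_b)

    # atlas terms: sampled-z reconstruction and KL per type
    recon_atlas, kl_atlas = 0.0, 0.0
    for lab in labels:
        s_in, s_tgt = atlas_by_type[lab]
        tree = trees[lab]
        mu_z, var_z = _encode_fn(tree, s_in, floor)
        z = mu_z + anp.sqrt(var_z) * eps_by_type[lab]
        mu_x, var_x = _decode_fn(tree, z, floor)
        recon_atlas = recon_atlas - 0.5 * anp.sum(
            anp.log(2 * anp.pi * var_x) + (s_tgt - mu_x) ** 2 / var_x
        )
        kl_atlas = kl_atlas + 0.5 * anp.sum(var_z + mu_z**2 - 1.0 - anp.log(var_z))

    kl_atlas_signed = kl_atlas if literal_kl else -kl_atlas
    elbo = ll_mix - kl_mix + w_atlas * (recon_atlas + kl_atlas_signed)
    scale = n * len(midx)
    return -elbo / scale + l2 * l2_penalty(trees)


def mixture_log_likelihood(
    bundle: VAEBundle,
    mixtures: MixtureSet,
    ab: AbundanceMatrix,
    noise: MixtureNoiseModel,
) -> float:
    """The mixture reconstruction term of the composite objective, evaluated
    at the bundle's current parameters (useful for before/after comparisons)."""
    proj = initial_projections(bundle, mixtures)
    midx = _measured_index(proj, mixtures)
    b = mixtures.expr.values.T
    mean = np.einsum("nk,nkg->ng", ab.alpha, proj.x[:, :, midx])
    var = noise.predict(proj.var, ab.alpha)[:, None]
    return float(-0.5 * np.sum(np.log(2 * np.pi * var) + (b - mean) ** 2 / var))


def refine_projections(
    bundle: VAEBundle,
    mixtures: MixtureSet,
    atlas: CellAtlas,
    ab: AbundanceMatrix,
    noise: MixtureNoiseModel,
    config: RefineConfig | None = None,
) -> tuple[VAEBundle, ProjectionTensor]:
    """Jointly re-optimize all K VAEs with alpha and the noise model frozen.

    Returns the refined bundle (the input bundle is not modified) and the
    refined projections x_nk = mu_theta(mu_phi(b_n)) at the new parameters.
    With ``epochs=0`` the output equals ``initial_projections`` exactly.
    """
    config = config or RefineConfig()
    refined = bundle.copy()
    if config.epochs > 0:
        b = _mixture_matrix(bundle, mixtures)
        proj0 = initial_projections(bundle, mixtures)
        midx = _measured_index(proj0, mixtures)
        alpha = ab.alpha
        if list(ab.labels) != bundle.labels:
            raise ValueError("abundance labels do not match bundle labels")

        full = atlas.expr.subset_genes(bundle.panel.full_genes)
        x_full = full.values.T
        x_meas = x_full[:, bundle.panel.measured_indices]
        atlas_by_type = {
            lab: (x_meas[atlas.cells_of_type(lab)], x_full[atlas.cells_of_type(lab)])
            for lab in bundle.labels
        }
        n_atlas = sum(v[0].shape[0] for v in atlas_by_type.values())
        w_atlas = (b.shape[0] / n_atlas) if config.balance_terms else 1.0

        floor = bundle.config.variance_floor
        noise_tree = {"layers": noise.layers, "head": noise.head}
        rng = np.random.default_rng(config.seed)
        trees = {lab: refined[lab].tree for lab in refined.labels}
        opt = Adam(trees, lr=config.learning_rate)
        vag = value_and_grad(
            lambda t, eps: _composite_loss(
                t, b, midx, alpha, noise_tree, atlas_by_type, eps,
                bundle.labels, floor, noise.variance_floor, w_atlas,
                config.literal_kl_signs, bundle.config.l2,
            )
        )
        best_val, best_x, stall = np.inf, opt.x.copy(), 0
        for epoch in range(config.epochs):
            eps_by_type = {
                lab: rng.standard_normal(
                    (atlas_by_type[lab][0].shape[0], bundle.config.latent_dim)
                )
                for lab in bundle.labels
            }
            val, grads = vag(opt.params, eps_by_type)
            val = float(val)
            if not np.isfinite(val):
                warnings.warn(
                    f"non-finite refinement loss at epoch {epoch}; "
                    "keeping last good parameters"
                )
                break
            if val < best_val - 1e-9:
                best_val, best_x, stall = val, opt.x.copy(), 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
            opt.step(grads, lr=config.learning_rate * config.lr_decay**epoch)
        final = opt.unflatten(best_x)
        for lab in refined.labels:
            refined[lab].tree = final[lab]

    proj = initial_projections(refined, mixtures)
    return refined, ProjectionTensor(
        x=proj.x, var=proj.var, labels=proj.labels, sample_ids=proj.sample_ids,
        gene_ids=proj.gene_ids, stage="refined",
    )


def filter_low_abundance(
    proj: ProjectionTensor, ab: AbundanceMatrix, threshold: float = 0.05
) -> ProjectionTensor:
    """Mask projections whose predicted fraction falls below ``threshold``
    (default 5%).  Masked entries are flagged invalid but retained for audit."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if list(ab.labels) != list(proj.labels) or list(ab.sample_ids) != list(proj.sample_ids):
        raise ValueError("projections and abundances are not aligned")
    mask = ab.alpha >= threshold
    return ProjectionTensor(
        x=proj.x, var=proj.var, labels=list(proj.labels),
        sample_ids=list(proj.sample_ids), gene_ids=list(proj.gene_ids),
        stage=proj.stage, mask=mask,
    )


def weighted_reconstruction(proj: ProjectionTensor, ab: AbundanceMatrix) -> np.ndarray:
    """Model reconstruction of each mixture: sum_k alpha_nk x_nk (N x G)."""
    return np.einsum("nk,nkg->ng", ab.alpha, proj.x)


def impute_genes(
    bundle_asym: VAEBundle,
    mixtures_on_panel: MixtureSet,
    ab: AbundanceMatrix | None = None,
) -> ProjectionTensor:
    """Project marker-panel mixtures through an asymmetric bundle to obtain
    full-panel profiles; unmeasured genes come from the decoder mean."""
    if bundle_asym.panel.is_symmetric:
        raise ValueError("impute_genes requires an asymmetric bundle (G_e < G)")
    missing = set(mixtures_on_panel.expr.gene_ids) - set(bundle_asym.panel.measured_genes)
    if missing:
        raise ValueError(f"mixture genes outside the bundle's panel: {sorted(missing)[:5]}")
    proj = initial_projections(bundle_asym, mixtures_on_panel)
    if ab is not None:
        if list(ab.sample_ids) != list(proj.sample_ids):
            raise ValueError("abundances not aligned with mixtures")
    return proj


# ---------------------------------------------------------------------------
# Leave-one-gene-out imputation benchmark
# ---------------------------------------------------------------------------

def score_gene(
    pred: np.ndarray,
    truth: np.ndarray,
    coords: Optional[pd.DataFrame] = None,
    grid: int = 16,
) -> dict:
    """Per-gene imputation scores across samples: SCC, RMSE, JSD and — when
    spatial coordinates are available — SSIM of the rasterized patterns."""
    from . import metrics as _metrics

    out = {
        "scc": _metrics.spearman(pred, truth),
        "rmse": _metrics.rmse(pred[None, :], truth[None, :]),
        "jsd": _metrics.jsd(pred[None, :], truth[None, :]),
    }
    if coords is not None:
        img_p = _metrics.rasterize(coords, pred, grid)
        img_t = _metrics.rasterize(coords, truth, grid)
        out["ssim"] = _metrics.ssim(img_p, img_t)
    else:
        out["ssim"] = np.nan
    return out


def leave_one_gene_out(
    bundle_factory: Callable[[GenePanel], VAEBundle],
    spatial: MixtureSet,
    atlas: CellAtlas,
    refine_abundances: bool = False,
    grid: int = 16,
) -> pd.DataFrame:
    """Hold out each panel gene in turn, retrain the asymmetric VAEs on the
    remaining genes, impute the held-out gene and score it.

    ``bundle_factory(panel)`` must return a *trained* bundle for the given
    asymmetric panel (this is where callers pick reduced epochs for speed).
    The imputed value per sample is the abundance-weighted reconstruction
    sum_k alpha_nk x_nk at the held-out gene.
    """
    panel_genes = list(spatial.expr.gene_ids)
    if len(panel_genes) < 2:
        raise ValueError("leave-one-gene-out needs at least 2 panel genes")
    full_genes = list(spatial.panel.full_genes)
    rows = []
    for gene in panel_genes:
        kept = [g for g in panel_genes if g != gene]
        panel = GenePanel(full_genes, kept)
        bundle = bundle_factory(panel)
        sub = MixtureSet(
            expr=spatial.expr.subset_genes(kept), panel=panel, coords=spatial.coords
        )
        proj = impute_genes(bundle, sub)
        ab = init_abundances_linear(sub, proj)
        if refine_abundances:
            ab, _ = estimate_abundances(sub, proj, ab)
        recon = weighted_reconstruction(proj, ab)  # N x |G|
        gidx = full_genes.index(gene)
        pred = recon[:, gidx]
        truth = spatial.expr.values[panel_genes.index(gene), :]
        coords = None
        if spatial.coords is not None:
            coords = spatial.coords.loc[spatial.expr.obs_ids]
        row = score_gene(pred, truth, coords, grid=grid)
        row["gene"] = gene
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
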