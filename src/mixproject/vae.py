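"""Per-cell-type variational autoencoders (training step 1).

One Gaussian VAE is trained per cell type on the atlas cells of that type.
Each VAE delimits the set of feasible expression states for its type: the
encoder q(z|s) = N(mu_phi(s), diag sigma2_phi(s)) maps an expression profile
to a latent code, the decoder p(s|z) = N(mu_theta(z), sigma2_theta(z) I)
maps codes back to expression space with a single predicted observation
variance per profile.  Training maximizes the ELBO (Gaussian reconstruction
minus KL against a standard-normal prior) with Adam, a decaying learning
rate and a smooth linear warmup of the KL weight.

In asymmetric (imputation) mode the encoder consumes only the measured
marker subset G_e while the decoder emits the full panel G, so decoding
yields estimates for unmeasured genes.

Models run on a normalized or z-scored expression layer; raw counts are
never modeled as Gaussian.
"""

from __future__ import annotations

import copy
import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import value_and_grad

from ._nnet import (
    Adam,
    gaussian_logpdf_sum,
    init_mlp,
    kl_standard_normal,
    l2_penalty,
    linear_forward,
    make_dropout_masks,
    mlp_forward,
    relu,
    softplus,
)
from .datatypes import CellAtlas, GenePanel


@dataclass
class VAEConfig:
    """Architecture and optimizer settings shared by the K per-type models."""

    latent_dim: int = 16
    hidden: tuple = (128, 64)
    dropout: float = 0.30
    l2: float = 1e-4
    learning_rate: float = 1e-3
    lr_decay: float = 0.99  # exponential, per epoch
    epochs: int = 100
    batch_size: int = 128
    kl_warmup_frac: float = 0.25  # linear 0 -> 1 over this fraction of epochs
    variance_floor: float = 1e-4
    min_cells: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if any(h < self.latent_dim for h in self.hidden):
            raise ValueError("hidden sizes must be >= latent_dim")

    def kl_weight(self, epoch: int) -> float:
        """KL warmup weight for a given epoch: ~0 at epoch 0, 1 after warmup."""
        warmup = max(1, int(np.ceil(self.kl_warmup_frac * self.epochs)))
        if self.kl_warmup_frac <= 0:
            return 1.0
        return min(1.0, (epoch + 1) / warmup)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pure functions over the parameter pytree (autograd-differentiable)
# ---------------------------------------------------------------------------

def _encode_fn(tree, x, floor, enc_masks=None):
    h = mlp_forward(tree["enc_body"], x, relu, enc_masks)
    mu = linear_forward(tree["enc_mu"], h)
    var = softplus(linear_forward(tree["enc_var"], h)) + floor
    return mu, var


def _decode_fn(tree, z, floor, dec_masks=None):
    h = mlp_forward(tree["dec_body"], z, relu, dec_masks)
    mu = linear_forward(tree["dec_mu"], h)
    var = softplus(linear_forward(tree["dec_var"], h)) + floor  # (n, 1) isotropic
    return mu, var


class VAEParams:
    """Encoder/decoder parameters for one cell type."""

    def __init__(self, tree: dict, panel: GenePanel, config: VAEConfig):
        self.tree = tree
        self.panel = panel
        self.config = config
        self.trained = False

    # -- inference-mode forward passes (deterministic) ----------------------

    @property
    def input_dim(self) -> int:
        return self.tree["enc_body"][0]["W"].shape[0]

    @property
    def output_dim(self) -> int:
        return self.tree["dec_mu"]["W"].shape[1]

    def encode(self, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and diagonal variance of the latent code.

        ``obs`` is (n, |G_e|) or a single profile of width |G_e|.
        """
        x = np.atleast_2d(np.asarray(obs, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"observation width {x.shape[1]} != encoder width {self.input_dim}"
            )
        mu, var = _encode_fn(self.tree, x, self.config.variance_floor)
        return np.asarray(mu), np.asarray(var)

    def decode(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Decoder mean over the full panel and scalar per-observation variance."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent width {z.shape[1]} != latent_dim {self.config.latent_dim}"
            )
        mu, var = _decode_fn(self.tree, z, self.config.variance_floor)
        return np.asarray(mu), np.asarray(var)[:, 0]

    def reconstruct(self, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """decode(encode-mean): the projection map mu_theta(mu_phi(.))."""
        mu_z, _ = self.encode(obs)
        return self.decode(mu_z)


def build_vae(panel: GenePanel, config: VAEConfig, seed: Optional[int] = None) -> VAEParams:
    """Randomly initialized VAE for one cell type; deterministic given seed."""
    if not panel.measured_genes:
        raise ValueError("encoder gene panel is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d_in = len(panel.measured_genes)
    d_out = len(panel.full_genes)
    d = config.latent_dim
    hidden = list(config.hidden)
    enc_sizes = [d_in] + hidden
    dec_sizes = [d] + hidden[::-1]
    tree = {
        "enc_body": init_mlp(enc_sizes, rng),
        "enc_mu": init_mlp([enc_sizes[-1], d], rng)[0],
        "enc_var": init_mlp([enc_sizes[-1], d], rng)[0],
        "dec_body": init_mlp(dec_sizes, rng),
        "dec_mu": init_mlp([dec_sizes[-1], d_out], rng)[0],
        "dec_var": init_mlp([dec_sizes[-1], 1], rng)[0],
    }
    return VAEParams(tree, panel, config)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _elbo_components(tree, x_in, x_target, floor):
    """Deterministic (posterior-mean) per-cell ELBO pieces, numpy only."""
    mu_z, var_z = _encode_fn(tree, x_in, floor)
    mu_x, var_x = _decode_fn(tree, mu_z, floor)
    resid = x_target - mu_x
    recon = -0.5 * np.sum(
        np.log(2 * np.pi) + np.log(var_x) + resid**2 / var_x, axis=1
    )
    kl = 0.5 * np.sum(var_z + mu_z**2 - 1.0 - np.log(var_z), axis=1)
    return recon, kl


def train_vae(
    x_in: np.ndarray,
    x_target: np.ndarray,
    panel: GenePanel,
    config: VAEConfig,
    seed: int,
) -> tuple[VAEParams, pd.DataFrame]:
    """Train a single per-type VAE on cells x genes matrices.

    ``x_in`` is (J, |G_e|) encoder input, ``x_target`` (J, |G|) decoder target
    (identical in symmetric mode).  Returns trained params and per-epoch
    history (elbo, recon, kl, kl_weight, lr).
    """
    model = build_vae(panel, config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA1]))
    floor = config.variance_floor
    n = x_in.shape[0]
    opt = Adam(model.tree, lr=config.learning_rate)
    records = []

    def batch_loss(tree, xb_in, xb_tgt, eps, kl_w, enc_masks, dec_masks):
        mu_z, var_z = _encode_fn(tree, xb_in, floor, enc_masks)
        z = mu_z + anp.sqrt(var_z) * eps
        mu_x, var_x = _decode_fn(tree, z, floor, dec_masks)
        recon = gaussian_logpdf_sum(xb_tgt, mu_x, var_x)
        kl = kl_standard_normal(mu_z, var_z)
        return -(recon - kl_w * kl) / xb_in.shape[0] + config.l2 * l2_penalty(tree)

    vag = value_and_grad(batch_loss)
    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay**epoch
        kl_w = config.kl_weight(epoch)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            enc_masks = make_dropout_masks(
                opt.params["enc_body"], len(idx), config.dropout, rng
            )
            dec_masks = make_dropout_masks(
                opt.params["dec_body"], len(idx), config.dropout, rng
            )
            val, grads = vag(
                opt.params, x_in[idx], x_target[idx], eps, kl_w, enc_masks, dec_masks
            )
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite VAE loss at epoch {epoch}, batch offset {start}"
                )
            opt.step(grads, lr=lr)
        recon, kl = _elbo_components(opt.params, x_in, x_target, floor)
        records.append(
            {
                "epoch": epoch,
                "elbo": float(np.mean(recon - kl)),
                "recon": float(np.mean(recon)),
                "kl": float(np.mean(kl)),
                "kl_weight": kl_w,
                "lr": lr,
            }
        )
    model.tree = opt.params
    model.trained = True
    return model, pd.DataFrame(records)


@dataclass
class VAEBundle:
    """K trained per-type VAEs sharing one architecture and gene panel."""

    models: dict[str, VAEParams]
    panel: GenePanel
    config: VAEConfig
    history: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted(self.models)

    def __getitem__(self, label: str) -> VAEParams:
        return self.models[label]

    def copy(self) -> "VAEBundle":
        return VAEBundle(
            models={
                lab: _copy_params(m) for lab, m in self.models.items()
            },
            panel=self.panel,
            config=self.config,
            history=dict(self.history),
        )

    # -- checkpointing ------------------------------------------------------

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "labels": self.labels,
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "full_genes": self.panel.full_genes,
            "measured_genes": self.panel.measured_genes,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
        for lab, model in self.models.items():
            flat = _tree_to_flat_dict(model.tree)
            np.savez(outdir / f"vae_{_safe(lab)}.npz", **flat)

    @classmethod
    def load(cls, indir) -> "VAEBundle":
        indir = Path(indir)
        manifest = json.loads((indir / "manifest.json").read_text())
        cfg_d = manifest["config"]
        cfg_d["hidden"] = tuple(cfg_d["hidden"])
        config = VAEConfig(**cfg_d)
        panel = GenePanel(manifest["full_genes"], manifest["measured_genes"])
        models = {}
        for lab in manifest["labels"]:
            data = np.load(indir / f"vae_{_safe(lab)}.npz")
            model = build_vae(panel, config)
            model.tree = _flat_dict_to_tree(data, model.tree)
            model.trained = True
            models[lab] = model
        return cls(models=models, panel=panel, config=config)


def _copy_params(m: VAEParams) -> VAEParams:
    clone = VAEParams(copy.deepcopy(m.tree), m.panel, m.config)
    clone.trained = m.trained
    return clone


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label)


def _tree_to_flat_dict(tree: dict) -> dict[str, np.ndarray]:
    flat = {}
    for key, val in tree.items():
        if isinstance(val, list):
            for i, layer in enumerate(val):
                flat[f"{key}.{i}.W"] = layer["W"]
                flat[f"{key}.{i}.b"] = layer["b"]
        else:
            flat[f"{key}.W"] = val["W"]
            flat[f"{key}.b"] = val["b"]
    return flat


def _flat_dict_to_tree(data, template: dict) -> dict:
    tree = {}
    for key, val in template.items():
        if isinstance(val, list):
            tree[key] = [
                {"W": data[f"{key}.{i}.W"], "b": data[f"{key}.{i}.b"]}
                for i in range(len(val))
            ]
        else:
            tree[key] = {"W": data[f"{key}.W"], "b": data[f"{key}.b"]}
    return tree


def train_atlas_vaes(
    atlas: CellAtlas,
    config: VAEConfig,
    panel: Optional[GenePanel] = None,
) -> VAEBundle:
    """Train one VAE per atlas cell type (step 1).

    The atlas must be on a normalized or scaled layer.  With an asymmetric
    ``panel`` the encoder reads only ``panel.measured_genes`` while targets
    cover ``panel.full_genes``.  Per-type seeds derive deterministically from
    ``config.seed``.
    """
    if atlas.expr.layer_tag == "counts":
        raise ValueError("train on a normalized/scaled layer, not raw counts")
    if panel is None:
        panel = GenePanel.symmetric(atlas.expr.gene_ids)
    full = atlas.expr.subset_genes(panel.full_genes)
    x_full = full.values.T  # cells x genes
    x_meas = x_full[:, panel.measured_indices]

    counts = atlas.counts_per_type()
    for lab, cnt in counts.items():
        if cnt < config.min_cells:
            raise ValueError(
                f"cell type {lab!r} has {cnt} cells < min_cells={config.min_cells}"
            )

    models, history = {}, {}
    for i, lab in enumerate(atlas.labels):
        idx = atlas.cells_of_type(lab)
        seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        model, hist = train_vae(x_meas[idx], x_full[idx], panel, config, seed=seed)
        models[lab] = model
        history[lab] = hist
    return VAEBundle(models=models, panel=panel, config=config, history=history)


def sample_log_likelihood(params: VAEParams, obs: np.ndarray) -> np.ndarray:
    """ELBO-style lower bound (reconstruction - KL) per observation.

    Evaluated deterministically at the posterior mean, so repeat calls give
    identical values and scores are comparable across cell types for a fixed
    observation.  ``obs``: (n, |G|) rows on the model's expression layer;
    in asymmetric mode only the measured columns are consumed by the encoder
    while the likelihood is evaluated on the full decoded panel.
    """
    if not params.trained:
        raise ValueError("sample_log_likelihood requires a trained model")
    x = np.atleast_2d(np.asarray(obs, dtype=float))
    if x.shape[1] != params.output_dim:
        raise ValueError(
            f"observation width {x.shape[1]} != decoder width {params.output_dim}"
        )
    x_in = x[:, params.panel.measured_indices] if not params.panel.is_symmetric else x
    recon, kl = _elbo_components(params.tree, x_in, x, params.config.variance_floor)
    return recon - kl
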