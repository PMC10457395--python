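"""RNA-fraction estimation (step 2).

Each mixture b_n is first projected onto every per-type VAE to obtain
initial profiles x_nk = mu_theta_k(mu_phi_k(b_n)) with predicted variances.
Fractions alpha are initialized by nonnegative least squares on
b_n ~ sum_k alpha_nk x_nk and then refined by maximizing the Gaussian
mixture likelihood

    L = sum_n log N( b_n | sum_k x_nk alpha_nk, f_sigma(sigma2_n (+) alpha_n) I )

jointly over per-sample simplex fractions (softmax of free logits) and the
small noise MLP f_sigma that maps the concatenated per-type decoder
variances and fractions to one observation variance per sample.  The fitted
alpha are frozen for the rest of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
import pandas as pd
import scipy.optimize

from ._nnet import init_mlp, linear_forward, minimize_adam, mlp_forward, relu, softplus
from .datatypes import AbundanceMatrix, MixtureSet, ProjectionTensor
from .vae import VAEBundle, sample_log_likelihood


@dataclass
class MixtureNoiseModel:
    """MLP f_sigma: (sigma2_{n,:} (+) alpha_{n,:}) -> per-sample variance."""

    layers: list  # hidden dense layers
    head: dict  # final dense layer -> 1 output
    variance_floor: float = 1e-4

    def predict(self, sigma2: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        feats = np.concatenate([sigma2, alpha], axis=1)
        return np.asarray(_noise_forward(
            {"layers": self.layers, "head": self.head}, feats, self.variance_floor
        ))[:, 0]


def _noise_forward(tree, feats, floor):
    h = mlp_forward(tree["layers"], feats, relu)
    return softplus(linear_forward(tree["head"], h)) + floor


def _mixture_matrix(bundle: VAEBundle, mixtures: MixtureSet) -> np.ndarray:
    """(N, |G_e|) samples-by-genes matrix, validating gene order strictly."""
    if mixtures.expr.gene_ids != bundle.panel.measured_genes:
        raise ValueError(
            "mixture gene order does not match the bundle's encoder panel; "
            "restrict/reorder the mixtures explicitly before projecting"
        )
    return mixtures.expr.values.T


def initial_projections(bundle: VAEBundle, mixtures: MixtureSet) -> ProjectionTensor:
    """Project every mixture onto every per-type VAE (deterministic)."""
    b = _mixture_matrix(bundle, mixtures)
    labels = bundle.labels
    n, k, g = b.shape[0], len(labels), len(bundle.panel.full_genes)
    x = np.empty((n, k, g))
    var = np.empty((n, k))
    for j, lab in enumerate(labels):
        model = bundle[lab]
        if not model.trained:
            raise ValueError(f"VAE for type {lab!r} is untrained")
        mu, v = model.reconstruct(b)
        x[:, j, :] = mu
        var[:, j] = v
    return ProjectionTensor(
        x=x, var=var, labels=labels, sample_ids=list(mixtures.expr.obs_ids),
        gene_ids=list(bundle.panel.full_genes), stage="initial",
    )


def init_abundances_linear(
    mixtures: MixtureSet, proj: ProjectionTensor
) -> AbundanceMatrix:
    """Nonnegative least squares per sample, renormalized to the simplex.

    Duplicate projection columns share their weight equally (so K identical
    projections give the uniform distribution); an all-zero design falls back
    to uniform fractions with a warning.
    """
    if proj.stage != "initial":
        raise ValueError("linear initialization expects initial-stage projections")
    b = mixtures.expr.values.T  # N x |G_e|
    midx = _measured_index(proj, mixtures)
    n, k = proj.x.shape[0], len(proj.labels)
    alpha = np.empty((n, k))
    for i in range(n):
        design = proj.x[i][:, midx].T  # |G_e| x K
        alpha[i] = _nnls_simplex(design, b[i], proj.sample_ids[i])
    return AbundanceMatrix(
        alpha=alpha, labels=list(proj.labels), sample_ids=list(proj.sample_ids)
    )


def _measured_index(proj: ProjectionTensor, mixtures: MixtureSet) -> np.ndarray:
    index = {g: i for i, g in enumerate(proj.gene_ids)}
    missing = [g for g in mixtures.expr.gene_ids if g not in index]
    if missing:
        raise ValueError(f"mixture genes absent from projections: {missing[:5]}")
    return np.array([index[g] for g in mixtures.expr.gene_ids])


def _nnls_simplex(design: np.ndarray, target: np.ndarray, sample_id: str) -> np.ndarray:
    k = design.shape[1]
    if not design.any():
        warnings.warn(f"all-zero projections for sample {sample_id}; uniform fallback")
        return np.full(k, 1.0 / k)
    # group duplicate columns so exact ties share weight symmetrically
    groups: list[list[int]] = []
    for j in range(k):
        for grp in groups:
            if np.array_equal(design[:, j], design[:, grp[0]]):
                grp.append(j)
                break
        else:
            groups.append([j])
    reduced = np.column_stack([design[:, grp[0]] for grp in groups])
    w, _ = scipy.optimize.nnls(reduced, target)
    if w.sum() <= 0:
        warnings.warn(f"degenerate NNLS fit for sample {sample_id}; uniform fallback")
        return np.full(k, 1.0 / k)
    alpha = np.zeros(k)
    for grp, weight in zip(groups, w):
        for j in grp:
            alpha[j] = weight / len(grp)
    return alpha / alpha.sum()


@dataclass
class AbundanceConfig:
    learning_rate: float = 1e-3
    max_steps: int = 5000
    rel_tol: float = 1e-5
    patience: int = 25
    noise_hidden: tuple = (32, 32)
    variance_floor: float = 1e-4
    seed: int = 0


def estimate_abundances(
    mixtures: MixtureSet,
    proj: ProjectionTensor,
    alpha_init: AbundanceMatrix,
    config: AbundanceConfig | None = None,
    bundle: VAEBundle | None = None,
) -> tuple[AbundanceMatrix, MixtureNoiseModel]:
    """Maximize the mixture likelihood over alpha (softmax logits) and the
    noise MLP, holding the projections fixed.

    Passing ``bundle`` additionally fills per-type ELBO diagnostics and the
    margin-based confidence score.
    """
    config = config or AbundanceConfig()
    b = mixtures.expr.values.T
    midx = _measured_index(proj, mixtures)
    x = proj.x[:, :, midx]  # N x K x |G_e|, fixed
    sigma2 = proj.var  # N x K
    n, k = sigma2.shape
    g = b.shape[1]

    rng = np.random.default_rng(config.seed)
    sizes = [2 * k, *config.noise_hidden]
    layers = init_mlp(sizes, rng)
    head = init_mlp([sizes[-1], 1], rng)[0]
    logits0 = np.log(np.maximum(alpha_init.alpha, 1e-6))
    params = {"logits": logits0, "noise": {"layers": layers, "head": head}}

    def negloglik(p):
        z = p["logits"] - anp.max(p["logits"], axis=1, keepdims=True)
        alpha = anp.exp(z) / anp.sum(anp.exp(z), axis=1, keepdims=True)
        mean = anp.einsum("nk,nkg->ng", alpha, x)
        feats = anp.concatenate([sigma2, alpha], axis=1)
        var = _noise_forward(p["noise"], feats, config.variance_floor)  # (n, 1)
        ll = -0.5 * anp.sum(
            anp.log(2 * anp.pi * var) + (b - mean) ** 2 / var
        )
        return -ll / (n * g)

    best, history, converged = minimize_adam(
        negloglik, params, lr=config.learning_rate, max_steps=config.max_steps,
        rel_tol=config.rel_tol, patience=config.patience,
    )
    if not converged:
        warnings.warn("abundance optimization hit max_steps before convergence")

    z = best["logits"] - best["logits"].max(axis=1, keepdims=True)
    alpha = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)

    loglik = conf = None
    if bundle is not None:
        loglik = per_type_log_likelihood(bundle, mixtures)
        conf = confidence_from_loglik(loglik)
    ab = AbundanceMatrix(
        alpha=alpha, labels=list(proj.labels), sample_ids=list(proj.sample_ids),
        per_sample_loglik=loglik, confidence=conf, converged=converged,
    )
    ab.opt_history = history  # negative mean log-likelihood per Adam step
    noise = MixtureNoiseModel(
        layers=best["noise"]["layers"], head=best["noise"]["head"],
        variance_floor=config.variance_floor,
    )
    return ab, noise


def per_type_log_likelihood(bundle: VAEBundle, mixtures: MixtureSet) -> np.ndarray:
    """N x K ELBO lower bounds of each mixture under each type's VAE."""
    b = _mixture_matrix(bundle, mixtures)
    if not bundle.panel.is_symmetric:
        raise ValueError("per-type likelihood needs the full decoded panel")
    out = np.column_stack(
        [sample_log_likelihood(bundle[lab], b) for lab in bundle.labels]
    )
    return out


def confidence_from_loglik(loglik: np.ndarray) -> np.ndarray:
    """Margin between best and second-best type after softmax normalization.

    A documented stand-in for a per-sample assignment confidence: 0 when two
    types explain the sample equally well, -> 1 when one dominates.
    """
    shifted = loglik - loglik.max(axis=1, keepdims=True)
    p = np.exp(shifted)
    p /= p.sum(axis=1, keepdims=True)
    part = np.sort(p, axis=1)
    return part[:, -1] - part[:, -2]


def predict_cell_type(ab: AbundanceMatrix) -> pd.DataFrame:
    """Assign each sample the type with maximal fraction.

    Exact ties resolve to the first label in canonical order and set the
    ``tie`` flag.
    """
    best = np.argmax(ab.alpha, axis=1)  # first max wins (canonical label order)
    maxval = ab.alpha[np.arange(len(best)), best]
    tie = (np.abs(ab.alpha - maxval[:, None]) < 1e-12).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "cell_type": [ab.labels[j] for j in best],
            "abundance": maxval,
            "tie": tie,
        },
        index=ab.sample_ids,
    )


def contamination_score(ab: AbundanceMatrix, contaminant_types) -> pd.Series:
    """Summed fraction of contaminant types per sample (e.g. non-neuronal
    RNA in patched-neuron measurements); in [0, 1]."""
    contaminants = list(contaminant_types)
    unknown = [c for c in contaminants if c not in ab.labels]
    if unknown:
        raise KeyError(f"unknown cell types: {unknown}")
    cols = [ab.labels.index(c) for c in contaminants]
    score = ab.alpha[:, cols].sum(axis=1) if cols else np.zeros(len(ab.sample_ids))
    return pd.Series(np.clip(score, 0.0, 1.0), index=ab.sample_ids, name="contamination")
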