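"""End-to-end workflows chaining preprocessing, the three training steps and
filtering — the programmatic counterparts of the command-line subcommands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import preprocess
from .datatypes import (
    AbundanceMatrix,
    CellAtlas,
    ExpressionMatrix,
    GenePanel,
    MixtureSet,
    ProjectionTensor,
)
from .deconvolve import (
    AbundanceConfig,
    MixtureNoiseModel,
    estimate_abundances,
    init_abundances_linear,
    initial_projections,
)
from .project import RefineConfig, filter_low_abundance, refine_projections
from .vae import VAEBundle, VAEConfig, train_atlas_vaes


def prepare_inputs(
    atlas_counts: ExpressionMatrix,
    annotations: pd.Series,
    mixture_counts: ExpressionMatrix,
    normalization: str = "rc",
    scale_factor: float = 10_000.0,
    n_hvg: Optional[int] = None,
    markers: Sequence[str] = (),
    measured_genes: Optional[Sequence[str]] = None,
) -> tuple[CellAtlas, MixtureSet]:
    """Normalize atlas and mixtures identically and bring both to the scaled
    layer, using the atlas' per-gene statistics for the mixtures so the two
    live in the same standardized space.

    ``normalization``: 'rc' (relative counts, no log — the default for
    mixture modeling, preserving the linear mixing relation) or 'log'
    (log1p of relative counts).  ``measured_genes`` restricts the mixture
    panel for asymmetric/imputation runs.
    """
    if normalization not in ("rc", "log"):
        raise ValueError("normalization must be 'rc' or 'log'")
    log = normalization == "log"

    missing = set(atlas_counts.obs_ids) - set(annotations.index.astype(str))
    if missing:
        raise ValueError(f"annotations missing for atlas cells: {sorted(missing)[:5]}")
    labels = [str(annotations[c]) for c in atlas_counts.obs_ids]

    atlas_norm = preprocess.normalize_library_size(atlas_counts, scale_factor, log)
    if n_hvg is not None or markers:
        panel = preprocess.select_features(
            atlas_norm, markers, n_hvg or min(2000, atlas_norm.n_genes)
        )
        genes = panel.full_genes
    else:
        genes = list(atlas_counts.gene_ids)
    shared = [g for g in genes if g in set(mixture_counts.gene_ids)]
    if not shared:
        raise ValueError("atlas and mixtures share no genes after selection")

    atlas_norm = atlas_norm.subset_genes(shared)
    atlas_scaled = preprocess.scale_center(atlas_norm)
    # mixtures: same normalization, scaled with the atlas' gene statistics
    stats = preprocess.gene_standardization_stats(atlas_norm)
    mix_norm = preprocess.normalize_library_size(mixture_counts, scale_factor, log)
    measured = list(measured_genes) if measured_genes is not None else shared
    bad = [g for g in measured if g not in shared]
    if bad:
        raise ValueError(f"measured genes absent from the shared panel: {bad[:5]}")
    mix_norm = mix_norm.subset_genes(measured)
    mix_scaled = preprocess.scale_center(mix_norm, stats=stats)

    atlas = CellAtlas(expr=atlas_scaled, cell_types=labels)
    panel = GenePanel(shared, measured)
    mixtures = MixtureSet(expr=mix_scaled, panel=panel)
    return atlas, mixtures


@dataclass
class DeconvolutionResult:
    bundle: VAEBundle
    projections: ProjectionTensor
    abundances: AbundanceMatrix
    noise: MixtureNoiseModel


def deconvolve_pipeline(
    atlas: CellAtlas,
    mixtures: MixtureSet,
    vae_config: Optional[VAEConfig] = None,
    abundance_config: Optional[AbundanceConfig] = None,
) -> DeconvolutionResult:
    """Steps 1-2: train per-type VAEs, project, estimate RNA fractions."""
    vae_config = vae_config or VAEConfig()
    bundle = train_atlas_vaes(atlas, vae_config, panel=mixtures.panel)
    proj = initial_projections(bundle, mixtures)
    alpha0 = init_abundances_linear(mixtures, proj)
    diag_bundle = bundle if mixtures.panel.is_symmetric else None
    ab, noise = estimate_abundances(
        mixtures, proj, alpha0, config=abundance_config, bundle=diag_bundle
    )
    return DeconvolutionResult(bundle, proj, ab, noise)


@dataclass
class ProjectionResult(DeconvolutionResult):
    refined_bundle: VAEBundle = None
    refined: ProjectionTensor = None
    filtered: ProjectionTensor = None


def project_pipeline(
    atlas: CellAtlas,
    mixtures: MixtureSet,
    vae_config: Optional[VAEConfig] = None,
    abundance_config: Optional[AbundanceConfig] = None,
    refine_config: Optional[RefineConfig] = None,
    abundance_threshold: float = 0.05,
) -> ProjectionResult:
    """Full pipeline (steps 1-3) plus low-abundance filtering."""
    dec = deconvolve_pipeline(atlas, mixtures, vae_config, abundance_config)
    refined_bundle, refined = refine_projections(
        dec.bundle, mixtures, atlas, dec.abundances, dec.noise,
        refine_config or RefineConfig(),
    )
    filtered = filter_low_abundance(refined, dec.abundances, abundance_threshold)
    return ProjectionResult(
        bundle=dec.bundle, projections=dec.projections, abundances=dec.abundances,
        noise=dec.noise, refined_bundle=refined_bundle, refined=refined,
        filtered=filtered,
    )
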