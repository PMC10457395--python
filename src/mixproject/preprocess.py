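"""Normalization, scaling and feature selection applied to atlas and mixtures.

Conventions (documented so tests are exact):

* library-size normalization rescales each observation (column) to a fixed
  total (relative counts, e.g. TP10K), optionally followed by natural log1p;
* z-scoring is per gene with the sample standard deviation (denominator
  n - 1, the convention of the standard single-cell toolkits, so a gene row
  [1, 2, 3] maps to [-1, 0, 1]); zero-variance genes map to all-zeros;
* highly variable genes are ranked by per-gene variance of the (normalized)
  matrix — deterministic and seed-free.

Mixtures must be brought to the same layer as the atlas before modeling.
Because every observation is scaled with the same per-gene affine transform
and the mixing weights sum to one, z-scoring preserves the linear mixture
relation exactly; use :func:`scale_center` with the atlas' ``stats`` on the
mixture matrix for that.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenePanel


def normalize_library_size(
    m: ExpressionMatrix,
    scale_factor: float = 10_000.0,
    log_transform: bool = False,
) -> ExpressionMatrix:
    """Relative-counts normalization: each column rescaled to ``scale_factor``.

    With ``log_transform`` the result is natural log1p of the rescaled values
    (log-normalized layer); without it, the relative-counts layer.
    """
    if m.layer_tag != "counts":
        raise ValueError(f"normalize_library_size expects counts layer, got {m.layer_tag!r}")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if np.any(m.values < 0):
        raise ValueError("negative entry in counts matrix")
    totals = m.values.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        names = [m.obs_ids[i] for i in zero[:5]]
        raise ValueError(f"zero-total observation(s): {names}")
    values = m.values / totals * scale_factor
    tag = "rc_normalized"
    if log_transform:
        values = np.log1p(values)
        tag = "log_normalized"
    return m.copy_with(values=values, layer_tag=tag)


def gene_standardization_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean and sample sd, for scaling another matrix consistently."""
    mean = m.values.mean(axis=1)
    ddof = 1 if m.n_obs > 1 else 0
    sd = m.values.std(axis=1, ddof=ddof)
    return pd.DataFrame({"mean": mean, "sd": sd}, index=m.gene_ids)


def scale_center(
    m: ExpressionMatrix, stats: Optional[pd.DataFrame] = None
) -> ExpressionMatrix:
    """Per-gene z-score across observations (sample sd, denominator n - 1).

    Genes with zero variance map to all-zeros.  Passing ``stats`` (from
    :func:`gene_standardization_stats` of a reference matrix) applies the
    reference's affine transform instead of the matrix's own — required when
    mixtures must live in the same standardized space as the atlas.
    """
    if m.layer_tag not in ("rc_normalized", "log_normalized"):
        raise ValueError(
            f"scale_center expects a normalized layer, got {m.layer_tag!r}"
        )
    if stats is None:
        stats = gene_standardization_stats(m)
    else:
        missing = [g for g in m.gene_ids if g not in stats.index]
        if missing:
            raise KeyError(f"stats missing genes: {missing[:5]}")
        stats = stats.loc[m.gene_ids]
    mean = stats["mean"].to_numpy()[:, None]
    sd = stats["sd"].to_numpy()[:, None]
    safe_sd = np.where(sd > 0, sd, 1.0)
    values = (m.values - mean) / safe_sd
    values[np.broadcast_to(sd == 0, values.shape)] = 0.0
    return m.copy_with(values=values, layer_tag="scaled")


def highly_variable_genes(m: ExpressionMatrix, n_hvg: int) -> list[str]:
    """Top ``n_hvg`` genes by variance, in the matrix's gene order.

    Ties are broken by gene order (stable), so the selection is deterministic.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    variances = m.values.var(axis=1)
    order = np.argsort(-variances, kind="stable")[: min(n_hvg, m.n_genes)]
    chosen = set(order.tolist())
    return [g for i, g in enumerate(m.gene_ids) if i in chosen]


def select_features(
    atlas: ExpressionMatrix, markers: Sequence[str] = (), n_hvg: int = 2000
) -> GenePanel:
    """Union of marker genes and the top-``n_hvg`` variable genes.

    Default ``n_hvg=2000`` follows common atlas practice.  The returned panel
    preserves atlas gene order and is symmetric (measured == full); restrict
    ``measured_genes`` afterwards for marker-panel imputation runs.
    """
    missing = [g for g in markers if g not in set(atlas.gene_ids)]
    if missing:
        raise KeyError(f"marker genes absent from atlas: {missing}")
    hvg = set(highly_variable_genes(atlas, n_hvg))
    keep = hvg | set(markers)
    genes = [g for g in atlas.gene_ids if g in keep]
    return GenePanel.symmetric(genes)
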