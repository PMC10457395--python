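"""Core in-memory containers shared across the pipeline.

All expression matrices are stored genes x observations (rows = genes), the
orientation used by most droplet-sequencing pipelines on disk.  ``layer_tag``
records which normalization stage the values are in, so downstream steps can
refuse inputs at the wrong stage instead of silently mis-modeling counts as
Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

LAYER_TAGS = ("counts", "rc_normalized", "log_normalized", "scaled")


@dataclass
class ExpressionMatrix:
    """Genes x observations numeric matrix with aligned identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x observations)")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise ValueError("obs_ids must be unique")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}; expected one of {LAYER_TAGS}")
        if self.layer_tag == "counts" and np.any(self.values < 0):
            raise ValueError("counts layer must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def copy_with(self, **kwargs) -> "ExpressionMatrix":
        return replace(self, **kwargs)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row subset in the requested gene order (no silent reordering elsewhere)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :], list(genes), list(self.obs_ids), self.layer_tag
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)


@dataclass
class GenePanel:
    """Full gene set G and the measured subset G_e used by asymmetric encoders."""

    full_genes: list[str]
    measured_genes: list[str]

    def __post_init__(self) -> None:
        self.full_genes = [str(g) for g in self.full_genes]
        self.measured_genes = [str(g) for g in self.measured_genes]
        if not self.full_genes or not self.measured_genes:
            raise ValueError("full_genes and measured_genes must be nonempty")
        full = set(self.full_genes)
        extra = [g for g in self.measured_genes if g not in full]
        if extra:
            raise ValueError(f"measured_genes not contained in full_genes: {extra}")

    @classmethod
    def symmetric(cls, genes: Sequence[str]) -> "GenePanel":
        return cls(list(genes), list(genes))

    @property
    def is_symmetric(self) -> bool:
        return self.full_genes == self.measured_genes

    @property
    def measured_indices(self) -> np.ndarray:
        """Positions of measured genes within the full panel order."""
        index = {g: i for i, g in enumerate(self.full_genes)}
        return np.array([index[g] for g in self.measured_genes], dtype=int)


@dataclass
class CellAtlas:
    """Reference atlas: expression plus a per-cell type label."""

    expr: ExpressionMatrix
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.cell_types = [str(c) for c in self.cell_types]
        if len(self.cell_types) != self.expr.n_obs:
            raise ValueError("one cell_type label required per atlas cell")

    @property
    def labels(self) -> list[str]:
        """Distinct cell-type labels in canonical (sorted) order."""
        return sorted(set(self.cell_types))

    @property
    def n_types(self) -> int:
        return len(self.labels)

    def cells_of_type(self, label: str) -> np.ndarray:
        mask = np.array([c == label for c in self.cell_types])
        if not mask.any():
            raise KeyError(f"no cells with label {label!r}")
        return np.where(mask)[0]

    def counts_per_type(self) -> dict[str, int]:
        return {lab: int(len(self.cells_of_type(lab))) for lab in self.labels}


@dataclass
class MixtureSet:
    """Mixed RNA samples b_n, optionally with spatial coordinates."""

    expr: ExpressionMatrix
    panel: GenePanel
    coords: Optional[pd.DataFrame] = None  # index = obs_ids; columns x, y[, layer]

    def __post_init__(self) -> None:
        if self.expr.gene_ids != self.panel.measured_genes:
            raise ValueError(
                "mixture expression rows must equal panel.measured_genes in order"
            )
        if self.coords is not None:
            missing = set(self.expr.obs_ids) - set(map(str, self.coords.index))
            if missing:
                raise ValueError(f"coords missing for samples: {sorted(missing)[:5]}")

    @property
    def n_samples(self) -> int:
        return self.expr.n_obs


@dataclass
class AbundanceMatrix:
    """Per-sample RNA fractions alpha (samples x cell types) on the simplex."""

    alpha: np.ndarray
    labels: list[str]
    sample_ids: list[str]
    per_sample_loglik: Optional[np.ndarray] = None  # N x K, ELBO-style
    confidence: Optional[np.ndarray] = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (len(self.sample_ids), len(self.labels)):
            raise ValueError("alpha must be samples x types")
        if np.any(self.alpha < -1e-9):
            raise ValueError("alpha entries must be nonnegative")
        sums = self.alpha.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("alpha rows must sum to 1 (tolerance 1e-6)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alpha, index=self.sample_ids, columns=self.labels)


@dataclass
class ProjectionTensor:
    """Projected profiles x[n, k, g] with per-(sample, type) predicted variances."""

    x: np.ndarray  # N x K x G
    var: np.ndarray  # N x K
    labels: list[str]
    sample_ids: list[str]
    gene_ids: list[str]
    stage: str = "initial"  # or "refined"
    mask: Optional[np.ndarray] = None  # N x K boolean; True = valid

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        n, k, g = len(self.sample_ids), len(self.labels), len(self.gene_ids)
        if self.x.shape != (n, k, g):
            raise ValueError(f"x must have shape {(n, k, g)}, got {self.x.shape}")
        if self.var.shape != (n, k):
            raise ValueError(f"var must have shape {(n, k)}, got {self.var.shape}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("projections must be finite")
        if np.any(self.var <= 0):
            raise ValueError("predicted variances must be positive")
        if self.stage not in ("initial", "refined"):
            raise ValueError("stage must be 'initial' or 'refined'")
        if self.mask is None:
            self.mask = np.ones((n, k), dtype=bool)

    def valid_x(self) -> np.ndarray:
        """Projections with masked entries replaced by NaN (audit copy kept in .x)."""
        out = self.x.copy()
        out[~self.mask, :] = np.nan
        return out
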