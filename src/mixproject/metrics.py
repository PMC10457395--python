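"""Evaluation metrics for projections and imputation, plus the composite
rank aggregation used to compare methods.

Projection metrics compare a predicted profile x_hat to the ground-truth
contributing cell s per sample: mean Spearman correlation (CC), mean
per-item RMSE, mean Jensen-Shannon distance (natural-log convention, so the
maximum is sqrt(ln 2)), and FOSCTTM — the fraction of other samples whose
prediction lies closer to a sample's truth than its own prediction does
(0 perfect, 0.5 random).  Imputation adds SSIM between rasterized spatial
patterns rescaled to [0, 1].

Expression vectors are converted to probability vectors for JSD by shifting
by the vector minimum when negative entries are present, flooring at 1e-12
and normalizing; nonnegative vectors are only rescaled.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
from skimage.metrics import structural_similarity

_EPS = 1e-12


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    rho = scipy.stats.spearmanr(a, b).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def cc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean Spearman rank correlation over items (rows)."""
    pred, truth = _as_2d_pair(pred, truth)
    return float(np.mean([spearman(p, t) for p, t in zip(pred, truth)]))


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean of per-item root-mean-square errors (per-item RMSE, then mean)."""
    pred, truth = _as_2d_pair(pred, truth)
    per_item = np.sqrt(np.sum((pred - truth) ** 2, axis=1) / pred.shape[1])
    return float(per_item.mean())


def to_probability(v: np.ndarray) -> np.ndarray:
    """Convert an expression vector to a probability vector.

    Vectors with negative entries (e.g. z-scored expression) are shifted by
    their minimum first; nonnegative vectors are left undistorted.  Entries
    are floored at 1e-12 and normalized to sum 1.
    """
    p = np.asarray(v, dtype=float)
    if p.min() < 0:
        p = p - p.min()
    p = np.maximum(p, _EPS)
    return p / p.sum()


def jsd(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean Jensen-Shannon distance per item (natural log; max sqrt(ln 2))."""
    pred, truth = _as_2d_pair(pred, truth)
    vals = [
        scipy.spatial.distance.jensenshannon(to_probability(p), to_probability(t))
        for p, t in zip(pred, truth)
    ]
    return float(np.mean(vals))


def foscttm(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of samples closer than the true match, averaged over items.

    For each item n, the fraction of other items m whose prediction x_m lies
    closer (squared Euclidean) to truth s_n than n's own prediction x_n does.
    """
    pred, truth = _as_2d_pair(pred, truth)
    n = pred.shape[0]
    if n < 2:
        raise ValueError("FOSCTTM needs at least 2 matched items")
    d2 = scipy.spatial.distance.cdist(pred, truth, metric="sqeuclidean")  # d2[m, n]
    own = np.diag(d2)
    closer = (d2 < own[None, :]).sum(axis=0)  # counts m with d(x_m, s_n) < d(x_n, s_n)
    return float(np.mean(closer / (n - 1)))


def rescale_unit(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def ssim(pred_img: np.ndarray, truth_img: np.ndarray, win_size: int | None = None) -> float:
    """Structural similarity of two expression images after rescaling each
    to [0, 1]; standard constants (K1=0.01, K2=0.03), 7-pixel window."""
    a, b = rescale_unit(pred_img), rescale_unit(truth_img)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if win_size is None:
        win_size = min(7, a.shape[0] - (a.shape[0] + 1) % 2, a.shape[1] - (a.shape[1] + 1) % 2)
    return float(
        structural_similarity(a, b, data_range=1.0, win_size=win_size, K1=0.01, K2=0.03)
    )


def rasterize(coords: pd.DataFrame, values: np.ndarray, grid: int = 16) -> np.ndarray:
    """Bin per-sample values onto a grid x grid image by mean within bins."""
    x = coords["x"].to_numpy(dtype=float)
    y = coords["y"].to_numpy(dtype=float)
    sums, xe, ye = np.histogram2d(x, y, bins=grid, weights=np.asarray(values, float))
    counts, _, _ = np.histogram2d(x, y, bins=[xe, ye])
    with np.errstate(invalid="ignore"):
        img = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return img


HIGHER_BETTER = frozenset({"cc", "scc", "ssim"})
LOWER_BETTER = frozenset({"rmse", "jsd", "foscttm"})


def composite_rank_score(
    per_method_metrics: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    higher_better: Sequence[str] | None = None,
    lower_better: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average metric rank per method (rank 1 = best; ties share the average
    rank).  Orientation: higher CC/SCC/SSIM is better, lower RMSE/JSD/FOSCTTM
    is better; unknown metric names must appear in one of the two arguments.
    """
    table = pd.DataFrame(per_method_metrics).T if not isinstance(
        per_method_metrics, pd.DataFrame
    ) else per_method_metrics.copy()
    if table.shape[0] < 2:
        raise ValueError("need at least 2 methods to rank")
    if table.isna().any().any():
        missing = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing metric values for: {missing}")
    hb = set(m.lower() for m in (higher_better or [])) | HIGHER_BETTER
    lb = set(m.lower() for m in (lower_better or [])) | LOWER_BETTER
    ranks = {}
    for metric in table.columns:
        name = metric.lower()
        if name in hb:
            ranks[metric] = table[metric].rank(ascending=False, method="average")
        elif name in lb:
            ranks[metric] = table[metric].rank(ascending=True, method="average")
        else:
            raise ValueError(f"unknown orientation for metric {metric!r}")
    rank_df = pd.DataFrame(ranks)
    rank_df["composite"] = rank_df.mean(axis=1)
    return rank_df


def _as_2d_pair(pred, truth):
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth
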