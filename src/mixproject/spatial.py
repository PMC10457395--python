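"""Downstream spatial statistics: neighborhood motif permutation testing,
k-NN label transfer, and zonation scoring.

A cell's *neighborhood type* is its own cell type together with the counts
of each cell type among neighbors within a fixed radius (default 100 um).
For permutation testing the counts are discretized to 0 / 1 / 2+ per type so
the space of neighborhood types stays finite and comparable across
permutations.  Cell-type labels are permuted only within layers, so layer
composition is preserved under the null; the p-value uses the +1 correction
and therefore has resolution 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

from .datatypes import CellAtlas

DEFAULT_RADIUS_UM = 100.0
DEFAULT_ALPHA = 5e-8
DEFAULT_MIN_CELLS = 50


def _require_columns(data: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"spatial table lacks columns: {missing}")


def _adjacency(data: pd.DataFrame, radius: float) -> scipy.sparse.csr_matrix:
    xy = data[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    n = len(data)
    if pairs.size == 0:
        return scipy.sparse.csr_matrix((n, n))
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return scipy.sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )


def assign_neighborhoods(
    data: pd.DataFrame, radius: float = DEFAULT_RADIUS_UM
) -> pd.DataFrame:
    """Per-cell neighbor-type counts within ``radius`` (query cell excluded).

    ``data`` needs columns x, y, cell_type (plus optional layer).  Returns a
    table indexed like ``data`` with the query cell type and one count column
    per cell type, in canonical (sorted) type order.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    _require_columns(data, ["x", "y", "cell_type"])
    types = sorted(data["cell_type"].astype(str).unique())
    tindex = {t: i for i, t in enumerate(types)}
    labels = data["cell_type"].astype(str).map(tindex).to_numpy()
    adj = _adjacency(data, radius)
    onehot = np.zeros((len(data), len(types)))
    onehot[np.arange(len(data)), labels] = 1.0
    counts = adj @ onehot
    out = pd.DataFrame(counts.astype(int), index=data.index,
                       columns=[f"n_{t}" for t in types])
    out.insert(0, "cell_type", data["cell_type"].astype(str).values)
    return out


def _signature_codes(labels: np.ndarray, counts: np.ndarray, n_types: int) -> np.ndarray:
    """Encode (query type, binned counts 0/1/2+) as one integer per cell."""
    binned = np.minimum(counts, 2)
    pow3 = 3 ** np.arange(n_types)
    return labels + n_types * (binned @ pow3).astype(int)


def _decode_signature(code: int, types: list[str]) -> tuple[str, tuple[int, ...]]:
    k = len(types)
    qtype = types[code % k]
    rest = code // k
    bins = []
    for _ in range(k):
        bins.append(rest % 3)
        rest //= 3
    return qtype, tuple(bins)


@dataclass
class MotifResult:
    """One neighborhood type with its permutation-test outcome."""

    query_type: str
    neighbor_bins: tuple  # per-type binned counts (0, 1, 2 = two-or-more)
    observed_cells: int
    p_value: float
    significant: bool


def motif_permutation_test(
    data: pd.DataFrame,
    radius: float = DEFAULT_RADIUS_UM,
    n_perm: int = 10_000,
    min_cells: int = DEFAULT_MIN_CELLS,
    alpha_threshold: float = DEFAULT_ALPHA,
    seed: int = 0,
    stratify_by_layer: bool = True,
    batch: int = 64,
) -> pd.DataFrame:
    """Permutation test for over-represented neighborhood types.

    Observed cell counts per neighborhood type are compared against the
    distribution obtained by permuting cell-type labels (within layers when
    ``stratify_by_layer``); p = (1 + #{perm >= obs}) / (1 + n_perm), and a
    neighborhood type is significant iff p < ``alpha_threshold`` AND at
    least ``min_cells`` cells carry it.  Defaults follow common practice for
    million-permutation scans (alpha 5e-8, >= 50 cells).
    """
    _require_columns(data, ["x", "y", "cell_type"])
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if stratify_by_layer and "layer" not in data.columns:
        raise ValueError("stratified permutations require a 'layer' column")

    types = sorted(data["cell_type"].astype(str).unique())
    k = len(types)
    tindex = {t: i for i, t in enumerate(types)}
    labels = data["cell_type"].astype(str).map(tindex).to_numpy()
    n = len(data)
    adj = _adjacency(data, radius)

    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    obs_codes = _signature_codes(labels, adj @ onehot, k)
    space = k * 3**k
    obs_hist = np.bincount(obs_codes, minlength=space)
    sig_codes = np.flatnonzero(obs_hist)
    obs_counts = obs_hist[sig_codes]

    if stratify_by_layer:
        groups = [np.flatnonzero(data["layer"].values == g)
                  for g in pd.unique(data["layer"].values)]
    else:
        groups = [np.arange(n)]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(sig_codes.size, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm_labels = np.tile(labels[:, None], (1, b))
        for grp in groups:
            for j in range(b):
                perm_labels[grp, j] = labels[grp[rng.permutation(grp.size)]]
        oh = np.zeros((n, b * k))
        cols = perm_labels + k * np.arange(b)[None, :]
        oh[np.arange(n)[:, None], cols] = 1.0
        counts = np.asarray(adj @ oh).reshape(n, b, k)
        binned = np.minimum(counts, 2)
        pow3 = 3 ** np.arange(k)
        codes = perm_labels + k * (binned @ pow3).astype(int)
        for j in range(b):
            hist = np.bincount(codes[:, j], minlength=space)
            exceed += hist[sig_codes] >= obs_counts
        done += b

    p = (1.0 + exceed) / (1.0 + n_perm)
    rows = []
    for code, obs, pv in zip(sig_codes, obs_counts, p):
        qtype, bins = _decode_signature(int(code), types)
        rows.append(
            {
                "query_type": qtype,
                "neighbor_bins": bins,
                "observed_cells": int(obs),
                "p_value": float(pv),
                "significant": bool(pv < alpha_threshold and obs >= min_cells),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def knn_label_transfer(
    observations: np.ndarray,
    atlas: CellAtlas,
    k: int = 15,
) -> pd.Series:
    """Label observations by majority vote among the k nearest atlas cells
    (Euclidean, in the shared feature space).  A tied vote resolves to the
    label of the closest neighbor among the tied classes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > atlas.expr.n_obs:
        raise ValueError(f"k={k} exceeds atlas size {atlas.expr.n_obs}")
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    ref = atlas.expr.values.T  # cells x genes
    if obs.shape[1] != ref.shape[1]:
        raise ValueError("observations and atlas are not in the same feature space")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, idx = nn.kneighbors(obs)
    atlas_labels = np.array(atlas.cell_types)
    out = []
    for drow, irow in zip(dist, idx):
        neigh = atlas_labels[irow]
        labs, votes = np.unique(neigh, return_counts=True)
        winners = set(labs[votes == votes.max()])
        if len(winners) == 1:
            out.append(winners.pop())
        else:  # tie: closest neighbor whose label is tied
            for d, lab in sorted(zip(drow, neigh)):
                if lab in winners:
                    out.append(lab)
                    break
    return pd.Series(out, name="cell_type")


def zonation_score(
    zone_profiles: pd.DataFrame,
    quantile: float = 0.75,
    direction: str = "specific",
) -> pd.DataFrame:
    """Score genes by distance of their normalized zone profile to the
    nearest one-hot ideal (e.g. (1,0,0,0,0) for a zone-1 gene).

    Per gene the raw zone profile is normalized to sum 1 (so the score is
    scale-invariant), the Euclidean distance to each zone's one-hot ideal is
    computed, and the minimum over zones is the headline score with the
    arg-min as the peak zone.  With ``direction='specific'`` (default) genes
    in the top ``quantile`` of zone-specificity — i.e. distance below the
    (1 - quantile) quantile of scores — are flagged zonated; ``'diffuse'``
    flags the opposite tail.  Genes whose profile sums to zero are flagged
    unscorable.
    """
    zones = zone_profiles.shape[0]
    vals = zone_profiles.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    unscorable = totals <= 0
    safe = np.where(unscorable, 1.0, totals)
    probs = vals / safe  # zones x genes

    ideals = np.eye(zones)
    # distance of each gene profile to each one-hot ideal
    d = np.sqrt(((probs[:, None, :] - ideals[:, :, None]) ** 2).sum(axis=0))
    score = d.min(axis=0)
    peak = d.argmin(axis=0)
    score = np.where(unscorable, np.nan, score)

    valid = score[~np.isnan(score)]
    if direction == "specific":
        threshold = np.quantile(valid, 1.0 - quantile)
        zonated = score <= threshold
    elif direction == "diffuse":
        threshold = np.quantile(valid, quantile)
        zonated = score >= threshold
    else:
        raise ValueError("direction must be 'specific' or 'diffuse'")
    zonated = np.where(np.isnan(score), False, zonated)

    return pd.DataFrame(
        {
            "score": score,
            "peak_zone": [zone_profiles.index[z] for z in peak],
            "zonated": zonated.astype(bool),
            "unscorable": unscorable,
        },
        index=zone_profiles.columns,
    )
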