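"""Synthetic benchmark generator.

Everything the pipeline consumes can be generated here with known ground
truth: clustered count atlases with within-type variation, pseudo-bulk
mixtures built by summing one sampled cell per contributing type,
Dirichlet-weighted continuous mixtures, spatial point patterns with planted
neighborhood motifs, and 5-zone zonation profiles.

The atlas generator draws counts from a negative-binomial hierarchy: a
log-normal baseline program shared by all types, a fraction ``separation``
of genes up-regulated per type (the type-specific program), log-normal
per-cell library sizes, and NB sampling with fixed dispersion around each
cell's expected rate.  Optional coupled gene pairs share a per-cell
log-normal factor, inducing within-type co-expression that imputation
benchmarks rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CellAtlas, ExpressionMatrix, GenePanel, MixtureSet


@dataclass
class SyntheticTruth:
    """Ground truth aligned by id to the generated observations."""

    alpha: Optional[pd.DataFrame] = None  # mixtures x types, true RNA fractions
    contributors: Optional[pd.DataFrame] = None  # mixtures x types, atlas cell ids
    motif_members: Optional[pd.Series] = None  # cell id -> motif instance (or -1)
    zonation: Optional[pd.DataFrame] = None  # genes x (zonated flag, peak zone)
    coupled_pairs: list[tuple[str, str]] = field(default_factory=list)


def make_atlas(
    n_types: int,
    n_genes: int,
    cells_per_type: int,
    separation: float = 0.3,
    seed: int = 0,
    dispersion: float | Sequence[float] = 0.3,
    fold: float = 5.0,
    program_sd: float = 1.0,
    library_size: float = 2000.0,
    n_coupled_pairs: int = 0,
    coupling_sd: float = 1.0,
    coupled_expression: float = 1.0,
    similar_pairs: Sequence[tuple[int, int]] = (),
    similarity: float = 0.9,
) -> CellAtlas:
    """Clustered multi-type count atlas.

    ``separation`` is the fraction of genes given a type-specific program
    (up-regulated ``fold``-fold in that type); 0 means all types share one
    program and labels are unpredictable from expression.  ``similar_pairs``
    lists type index pairs (i, j) whose programs are blended so type j is a
    near-copy of type i (``similarity`` = blend weight), for missing-type
    experiments.  ``n_coupled_pairs`` consecutive gene pairs (genes 0-1,
    2-3, ...) share a per-cell log-normal factor of sd ``coupling_sd``,
    inducing within-type co-expression for imputation benchmarks; their
    baseline expression is the program median times ``coupled_expression``.
    ``program_sd`` controls how skewed the baseline program is (flatter
    programs keep library-size normalization from coupling unrelated genes).
    """
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,))
    if np.any(disp <= 0):
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(0.0, program_sd, size=n_genes))  # log-normal program

    pair_genes = [(2 * p, 2 * p + 1) for p in range(n_coupled_pairs)]
    if n_coupled_pairs * 2 > n_genes:
        raise ValueError("too many coupled pairs for n_genes")
    coupled = {g for pair in pair_genes for g in pair}
    if coupled:
        base[sorted(coupled)] = np.median(base) * coupled_expression

    programs = np.tile(base, (n_types, 1))
    n_specific = int(round(separation * n_genes))
    free_genes = np.array([g for g in range(n_genes) if g not in coupled])
    for k in range(n_types):
        if n_specific > 0 and free_genes.size:
            idx = rng.choice(free_genes, size=min(n_specific, free_genes.size),
                             replace=False)
            programs[k, idx] *= fold
    for i, j in similar_pairs:
        programs[j] = similarity * programs[i] + (1 - similarity) * programs[j]

    values = np.zeros((n_genes, n_types * cells_per_type))
    labels, obs_ids = [], []
    col = 0
    for k in range(n_types):
        lab = f"type{k}"
        prog = programs[k] / programs[k].sum()
        for j in range(cells_per_type):
            lib = rng.lognormal(mean=np.log(library_size), sigma=0.25)
            rate = prog.copy()
            for g1, g2 in pair_genes:
                # mean-one log-normal factor so coupling does not inflate
                # the pair's expected library share
                shared = rng.lognormal(mean=-0.5 * coupling_sd**2, sigma=coupling_sd)
                rate[g1] *= shared
                rate[g2] *= shared
            # NB via gamma-Poisson with shape r = 1/dispersion (per gene)
            r = 1.0 / disp
            lam = rng.gamma(shape=r, scale=rate * lib / r)
            values[:, col] = rng.poisson(lam)
            labels.append(lab)
            obs_ids.append(f"{lab}_cell{j}")
            col += 1

    expr = ExpressionMatrix(
        values, [f"gene{g}" for g in range(n_genes)], obs_ids, "counts"
    )
    return CellAtlas(expr=expr, cell_types=labels)


def make_mixture_sets(
    atlas: CellAtlas,
    k_list: Sequence[int] = (2, 4, 6, 8),
    n_per_set: int = 5000,
    seed: int = 0,
) -> tuple[MixtureSet, SyntheticTruth]:
    """Pseudo-bulk mixtures: per set, each mixture is the elementwise sum of
    one sampled cell per contributing type.

    Defaults (four sets with 2/4/6/8 contributors, 5000 mixtures each) mirror
    the standard benchmark design and yield 20,000 mixtures.  Contributing
    types for a set of size k are a seeded random subset of the atlas types,
    shared by all mixtures of that set.  True RNA fractions are the
    contributing cells' library-size fractions.
    """
    rng = np.random.default_rng(seed)
    K = atlas.n_types
    labels = atlas.labels
    for k in k_list:
        if k > K:
            raise ValueError(f"contributor count {k} exceeds atlas types {K}")
    counts = atlas.expr.values  # genes x cells
    lib = counts.sum(axis=0)

    cols, alpha_rows, contrib_rows, obs_ids = [], [], [], []
    m = 0
    for k in k_list:
        chosen = sorted(rng.choice(K, size=k, replace=False).tolist())
        type_cells = {labels[t]: atlas.cells_of_type(labels[t]) for t in chosen}
        for _ in range(n_per_set):
            picks = {
                lab: int(rng.choice(cells)) for lab, cells in type_cells.items()
            }
            total = sum(lib[c] for c in picks.values())
            cols.append(sum(counts[:, c] for c in picks.values()))
            alpha_rows.append(
                {lab: lib[c] / total for lab, c in picks.items()}
            )
            contrib_rows.append(
                {lab: atlas.expr.obs_ids[c] for lab, c in picks.items()}
            )
            obs_ids.append(f"mix{k}_{m}")
            m += 1

    values = np.column_stack(cols)
    expr = ExpressionMatrix(values, list(atlas.expr.gene_ids), obs_ids, "counts")
    panel = GenePanel.symmetric(atlas.expr.gene_ids)
    alpha = pd.DataFrame(alpha_rows, index=obs_ids, columns=labels).fillna(0.0)
    contributors = pd.DataFrame(contrib_rows, index=obs_ids, columns=labels)
    return MixtureSet(expr=expr, panel=panel), SyntheticTruth(
        alpha=alpha, contributors=contributors
    )


def make_dirichlet_mixtures(
    atlas: CellAtlas,
    n: int,
    concentration: float | Sequence[float] = 1.0,
    seed: int = 0,
) -> tuple[MixtureSet, SyntheticTruth]:
    """Continuous-fraction mixtures: alpha ~ Dirichlet, components are sampled
    cells normalized to unit library size, mixture = sum_k alpha_k profile_k."""
    rng = np.random.default_rng(seed)
    labels = atlas.labels
    K = len(labels)
    conc = np.broadcast_to(np.asarray(concentration, dtype=float), (K,))
    counts = atlas.expr.values
    unit = counts / counts.sum(axis=0)  # each cell normalized to unit library

    alphas = rng.dirichlet(conc, size=n)
    cols, contrib_rows, obs_ids = [], [], []
    for i in range(n):
        picks = {lab: int(rng.choice(atlas.cells_of_type(lab))) for lab in labels}
        profile = sum(
            alphas[i, k] * unit[:, picks[lab]] for k, lab in enumerate(labels)
        )
        cols.append(profile)
        contrib_rows.append({lab: atlas.expr.obs_ids[c] for lab, c in picks.items()})
        obs_ids.append(f"dmix{i}")

    # continuous fractions of unit libraries: already "relative counts"
    values = np.column_stack(cols)
    expr = ExpressionMatrix(values, list(atlas.expr.gene_ids), obs_ids, "counts")
    panel = GenePanel.symmetric(atlas.expr.gene_ids)
    alpha = pd.DataFrame(alphas, index=obs_ids, columns=labels)
    contributors = pd.DataFrame(contrib_rows, index=obs_ids, columns=labels)
    return MixtureSet(expr=expr, panel=panel), SyntheticTruth(
        alpha=alpha, contributors=contributors
    )


def make_spatial_tissue(
    cell_types: Sequence[str],
    layers: Sequence[str],
    n_cells: int,
    motif_spec: Sequence[dict] = (),
    radius: float = 100.0,
    extent: tuple[float, float] = (2000.0, 1000.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Spatial point pattern: cells uniform within horizontal layer bands,
    plus planted motif instances whose members fall pairwise within ``radius``.

    ``motif_spec`` entries: {"types": [t1, t2, ...], "n_instances": int,
    "layer": str}.  Each instance places one cell of each listed type inside
    a disc of diameter < radius, so all pairwise distances are below radius;
    instance centers are kept at least 2.2 x radius apart (rejection
    sampling) so planted neighborhoods do not bleed into each other.
    Returns (table with cell_id, x, y, layer, cell_type; truth.motif_members).
    """
    rng = np.random.default_rng(seed)
    width, height = extent
    n_layers = len(layers)
    band = height / n_layers
    rows = []
    motif_of = {}

    def layer_of_y(y: float) -> str:
        return layers[min(int(y / band), n_layers - 1)]

    cid = 0
    for _ in range(n_cells):
        x, y = rng.uniform(0, width), rng.uniform(0, height)
        rows.append(
            {
                "cell_id": f"cell{cid}",
                "x": x,
                "y": y,
                "layer": layer_of_y(y),
                "cell_type": str(rng.choice(cell_types)),
            }
        )
        motif_of[f"cell{cid}"] = -1
        cid += 1

    instance = 0
    centers: list[tuple[float, float]] = []
    for spec in motif_spec:
        layer_idx = layers.index(spec["layer"]) if "layer" in spec else 0
        y_lo, y_hi = layer_idx * band, (layer_idx + 1) * band
        r_inst = radius * 0.45  # diameter < radius => all pairwise dists < radius
        spacing = 2.2 * radius
        for _ in range(int(spec["n_instances"])):
            for _attempt in range(10_000):
                cx = rng.uniform(r_inst, width - r_inst)
                cy = rng.uniform(y_lo + r_inst, y_hi - r_inst) if y_hi - y_lo > 2 * r_inst \
                    else (y_lo + y_hi) / 2
                if all((cx - px) ** 2 + (cy - py) ** 2 >= spacing**2
                       for px, py in centers):
                    break
            else:
                raise ValueError(
                    "could not place isolated motif instances; enlarge extent"
                )
            centers.append((cx, cy))
            for t in spec["types"]:
                ang, rad = rng.uniform(0, 2 * np.pi), r_inst * np.sqrt(rng.uniform())
                rows.append(
                    {
                        "cell_id": f"cell{cid}",
                        "x": cx + rad * np.cos(ang),
                        "y": cy + rad * np.sin(ang),
                        "layer": layers[layer_idx],
                        "cell_type": str(t),
                    }
                )
                motif_of[f"cell{cid}"] = instance
                cid += 1
            instance += 1

    table = pd.DataFrame(rows).set_index("cell_id", drop=False)
    truth = SyntheticTruth(motif_members=pd.Series(motif_of, name="motif"))
    return table, truth


def make_zonation_profiles(
    n_genes: int,
    zones: int = 5,
    zonated_fraction: float = 0.25,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Zone x gene expression profiles for zonation scoring.

    A ``zonated_fraction`` of genes peak sharply in one zone (near one-hot
    profile plus noise); the rest are flat plus noise.  Values are
    nonnegative; callers normalize per gene.
    """
    rng = np.random.default_rng(seed)
    n_zonated = int(round(zonated_fraction * n_genes))
    genes = [f"gene{g}" for g in range(n_genes)]
    mat = np.zeros((zones, n_genes))
    flags, peaks = [], []
    for g in range(n_genes):
        if g < n_zonated:
            peak = int(rng.integers(zones))
            profile = np.full(zones, 0.02)
            profile[peak] = 1.0
            flags.append(True)
            peaks.append(peak)
        else:
            profile = np.full(zones, 1.0 / zones)
            flags.append(False)
            peaks.append(-1)
        mat[:, g] = np.maximum(profile + rng.normal(0, noise_sd, size=zones), 0.0)
    table = pd.DataFrame(mat, index=[f"zone{z+1}" for z in range(zones)], columns=genes)
    truth = SyntheticTruth(
        zonation=pd.DataFrame({"zonated": flags, "peak_zone": peaks}, index=genes)
    )
    return table, truth
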