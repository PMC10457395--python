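"""Readers and writers for the on-disk formats the tool accepts.

Two interchangeable representations:

* Matrix Market triplet: ``matrix.mtx`` (genes x observations, sparse or array)
  next to ``genes.tsv`` and ``barcodes.tsv`` (one id per line).
* Dense delimited text: first column = gene ids, header row = observation ids.
  ``.csv`` or ``.tsv`` by extension.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import ExpressionMatrix

PathLike = Union[str, os.PathLike]


def read_expression(path: PathLike, layer_tag: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix from .mtx (with sidecar id files) or CSV/TSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_ids(path.parent / "genes.tsv")
        obs = _read_ids(path.parent / "barcodes.tsv")
        return ExpressionMatrix(np.asarray(mat, dtype=float), genes, obs, layer_tag)
    if path.suffix in (".csv", ".tsv"):
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float), list(df.index.astype(str)),
            list(df.columns.astype(str)), layer_tag,
        )
    raise ValueError(f"unsupported expression format: {path.suffix!r} ({path})")


def write_expression(m: ExpressionMatrix, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(m.values))
        _write_ids(path.parent / "genes.tsv", m.gene_ids)
        _write_ids(path.parent / "barcodes.tsv", m.obs_ids)
    elif path.suffix in (".csv", ".tsv"):
        sep = "," if path.suffix == ".csv" else "\t"
        m.to_frame().to_csv(path, sep=sep)
    else:
        raise ValueError(f"unsupported expression format: {path.suffix!r} ({path})")


def read_annotations(path: PathLike) -> pd.Series:
    """Cell-type annotation table: columns (cell_id, cell_type) or 2 unnamed cols."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"annotation table {path} needs at least 2 columns")
    cols = [c.lower() for c in df.columns]
    cid = df.columns[cols.index("cell_id")] if "cell_id" in cols else df.columns[0]
    ctype = df.columns[cols.index("cell_type")] if "cell_type" in cols else df.columns[1]
    return pd.Series(df[ctype].astype(str).values, index=df[cid].astype(str).values)


def read_coordinates(path: PathLike) -> pd.DataFrame:
    """Spatial coordinates: columns cell_id, x, y and optional layer / cell_type."""
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("x", "y"):
        if required not in cols:
            raise ValueError(f"coordinate table {path} lacks column {required!r}")
    idcol = cols.get("cell_id", df.columns[0])
    out = df.set_index(df[idcol].astype(str)).drop(columns=[idcol])
    out.columns = [c.lower() for c in out.columns]
    return out


def read_markers(path: PathLike) -> list[str]:
    """One marker gene per line (blank lines and '#' comments ignored)."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def _read_table(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep)


def _read_ids(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"expected sidecar id file {path}")
    return [ln.strip().split("\t")[0] for ln in path.read_text().splitlines() if ln.strip()]


def _write_ids(path: Path, ids: list[str]) -> None:
    path.write_text("\n".join(ids) + "\n")
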