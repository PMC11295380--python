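"""Readers and writers for the plain-text formats the pipeline touches.

Cohorts travel as Matrix Market bundles (``matrix.mtx`` with genes as rows
and cells as columns, 1-based indices per the format, plus ``genes.tsv`` /
``barcodes.tsv`` and an optional ``cells.tsv`` metadata table). Gene sets use
GMT; reports are JSON; tables are TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import FormatError

logger = logging.getLogger(__name__)

CELL_META_COLUMNS = ("sample_id", "patient_id", "cell_class")
CELL_CLASSES = {"tumor", "immune", "stromal", "unknown"}


def write_mtx_bundle(adata: ad.AnnData, path: str | Path) -> None:
    """Write counts + identifiers (+ cell metadata when present) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X).T  # genes x cells on disk, 10x convention
    scipy.io.mmwrite(str(path / "matrix.mtx"), X, field="integer")
    pd.Series(adata.var_names).to_csv(path / "genes.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    if len(adata.obs.columns):
        meta = adata.obs.copy()
        meta.index.name = "cell_id"
        meta.to_csv(path / "cells.tsv", sep="\t")


def read_mtx_bundle(path: str | Path) -> ad.AnnData:
    """Read a Matrix Market bundle back into an AnnData of integer counts.

    Duplicate gene symbols are merged by summing their count rows (with a
    logged warning); a mismatch between the matrix header and the identifier
    tables raises a :class:`FormatError` citing both counts.
    """
    path = Path(path)
    X = sp.csc_matrix(scipy.io.mmread(str(path / "matrix.mtx")))
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if X.shape[0] != len(genes):
        raise FormatError(f"matrix declares {X.shape[0]} genes but genes.tsv has "
                          f"{len(genes)} rows")
    if X.shape[1] != len(barcodes):
        raise FormatError(f"matrix declares {X.shape[1]} cells but barcodes.tsv has "
                          f"{len(barcodes)} rows")
    if X.min() < 0:
        raise FormatError("count matrix contains negative entries")
    if barcodes.duplicated().any():
        dups = barcodes[barcodes.duplicated()].unique()
        raise FormatError(f"duplicate cell barcodes: {list(dups)[:5]}")

    X = sp.csr_matrix(X.T)  # back to cells x genes
    if genes.duplicated().any():
        dup_names = sorted(genes[genes.duplicated()].unique())
        logger.warning("summing rows of %d duplicated gene symbols (e.g. %s)",
                       len(dup_names), dup_names[:5])
        frame = pd.DataFrame.sparse.from_spmatrix(X, columns=genes)
        dense = frame.T.groupby(level=0, sort=False).sum()
        genes = pd.Series(dense.index)
        X = sp.csr_matrix(dense.to_numpy().T)

    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    cells_path = path / "cells.tsv"
    if cells_path.exists():
        meta = read_cell_meta(cells_path)
        missing = obs.index.difference(meta.index)
        if len(missing):
            raise FormatError(f"cells.tsv is missing {len(missing)} barcodes "
                              f"(e.g. {missing[:3].tolist()})")
        obs = meta.loc[obs.index]
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read a cell metadata table indexed by ``cell_id``."""
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    missing = [c for c in ("cell_id", *CELL_META_COLUMNS) if c not in meta.columns]
    if missing:
        raise FormatError(f"cell metadata is missing required columns: {missing}")
    if meta["cell_id"].duplicated().any():
        raise FormatError("cell metadata has duplicated cell_id rows")
    bad = set(meta["cell_class"].unique()) - CELL_CLASSES
    if bad:
        raise FormatError(f"unknown cell_class values: {sorted(bad)}")
    if "mito_fraction" in meta.columns:
        frac = meta["mito_fraction"].astype(float)
        if ((frac < 0) | (frac > 1)).any():
            raise FormatError("mito_fraction outside [0, 1]")
    return meta.set_index("cell_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{set name: ordered unique members}``."""
    collection: dict[str, list[str]] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno} has {len(fields)} fields; "
                              "expected name, description and >=1 member")
        name, _desc, *members = fields
        collection[name] = list(dict.fromkeys(m for m in members if m))
    if not collection:
        logger.warning("GMT file %s contains no gene sets", path)
    return collection


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(members) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a cell-line mutation table: line_id, subtype, one boolean per gene."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("line_id", "subtype") if c not in table.columns]
    if missing:
        raise FormatError(f"mutation table is missing required columns: {missing}")
    if table["line_id"].duplicated().any():
        raise FormatError("mutation table has duplicated line_id rows")
    truthy = {"true": True, "false": False, "1": True, "0": False}
    for col in table.columns.drop(["line_id", "subtype"]):
        values = table[col]
        if values.dtype == bool:
            continue
        lowered = values.astype(str).str.lower()
        if not lowered.isin(truthy).all():
            bad = values[~lowered.isin(truthy)].iloc[0]
            raise FormatError(f"non-boolean mutation flag {bad!r} in column {col}")
        table[col] = lowered.map(truthy)
    return table.set_index("line_id")


def write_report(obj, path: str | Path) -> None:
    """Serialize a report object: dict-likes as JSON, DataFrames as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t")
        return

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray, pd.Index)):
            return list(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        if hasattr(o, "__dataclass_fields__"):
            return {f: getattr(o, f) for f in o.__dataclass_fields__}
        raise TypeError(f"cannot serialize {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_default))
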