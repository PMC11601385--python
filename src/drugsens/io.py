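"""Readers and writers for the tabular formats used across the pipeline.

GCT (#1.2 and #1.3 dialects) for expression matrices, TSV for everything else
(sample metadata, dose-response curves, scores, truth tables, mapping
tables), ``.smi`` for SMILES lists.  All writers are deterministic: fixed
column order, fixed float formatting, no timestamps.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .doseresponse import DoseResponseCurve
from .errors import FileFormatError, InputError
from .signatures import SignatureMatrix

__all__ = [
    "read_gct", "write_gct",
    "read_matrix_tsv", "write_matrix_tsv",
    "read_meta_tsv", "write_meta_tsv",
    "read_curves_tsv", "write_curves_tsv",
    "read_smiles", "write_smiles",
]

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# GCT

def write_gct(matrix: SignatureMatrix, path) -> None:
    """Write a genes x samples matrix as GCT #1.2 (sample metadata is kept in
    a separate TSV; see :func:`write_meta_tsv`)."""
    path = Path(path)
    ng, ns = matrix.data.shape
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{ng}\t{ns}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.data.columns)) + "\n")
        for gene, row in zip(matrix.data.index, matrix.data.to_numpy()):
            vals = "\t".join(FLOAT_FMT % v for v in row)
            fh.write(f"{gene}\tna\t{vals}\n")


def read_gct(path, meta: pd.DataFrame | None = None,
             scaling_state: str = "raw") -> SignatureMatrix:
    """Read a GCT #1.2 or #1.3 file into a :class:`SignatureMatrix`."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise FileFormatError(f"{path}: unsupported GCT version {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FileFormatError(f"{path}: malformed GCT dimension line")
        ng, ns = int(dims[0]), int(dims[1])
        n_row_meta = int(dims[2]) if version == "#1.3" and len(dims) >= 4 else 0
        n_col_meta = int(dims[3]) if version == "#1.3" and len(dims) >= 4 else 0
        table = pd.read_csv(fh, sep="\t", index_col=0)
    # drop Description column (#1.2) / row-metadata columns (#1.3)
    n_meta_cols = 1 if version == "#1.2" else n_row_meta
    data = table.iloc[n_col_meta:, n_meta_cols:].astype(float)
    data.index.name = None
    if data.shape != (ng, ns):
        raise FileFormatError(
            f"{path}: declared {ng}x{ns}, found {data.shape[0]}x{data.shape[1]}")
    return SignatureMatrix(data, meta, scaling_state)


# ---------------------------------------------------------------------------
# Plain TSV matrices and metadata

def write_matrix_tsv(matrix: SignatureMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id",
                       float_format=FLOAT_FMT)


def read_matrix_tsv(path, meta: pd.DataFrame | None = None,
                    scaling_state: str = "raw") -> SignatureMatrix:
    data = pd.read_csv(path, sep="\t", index_col="gene_id")
    data.index.name = None
    return SignatureMatrix(data.astype(float), meta, scaling_state)


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT)


def read_meta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# Dose-response curves

CURVE_COLUMNS = ("cell_line_id", "compound_id", "dose_um", "inhibition_pct")


def write_curves_tsv(curves: Sequence[DoseResponseCurve], path) -> None:
    """Long-format TSV: one row per (experiment, dose)."""
    rows = []
    for c in curves:
        for dose, inhib in zip(c.concentrations, c.inhibition):
            rows.append((c.cell_line_id, c.compound_id, dose, inhib))
    df = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_curves_tsv(path) -> list[DoseResponseCurve]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: curve table lacks columns {missing}")
    curves = []
    for (line, compound), grp in df.groupby(["cell_line_id", "compound_id"],
                                            sort=True):
        curves.append(DoseResponseCurve(
            cell_line_id=str(line), compound_id=str(compound),
            concentrations=grp["dose_um"].to_numpy(),
            inhibition=grp["inhibition_pct"].to_numpy()))
    return curves


# ---------------------------------------------------------------------------
# SMILES

def write_smiles(table: pd.DataFrame, path) -> None:
    """Write a ``.smi`` file: one 'SMILES<tab>id' line per compound."""
    if not {"compound_id", "smiles"} <= set(table.columns):
        raise InputError("SMILES table needs columns compound_id and smiles")
    with Path(path).open("w") as fh:
        for _, row in table.iterrows():
            fh.write(f"{row['smiles']}\t{row['compound_id']}\n")


def read_smiles(path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"compound_{i}"
        rows.append({"compound_id": cid, "smiles": smiles})
    return pd.DataFrame(rows)
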