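"""Perturbation-signature handling and transcriptional consensus signatures.

A :class:`SignatureMatrix` is a genes x samples expression matrix with
per-sample metadata (perturbagen, cell line, dose, timepoint) and a declared
scaling state.  The same container holds level-4-style perturbation
signatures, baseline cell-line expression (TPM-like) and aggregated consensus
signatures.

A transcriptional consensus signature (TCS) condenses all level-4 replicate
signatures of one perturbagen into one dose- and cell-line-independent vector:
per cell line the signatures are aggregated across doses, then aggregated
across cell lines (median at both stages by default).  Before aggregation the
level-4 data are filtered to perturbagens profiled at the target timepoint in
at least two doses and at least two cell lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "SignatureMatrix",
    "TCS",
    "filter_level4",
    "build_tcs",
    "build_tcs_table",
    "landmark_intersect",
    "rescale_unit",
]

#: required sample-metadata columns for level-4 signatures
META_COLUMNS = ("perturbagen_id", "cell_line_id", "dose_um", "timepoint_h")


@dataclass
class SignatureMatrix:
    """Genes x samples matrix plus per-sample metadata.

    ``data`` is a DataFrame indexed by gene id with one column per sample;
    ``meta`` is indexed by sample id and aligned with ``data.columns``.
    ``scaling_state`` is ``"raw"`` until :func:`rescale_unit` maps the whole
    matrix onto [0, 1].
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None
    scaling_state: str = "raw"

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise InputError("gene ids must be unique")
        if self.meta is not None:
            if len(self.meta) != self.data.shape[1]:
                raise InputError("metadata row count must equal sample count")
            if not self.meta.index.equals(self.data.columns):
                self.meta = self.meta.reindex(self.data.columns)
                if self.meta.isna().all(axis=1).any():
                    raise InputError("metadata missing for some samples")
        if self.scaling_state not in ("raw", "unit"):
            raise InputError(f"unknown scaling_state {self.scaling_state!r}")
        if self.scaling_state == "unit":
            vals = self.data.to_numpy()
            if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
                raise InputError("scaling_state='unit' requires values in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "SignatureMatrix":
        meta = self.meta.loc[sample_ids] if self.meta is not None else None
        return SignatureMatrix(self.data[list(sample_ids)], meta, self.scaling_state)


@dataclass(frozen=True)
class TCS:
    """Consensus signature of one perturbagen over the landmark genes."""

    perturbagen_id: str
    values: pd.Series  # indexed by gene id
    n_cell_lines: int
    n_doses: int
    timepoint_h: float

    def __post_init__(self):
        if self.values.isna().any():
            raise InputError("TCS must not contain missing values")


def filter_level4(sigs: SignatureMatrix, timepoint_h: float = 24.0,
                  min_doses: int = 2, min_cell_lines: int = 2) -> SignatureMatrix:
    """Keep samples at ``timepoint_h`` of perturbagens profiled at
    >= ``min_doses`` distinct doses and in >= ``min_cell_lines`` distinct cell
    lines at that timepoint.  Perturbagens failing either minimum are dropped
    entirely.  Idempotent."""
    if sigs.meta is None:
        raise InputError("level-4 filtering requires sample metadata")
    meta = sigs.meta
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise InputError(f"metadata lacks columns {missing}")

    at_tp = meta[meta["timepoint_h"] == timepoint_h]
    counts = at_tp.groupby("perturbagen_id").agg(
        n_doses=("dose_um", "nunique"), n_lines=("cell_line_id", "nunique"))
    keep_perts = counts[(counts["n_doses"] >= min_doses)
                        & (counts["n_lines"] >= min_cell_lines)].index
    keep = at_tp.index[at_tp["perturbagen_id"].isin(keep_perts)]
    if len(keep) == 0:
        warnings.warn("level-4 filter removed every sample", stacklevel=2)
    return sigs.select_samples(keep)


def build_tcs(sigs: SignatureMatrix, perturbagen_id: str,
              stat: str = "median") -> TCS:
    """Aggregate one perturbagen's signatures into its consensus signature.

    Stage 1 aggregates across doses within each cell line (per gene); stage 2
    aggregates the per-cell-line profiles across cell lines.  ``stat`` is
    ``"median"`` (default, robust to outlier signatures) or ``"mean"``.
    """
    if stat not in ("median", "mean"):
        raise InputError(f"unknown aggregation statistic {stat!r}")
    if sigs.meta is None:
        raise InputError("TCS construction requires sample metadata")
    mask = sigs.meta["perturbagen_id"] == perturbagen_id
    if not mask.any():
        raise InputError(f"unknown perturbagen {perturbagen_id!r}")
    meta = sigs.meta[mask]
    values = sigs.data.loc[:, mask.index[mask]]

    agg = getattr(pd.DataFrame, stat)
    per_line = {line: agg(values.loc[:, grp.index], axis=1)
                for line, grp in meta.groupby("cell_line_id")}
    stage1 = pd.DataFrame(per_line)
    consensus = agg(stage1, axis=1)
    return TCS(
        perturbagen_id=perturbagen_id,
        values=consensus,
        n_cell_lines=int(meta["cell_line_id"].nunique()),
        n_doses=int(meta["dose_um"].nunique()),
        timepoint_h=float(meta["timepoint_h"].iloc[0]),
    )


def build_tcs_table(sigs: SignatureMatrix, stat: str = "median") -> SignatureMatrix:
    """Consensus signatures for every perturbagen present, as a genes x
    perturbagens :class:`SignatureMatrix` (meta: perturbagen_id)."""
    if sigs.meta is None:
        raise InputError("TCS construction requires sample metadata")
    perts = sorted(sigs.meta["perturbagen_id"].unique())
    cols = {p: build_tcs(sigs, p, stat=stat).values for p in perts}
    data = pd.DataFrame(cols, index=sigs.data.index)
    meta = pd.DataFrame({"perturbagen_id": perts}, index=pd.Index(perts, name="sample"))
    return SignatureMatrix(data, meta, scaling_state="raw")


def landmark_intersect(matrix: SignatureMatrix,
                       landmark_ids) -> tuple[SignatureMatrix, list[str]]:
    """Restrict rows to the landmark gene list, in landmark order.

    Returns the restricted matrix and the landmark ids that were absent from
    the matrix.  An empty intersection is an error.
    """
    landmark_ids = list(landmark_ids)
    present = [g for g in landmark_ids if g in matrix.data.index]
    missing = [g for g in landmark_ids if g not in matrix.data.index]
    if not present:
        raise InputError("no landmark genes present in the matrix")
    out = SignatureMatrix(matrix.data.loc[present], matrix.meta, matrix.scaling_state)
    return out, missing


def rescale_unit(matrix: SignatureMatrix, per_gene: bool = False) -> SignatureMatrix:
    """Min-max rescale the whole matrix onto [0, 1].

    One global minimum and maximum over the entire dataset by default (each
    dataset is scaled independently of any other); ``per_gene=True`` rescales
    each gene row separately.  A constant matrix (or row) maps to all zeros.
    """
    if matrix.scaling_state != "raw":
        raise InputError("matrix is already unit-scaled")
    vals = matrix.data.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise InputError("cannot rescale a matrix containing NaN")
    if per_gene:
        lo = vals.min(axis=1, keepdims=True)
        span = vals.max(axis=1, keepdims=True) - lo
        span[span == 0] = np.inf  # constant rows -> 0
        scaled = (vals - lo) / span
    else:
        lo, hi = vals.min(), vals.max()
        scaled = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
    data = pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns)
    return SignatureMatrix(data, matrix.meta, scaling_state="unit")
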