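"""Record harmonization, deduplication, feature assembly and split schemes.

The record container is a DataFrame with columns ``cell_line_id``,
``compound_id``, ``score``, ``metric``, ``label`` (0/1) and optionally
``source``.  :func:`assemble` inner-joins records with the two unit-scaled
feature sources -- a consensus-signature table for compounds and a baseline
expression matrix for cell lines -- into a :class:`ModelInput` of paired
feature blocks.  :func:`split` produces every partition scheme used for
validation: the 60/10/30 random split, 10-fold, Monte-Carlo subsampling,
leave-one-tissue-out, leave-one-chemotype-out, and the five balanced subsets
obtained by partitioning the resistant majority.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, MappingError
from .signatures import SignatureMatrix

__all__ = [
    "RECORD_COLUMNS", "ModelInput", "SplitPlan",
    "map_entities", "deduplicate", "assemble", "split", "scramble_labels",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("cell_line_id", "compound_id", "score", "metric", "label")

SCHEMES = ("random-60-10-30", "kfold-10", "monte-carlo",
           "leave-one-tissue-out", "leave-one-chemotype-out",
           "balanced-subsets-5")

#: Monte-Carlo defaults: train fractions x repeats
MC_TRAIN_FRACTIONS = (0.01, 0.05, 0.10, 0.25, 0.50, 0.60)
MC_REPEATS = 10


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in ("cell_line_id", "compound_id") if c not in records.columns]
    if missing:
        raise InputError(f"record table lacks columns {missing}")


# ---------------------------------------------------------------------------
# Entity harmonization

def _apply_map(values: pd.Series, mapping: pd.DataFrame, what: str) -> pd.Series:
    if not {"source_id", "canonical_id"} <= set(mapping.columns):
        raise InputError(f"{what} map needs columns source_id, canonical_id")
    conflicts = mapping.groupby("source_id")["canonical_id"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise MappingError(
            f"{what} synonyms map to conflicting canonical ids: {list(bad.index)}")
    lut = mapping.drop_duplicates("source_id").set_index("source_id")["canonical_id"]
    return values.map(lut)


def map_entities(records: pd.DataFrame, compound_map: pd.DataFrame,
                 cell_line_map: pd.DataFrame, drop_unmatched: bool = False
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace source ids with canonical ids from the two mapping tables.

    Returns (harmonized records, unmatched report).  Unmatched records keep
    their original ids and are listed in the report, unless
    ``drop_unmatched`` removes them.
    """
    _check_records(records)
    out = records.copy()
    mapped_cp = _apply_map(out["compound_id"], compound_map, "compound")
    mapped_cl = _apply_map(out["cell_line_id"], cell_line_map, "cell line")
    unmatched_mask = mapped_cp.isna() | mapped_cl.isna()
    unmatched = out[unmatched_mask].copy()
    unmatched["missing"] = np.select(
        [mapped_cp[unmatched_mask].isna() & mapped_cl[unmatched_mask].isna(),
         mapped_cp[unmatched_mask].isna()],
        ["both", "compound"], default="cell_line")
    out["compound_id"] = mapped_cp.fillna(out["compound_id"])
    out["cell_line_id"] = mapped_cl.fillna(out["cell_line_id"])
    if drop_unmatched:
        out = out[~unmatched_mask].reset_index(drop=True)
    return out, unmatched


# ---------------------------------------------------------------------------
# Deduplication

def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """One record per (cell line, compound): the highest score is retained.

    Ties keep the first occurrence in input order (and are logged).  Mixing
    different metrics within one pair is an error, since their scores are not
    comparable.
    """
    _check_records(records)
    if "score" not in records.columns:
        raise InputError("deduplication requires a score column")
    if "metric" in records.columns:
        n_metrics = records.groupby(["cell_line_id", "compound_id"])["metric"].nunique()
        if (n_metrics > 1).any():
            bad = n_metrics[n_metrics > 1].index[:3].tolist()
            raise InputError(f"mixed metrics within pair(s) {bad}")
    grp = records.groupby(["cell_line_id", "compound_id"], sort=False)["score"]
    best = grp.transform("max")
    keep = records[records["score"] == best]
    ties = keep.duplicated(["cell_line_id", "compound_id"], keep="first")
    if ties.any():
        logger.info("deduplicate: %d exact score ties broken by input order",
                    int(ties.sum()))
    return keep[~ties].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model inputs

@dataclass
class ModelInput:
    """Paired feature blocks plus labels and group keys.

    ``blocks`` maps a block name (``"compound"``, ``"cell"``, optionally
    ``"fingerprint"``) to an (n, width) float32 array; all blocks are
    unit-scaled.  ``ids`` carries cell_line_id / compound_id and any group
    keys (tissue, chemotype) aligned with the rows.
    """

    blocks: dict[str, np.ndarray]
    y: np.ndarray
    ids: pd.DataFrame

    def __post_init__(self):
        n = len(self.y)
        for name, X in self.blocks.items():
            if X.shape[0] != n:
                raise InputError(f"block {name!r} has {X.shape[0]} rows, labels {n}")
        if len(self.ids) != n:
            raise InputError("ids not aligned with labels")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(X.shape[1] for X in self.blocks.values())

    def take(self, idx) -> "ModelInput":
        idx = np.asarray(idx)
        return ModelInput(
            blocks={k: X[idx] for k, X in self.blocks.items()},
            y=self.y[idx],
            ids=self.ids.iloc[idx].reset_index(drop=True))

    def groups(self, key: str) -> np.ndarray:
        if key not in self.ids.columns:
            raise InputError(f"group key {key!r} not present")
        return self.ids[key].to_numpy()

    def save(self, path) -> None:
        """Persist to a single .npz archive (feature blocks, labels, ids)."""
        arrays = {f"block_{k}": v for k, v in self.blocks.items()}
        arrays["y"] = self.y
        for col in self.ids.columns:
            arrays[f"ids_{col}"] = np.asarray(self.ids[col].astype(str),
                                              dtype=np.str_)
        arrays["_id_columns"] = np.asarray(list(self.ids.columns), dtype=np.str_)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelInput":
        with np.load(path, allow_pickle=False) as data:
            blocks = {k[len("block_"):]: data[k] for k in data.files
                      if k.startswith("block_")}
            id_cols = [str(c) for c in data["_id_columns"]]
            ids = pd.DataFrame({c: data[f"ids_{c}"] for c in id_cols})
            return cls(blocks=blocks, y=data["y"], ids=ids)


def _unit_block(matrix: SignatureMatrix, what: str) -> pd.DataFrame:
    if matrix.scaling_state != "unit":
        raise InputError(f"{what} features must be unit-scaled before assembly")
    return matrix.data


def assemble(records: pd.DataFrame, tcs: SignatureMatrix,
             cell_lines: SignatureMatrix,
             tissues: pd.Series | None = None,
             chemotypes: dict[str, int] | None = None,
             fingerprints: pd.DataFrame | None = None
             ) -> tuple[ModelInput, dict[str, int]]:
    """Inner-join records with both unit-scaled feature sources.

    ``tcs``: genes x compounds consensus signatures; ``cell_lines``: genes x
    cell lines expression.  Records missing either feature block are dropped
    and counted in the returned report.  Optional ``fingerprints`` (compounds
    x bits DataFrame) adds a third block.
    """
    _check_records(records)
    if "label" not in records.columns:
        raise InputError("assembly requires a binary label column")
    tcs_data = _unit_block(tcs, "compound")
    cl_data = _unit_block(cell_lines, "cell line")

    has_cp = records["compound_id"].isin(tcs_data.columns)
    has_cl = records["cell_line_id"].isin(cl_data.columns)
    if fingerprints is not None:
        has_fp = records["compound_id"].isin(fingerprints.index)
    else:
        has_fp = pd.Series(True, index=records.index)
    keep = records[has_cp & has_cl & has_fp].reset_index(drop=True)
    report = {
        "n_input": len(records),
        "n_assembled": len(keep),
        "n_missing_compound": int((~has_cp).sum()),
        "n_missing_cell_line": int((~has_cl).sum()),
        "n_missing_fingerprint": int((~has_fp).sum()),
    }

    blocks = {
        "compound": tcs_data[keep["compound_id"]].to_numpy(dtype=np.float32).T,
        "cell": cl_data[keep["cell_line_id"]].to_numpy(dtype=np.float32).T,
    }
    if fingerprints is not None:
        blocks["fingerprint"] = fingerprints.loc[
            keep["compound_id"]].to_numpy(dtype=np.float32)

    ids = keep[["cell_line_id", "compound_id"]].copy()
    if tissues is not None:
        ids["tissue"] = keep["cell_line_id"].map(tissues)
    if chemotypes is not None:
        ids["chemotype"] = keep["compound_id"].map(chemotypes)
    y = keep["label"].to_numpy(dtype=np.int8)
    return ModelInput(blocks=blocks, y=y, ids=ids), report


# ---------------------------------------------------------------------------
# Split schemes

@dataclass
class SplitPlan:
    """Named index sets for one partition scheme."""

    scheme: str
    seed: int
    sets: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def to_json(self, path) -> None:
        payload = {"scheme": self.scheme, "seed": self.seed,
                   "sets": {k: np.asarray(v).tolist() for k, v in self.sets.items()}}
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(scheme=payload["scheme"], seed=int(payload["seed"]),
                   sets={k: np.asarray(v, dtype=int)
                         for k, v in payload["sets"].items()})


def split(inputs: ModelInput | int, scheme: str, seed: int = 1234,
          group_key: str | None = None,
          train_fractions=MC_TRAIN_FRACTIONS, repeats: int = MC_REPEATS
          ) -> SplitPlan:
    """Build a :class:`SplitPlan` for ``scheme`` over ``inputs`` (or a row
    count).

    * ``random-60-10-30`` -- train/val/test with 60/10/30 proportions.
    * ``kfold-10`` -- ten disjoint folds covering all rows.
    * ``monte-carlo`` -- for each train fraction and repeat, a random train
      subsample and its complement as test.
    * ``leave-one-tissue-out`` / ``leave-one-chemotype-out`` -- one fold per
      group value; a fold holds all records of that group.
    * ``balanced-subsets-5`` -- negatives partitioned into five parts, each
      joined with every positive.
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown split scheme {scheme!r}")
    if isinstance(inputs, ModelInput):
        n = len(inputs)
    else:
        n = int(inputs)
        if scheme in ("leave-one-tissue-out", "leave-one-chemotype-out",
                      "balanced-subsets-5"):
            raise InputError(f"scheme {scheme} needs a ModelInput, not a count")
    if n < 1:
        raise InputError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)

    if scheme == "random-60-10-30":
        perm = rng.permutation(n)
        n_train, n_val = round(0.6 * n), round(0.1 * n)
        sets = {"train": np.sort(perm[:n_train]),
                "val": np.sort(perm[n_train:n_train + n_val]),
                "test": np.sort(perm[n_train + n_val:])}
    elif scheme == "kfold-10":
        perm = rng.permutation(n)
        sets = {f"fold_{i + 1}": np.sort(f)
                for i, f in enumerate(np.array_split(perm, 10))}
    elif scheme == "monte-carlo":
        sets = {}
        for frac in train_fractions:
            n_train = max(1, round(frac * n))
            for r in range(repeats):
                perm = rng.permutation(n)
                tag = f"mc_f{round(frac * 100):03d}_r{r + 1:02d}"
                sets[tag + "_train"] = np.sort(perm[:n_train])
                sets[tag + "_test"] = np.sort(perm[n_train:])
    elif scheme in ("leave-one-tissue-out", "leave-one-chemotype-out"):
        key = group_key or ("tissue" if "tissue" in scheme else "chemotype")
        groups = inputs.groups(key)
        sets = {str(g): np.flatnonzero(groups == g)
                for g in pd.unique(pd.Series(groups)).tolist()}
    else:  # balanced-subsets-5
        y = inputs.y
        pos = np.flatnonzero(y == 1)
        neg = rng.permutation(np.flatnonzero(y == 0))
        sets = {f"subset_{i + 1}": np.sort(np.concatenate([pos, part]))
                for i, part in enumerate(np.array_split(neg, 5))}
    return SplitPlan(scheme=scheme, seed=seed, sets=sets)


def scramble_labels(inputs: ModelInput, seed: int) -> ModelInput:
    """Uniform random permutation of the label vector; class counts (and all
    features) unchanged."""
    rng = np.random.default_rng(seed)
    return ModelInput(blocks=inputs.blocks,
                      y=rng.permutation(inputs.y),
                      ids=inputs.ids)
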