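"""Circular-topology fingerprints and chemotype clustering.

Compounds are represented by folded 1024-bit circular fingerprints of radius 2
(diameter 4): ECFP4 with the standard connectivity atom invariants or FCFP4
with functional-class (pharmacophoric) invariants.  For cross-domain
validation, compounds are grouped into chemotypes by k-medoids clustering
under Jaccard (1 - Tanimoto) distance; Butina sphere-exclusion clustering is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.ML.Cluster import Butina

from .errors import ChemParseError, ConfigurationError
from .io import read_smiles  # noqa: F401  (re-exported convenience)

__all__ = [
    "Fingerprint", "ChemotypeAssignment",
    "fingerprint", "fingerprint_table", "tanimoto", "tanimoto_matrix",
    "cluster_chemotypes", "toy_smiles_library",
]

N_BITS = 1024
RADIUS = 2


@dataclass(frozen=True)
class Fingerprint:
    compound_id: str
    bits: np.ndarray  # uint8 vector of length 1024
    kind: str  # "ECFP4" | "FCFP4"

    def __post_init__(self):
        if self.bits.shape != (N_BITS,):
            raise ConfigurationError(f"fingerprint must have {N_BITS} bits")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def _generator(kind: str):
    kind = kind.upper()
    if kind == "ECFP4":
        return rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS, fpSize=N_BITS)
    if kind == "FCFP4":
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=RADIUS, fpSize=N_BITS, atomInvariantsGenerator=inv)
    raise ConfigurationError(f"unknown fingerprint kind {kind!r}")


def fingerprint(smiles: str, kind: str = "ECFP4",
                compound_id: str | None = None) -> Fingerprint:
    """1024-bit folded circular fingerprint (radius 2) of one SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemParseError(smiles)
    fp = _generator(kind).GetFingerprint(mol)
    bits = np.zeros(N_BITS, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return Fingerprint(compound_id=compound_id or smiles, bits=bits,
                       kind=kind.upper())


def fingerprint_table(smiles_table, kind: str = "ECFP4") -> list[Fingerprint]:
    """Fingerprints for a DataFrame with columns compound_id, smiles."""
    return [fingerprint(row["smiles"], kind=kind, compound_id=row["compound_id"])
            for _, row in smiles_table.iterrows()]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    return inter / union if union else 0.0


def tanimoto_matrix(fps: list[Fingerprint]) -> np.ndarray:
    bits = np.stack([fp.bits for fp in fps]).astype(np.int32)
    inter = bits @ bits.T
    counts = bits.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, np.where(counts > 0, 1.0, 0.0))
    return sim


@dataclass(frozen=True)
class ChemotypeAssignment:
    labels: dict[str, int]  # compound_id -> cluster label in 1..k
    k: int
    kind: str


def _kmedoids(dist: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Seeded Voronoi-iteration k-medoids; ties broken toward lower index."""
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue  # keep old medoid for an emptied cluster
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    return assign


def cluster_chemotypes(fps: list[Fingerprint], k: int, seed: int = 1234,
                       method: str = "kmedoids",
                       butina_cutoff: float = 0.6) -> ChemotypeAssignment:
    """Cluster compounds into ``k`` chemotype groups.

    Default is k-medoids under Jaccard (1 - Tanimoto) distance with a seeded
    deterministic initialization.  ``method="butina"`` runs rdkit's Butina
    sphere exclusion at ``butina_cutoff`` distance instead (``k`` then only
    caps the number of reported clusters; the remainder merge into the last).
    """
    n = len(fps)
    if k < 1 or k > n:
        raise ConfigurationError(f"k={k} must be in [1, {n}]")
    kinds = {fp.kind for fp in fps}
    kind = kinds.pop() if len(kinds) == 1 else "mixed"
    dist = 1.0 - tanimoto_matrix(fps)

    if method == "kmedoids":
        if k == n:
            assign = np.arange(n)
        else:
            assign = _kmedoids(dist, k, seed)
    elif method == "butina":
        flat = [dist[i, j] for i in range(1, n) for j in range(i)]
        clusters = Butina.ClusterData(flat, n, butina_cutoff, isDistData=True)
        assign = np.zeros(n, dtype=int)
        for ci, members in enumerate(clusters):
            for m in members:
                assign[m] = min(ci, k - 1)
    else:
        raise ConfigurationError(f"unknown clustering method {method!r}")

    # relabel to 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = {}
    for fp, a in zip(fps, assign):
        if a not in remap:
            remap[a] = len(remap) + 1
        labels[fp.compound_id] = remap[a]
    return ChemotypeAssignment(labels=labels, k=k, kind=kind)


# ---------------------------------------------------------------------------
# A small built-in library of valid structures for synthetic benchmarks.

_SCAFFOLDS = [
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1ccc2ccccc2c1",    # naphthalene
    "C1CCCCC1",          # cyclohexane
    "c1ccsc1",           # thiophene
    "c1cnc2[nH]ccc2c1",  # azaindole
]
_SUBSTITUENTS = ["", "C", "CC", "CCC", "O", "OC", "N", "NC", "Cl", "F",
                 "C(=O)O", "C(=O)N", "S(=O)(=O)N", "N#C", "CO", "CN"]


def toy_smiles_library(n: int, prefix: str = "CP") -> "pd.DataFrame":
    """Deterministic list of ``n`` valid SMILES built from scaffold x
    substituent combinations (plus alkane chains beyond the grid)."""
    import pandas as pd

    smiles = []
    for sub in _SUBSTITUENTS:
        for scaf in _SCAFFOLDS:
            smiles.append(sub + scaf if sub else scaf)
    i = 1
    while len(smiles) < n:
        smiles.append("C" * (i + 1))  # ethane, propane, ...
        i += 1
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    return pd.DataFrame({"compound_id": ids, "smiles": smiles[:n]})
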