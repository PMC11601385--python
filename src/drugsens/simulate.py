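"""Synthetic benchmark generator with a planted compound x cell-line interaction.

Every pipeline input is emulated with the statistical structure the method
assumes, so each downstream stage has a ground-truth oracle:

* **Cell lines** -- tissue-clustered, nonnegative TPM-like expression over the
  landmark genes.  Each tissue has a mean profile; cell lines add noise and a
  pathway-activity contribution encoded through a shared gene-program matrix.
* **Perturbation signatures** -- level-4-style profiles, one per
  (compound, cell line, dose) triple, equal to the compound's
  mechanism-of-action (MoA) loading projected through the gene programs,
  scaled by a dose effect, plus noise.
* **Dose-response curves** -- Hill-model inhibition evaluated on the dose
  grid plus observation noise; the latent log-potency of a pair is

      log10 IC50_ij = a - interaction_scale * (moa_i . pathway_j) + eps_ij

  so both feature blocks carry real predictive signal.  The offset ``a`` is
  calibrated by bisection so the fraction of sensitive labels (true DSS3
  above the cutoff) matches ``target_positive_rate`` within +-2 points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import toy_smiles_library
from .doseresponse import DoseResponseCurve, hill_inhibition
from .errors import ConfigurationError
from . import io as dsio
from .signatures import SignatureMatrix

__all__ = [
    "SimConfig", "GroundTruth", "Benchmark",
    "simulate_cell_lines", "simulate_perturbations",
    "make_ground_truth", "simulate_dose_response", "make_benchmark",
    "write_benchmark", "read_benchmark",
]

#: in-house screen dose grid, uM (vehicle/0 excluded: scoring needs C > 0)
DEFAULT_DOSES = (0.37, 1.11, 3.33, 10.0, 30.0)

#: replicate seed set used for repeated runs
REPLICATE_SEEDS = (111, 222, 123, 1234, 12345)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    The defaults define the standard desk-scale benchmark: 200 cell lines in
    5 tissues x 100 compounds = 20,000 experiments, 969 landmark genes, the
    five-point uM dose grid, and a 15% sensitive-class rate.
    """

    n_cell_lines: int = 200
    n_tissues: int = 5
    n_compounds: int = 100
    n_genes: int = 969
    n_moa_factors: int = 3
    doses: tuple[float, ...] = DEFAULT_DOSES
    timepoint_hours: float = 24.0
    noise_sd: float = 0.3              # expression units, per gene
    interaction_scale: float = 1.0     # dimensionless strength of moa.pathway
    target_positive_rate: float = 0.15
    seed: int = 1234
    # secondary knobs (see docs/methods.md for rationale)
    n_assay_cell_lines: int = 5        # cell lines profiled in the L1000-like assay
    response_noise_sd: float = 2.0     # % inhibition observation noise
    potency_noise_sd: float = 0.3      # log10-uM pair-level noise eps_ij
    dss3_cutoff: float = 0.04          # sensitivity cutoff defining labels

    def __post_init__(self):
        counts = {"n_cell_lines": self.n_cell_lines, "n_tissues": self.n_tissues,
                  "n_compounds": self.n_compounds, "n_genes": self.n_genes,
                  "n_moa_factors": self.n_moa_factors}
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v}")
        if self.n_tissues > self.n_cell_lines:
            raise ConfigurationError("n_tissues must not exceed n_cell_lines")
        doses = tuple(float(d) for d in self.doses)
        if len(doses) == 0:
            raise ConfigurationError("dose list must not be empty")
        if any(d <= 0 for d in doses) or any(b <= a for a, b in zip(doses, doses[1:])):
            raise ConfigurationError("doses must be strictly increasing and positive")
        if not 0.0 < self.target_positive_rate < 1.0:
            raise ConfigurationError("target_positive_rate must be in (0, 1)")
        if self.noise_sd < 0 or self.response_noise_sd < 0 or self.potency_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        object.__setattr__(self, "doses", doses)


@dataclass
class GroundTruth:
    """Latent truth for every (cell line, compound) pair, exactly once each.

    ``pairs`` columns: cell_line_id, compound_id, potency (log10 uM IC50),
    ic50_true, auc_true, aac_true, dss3_true, label.  ``moa`` (compounds x
    factors), ``pathway`` (cell lines x factors) and ``tissues`` carry the
    latent vectors when the truth was generated in-session (they are not
    serialized).
    """

    pairs: pd.DataFrame
    tissues: pd.Series
    moa: pd.DataFrame | None = None
    pathway: pd.DataFrame | None = None
    programs: np.ndarray | None = None  # factors x genes
    potency_offset: float | None = None

    @property
    def positive_rate(self) -> float:
        return float(self.pairs["label"].mean())


# ---------------------------------------------------------------------------
# Latent state, derived deterministically from (cfg, seed)

# fixed magnitudes of the latent model (see docs/methods.md)
_SHARED_PATHWAY_NORM = 0.4   # ||mu_p||: compound main-effect strength
_TISSUE_PATHWAY_SD = 0.10    # per-factor tissue-level pathway spread
_LINE_JITTER_FACTOR = 2.0    # per-line pathway jitter = factor * noise_sd
_EXPR_PATHWAY_GAIN = 10.0    # pathway contribution to expression
_PERT_GAIN = 5.0             # MoA contribution to perturbation signatures
_TISSUE_EXPR_SD = 0.25       # per-gene tissue expression offset sd


class _Latents:
    """All latent draws, derived from independent child seeds of cfg.seed."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        kids = np.random.SeedSequence(cfg.seed).spawn(8)
        (self._rs_base, self._rs_tissue, self._rs_pathway, self._rs_moa,
         self._rs_expr, self._rs_pert, self._rs_potency, self._rs_resp) = (
            np.random.default_rng(k) for k in kids)

        g, k = cfg.n_genes, cfg.n_moa_factors
        self.cell_line_ids = [f"CL{i + 1:04d}" for i in range(cfg.n_cell_lines)]
        self.compound_ids = [f"CP{i + 1:04d}" for i in range(cfg.n_compounds)]
        self.tissue_ids = [f"tissue_{i + 1}" for i in range(cfg.n_tissues)]

        # gene programs: k rows of unit norm over genes
        P = self._rs_base.standard_normal((k, g))
        self.programs = P / np.linalg.norm(P, axis=1, keepdims=True)
        self.base_expression = self._rs_base.gamma(2.0, 2.0, size=g)

        # balanced tissue assignment, shuffled
        assign = np.arange(cfg.n_cell_lines) % cfg.n_tissues
        self.tissue_index = self._rs_tissue.permutation(assign)
        self.tissue_profiles = _TISSUE_EXPR_SD * self._rs_tissue.standard_normal(
            (g, cfg.n_tissues))

        mu_dir = self._rs_pathway.standard_normal(k)
        mu = mu_dir / np.linalg.norm(mu_dir) * _SHARED_PATHWAY_NORM
        tissue_pathway = self._rs_pathway.standard_normal((cfg.n_tissues, k)) \
            * _TISSUE_PATHWAY_SD
        jitter = self._rs_pathway.standard_normal((cfg.n_cell_lines, k)) \
            * (_LINE_JITTER_FACTOR * cfg.noise_sd)
        self.pathway = mu[None, :] + tissue_pathway[self.tissue_index] + jitter

        self.moa = self._rs_moa.standard_normal((cfg.n_compounds, k))

        # pair-level potency noise, fixed order: compounds x cell lines
        self.potency_noise = self._rs_potency.standard_normal(
            (cfg.n_compounds, cfg.n_cell_lines)) * cfg.potency_noise_sd

    @property
    def tissues(self) -> pd.Series:
        return pd.Series([self.tissue_ids[t] for t in self.tissue_index],
                         index=self.cell_line_ids, name="tissue")

    def interaction(self) -> np.ndarray:
        """moa_i . pathway_j, shape (n_compounds, n_cell_lines)."""
        return self.moa @ self.pathway.T


# ---------------------------------------------------------------------------
# True scores: Hill curve with Rmax=100, Rmin=0, slope=1 (vectorized)

def _true_scores(potency: np.ndarray, doses: tuple[float, ...],
                 t: float = 10.0) -> dict[str, np.ndarray]:
    lo = math.log10(doses[0])
    hi = math.log10(doses[-1])
    m = np.asarray(potency, dtype=float)

    def antider(u):
        return np.log1p(10.0 ** np.minimum(u - m, 300.0)) / math.log(10.0)

    # threshold crossing for Rmax=100, Rmin=0, b=1: x1 = m - log10((100-t)/t)
    x1 = np.clip(m - math.log10((100.0 - t) / t), lo, hi)
    width = hi - x1
    auc = 100.0 * (antider(hi) - antider(x1))
    with np.errstate(invalid="ignore", divide="ignore"):
        dss1 = np.where(width > 0,
                        np.maximum((auc - t * width) / ((100.0 - t) * width), 0.0),
                        0.0)
    dss2 = dss1 / 2.0  # log10(Rmax=100) = 2
    dss3 = dss2 * width / (hi - lo)
    full_auc = 100.0 * (antider(hi) - antider(lo))
    aac = full_auc / (100.0 * (hi - lo))
    return {"auc": auc, "aac": aac, "dss3": dss3}


def _calibrate_offset(q: np.ndarray, cfg: SimConfig) -> float:
    """Bisection on the potency-distribution offset so that the realized
    sensitive fraction matches cfg.target_positive_rate."""
    target = cfg.target_positive_rate

    def frac(a: float) -> float:
        s = _true_scores(a + q, cfg.doses)
        return float(np.mean(s["dss3"] > cfg.dss3_cutoff))

    lo, hi = -10.0, 15.0
    for _ in range(200):  # frac is decreasing in the offset
        if frac(lo) >= target:
            break
        lo -= 5.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target) <= 0.002:
            return mid
        if f > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Public generators

def simulate_cell_lines(cfg: SimConfig,
                        latents: _Latents | None = None
                        ) -> tuple[SignatureMatrix, pd.Series]:
    """TPM-like baseline expression (genes x cell lines) and the tissue map.

    Cell lines of one tissue share the tissue mean profile; per-line
    variation (gene noise and pathway jitter) scales with ``noise_sd``, so a
    zero-noise configuration yields identical columns within each tissue.
    """
    lat = latents or _Latents(cfg)
    expr = (lat.base_expression[:, None]
            + lat.tissue_profiles[:, lat.tissue_index]
            + _EXPR_PATHWAY_GAIN * (lat.programs.T @ lat.pathway.T)
            + cfg.noise_sd * lat._rs_expr.standard_normal(
                (cfg.n_genes, cfg.n_cell_lines)))
    expr = np.clip(expr, 0.0, None)
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    data = pd.DataFrame(expr, index=gene_ids, columns=lat.cell_line_ids)
    meta = pd.DataFrame({"cell_line_id": lat.cell_line_ids,
                         "tissue": lat.tissues.values},
                        index=pd.Index(lat.cell_line_ids, name="sample"))
    return SignatureMatrix(data, meta), lat.tissues


def simulate_perturbations(cfg: SimConfig,
                           latents: _Latents | None = None) -> SignatureMatrix:
    """Level-4-style signatures: one column per (compound, cell line, dose).

    Compounds are profiled in ``n_assay_cell_lines`` lines (spread over the
    tissue roster) at every dose of the grid and at ``timepoint_hours``.
    signature = dose_effect * (moa . programs) + noise; the dose effect is
    log10(1 + dose), so differences between doses point along the compound's
    MoA direction.
    """
    lat = latents or _Latents(cfg)
    n_assay = min(cfg.n_assay_cell_lines, cfg.n_cell_lines)
    assay_idx = np.linspace(0, cfg.n_cell_lines - 1, n_assay).astype(int)
    doses = np.asarray(cfg.doses)
    dose_effect = np.log10(1.0 + doses)

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    moa_dir = lat.moa @ lat.programs  # compounds x genes

    cols, meta_rows = [], []
    blocks = np.empty((cfg.n_genes, cfg.n_compounds * n_assay * len(doses)))
    noise = lat._rs_pert.standard_normal(blocks.shape) * cfg.noise_sd
    s = 0
    for ci, cid in enumerate(lat.compound_ids):
        for j in assay_idx:
            for d, eff in zip(doses, dose_effect):
                blocks[:, s] = _PERT_GAIN * eff * moa_dir[ci]
                cols.append(f"SIG{s + 1:06d}")
                meta_rows.append((lat.compound_ids[ci], lat.cell_line_ids[j],
                                  float(d), cfg.timepoint_hours))
                s += 1
    blocks += noise
    data = pd.DataFrame(blocks, index=gene_ids, columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["perturbagen_id", "cell_line_id",
                                            "dose_um", "timepoint_h"],
                        index=pd.Index(cols, name="sample"))
    return SignatureMatrix(data, meta)


def make_ground_truth(cfg: SimConfig,
                      latents: _Latents | None = None) -> GroundTruth:
    """Latent potencies, true scores and calibrated binary labels."""
    lat = latents or _Latents(cfg)
    q = -cfg.interaction_scale * lat.interaction() + lat.potency_noise
    offset = _calibrate_offset(q.ravel(), cfg)
    potency = offset + q  # log10 uM IC50, compounds x cell lines

    scores = _true_scores(potency.ravel(), cfg.doses)
    n_cp, n_cl = cfg.n_compounds, cfg.n_cell_lines
    pairs = pd.DataFrame({
        "cell_line_id": np.tile(lat.cell_line_ids, n_cp),
        "compound_id": np.repeat(lat.compound_ids, n_cl),
        "potency": potency.ravel(),
        "ic50_true": 10.0 ** potency.ravel(),
        "auc_true": scores["auc"],
        "aac_true": scores["aac"],
        "dss3_true": scores["dss3"],
        "label": (scores["dss3"] > cfg.dss3_cutoff).astype(int),
    })
    moa = pd.DataFrame(lat.moa, index=lat.compound_ids)
    pathway = pd.DataFrame(lat.pathway, index=lat.cell_line_ids)
    return GroundTruth(pairs=pairs, tissues=lat.tissues, moa=moa,
                       pathway=pathway, programs=lat.programs,
                       potency_offset=offset)


def simulate_dose_response(cfg: SimConfig, truth: GroundTruth,
                           latents: _Latents | None = None
                           ) -> list[DoseResponseCurve]:
    """One noisy Hill curve per (cell line, compound) pair on the dose grid."""
    lat = latents or _Latents(cfg)
    doses = np.asarray(cfg.doses)
    n = len(truth.pairs)
    noise = lat._rs_resp.standard_normal((n, len(doses))) * cfg.response_noise_sd
    curves = []
    for row, eta in zip(truth.pairs.itertuples(index=False), noise):
        inhib = hill_inhibition(doses, 100.0, 0.0, 1.0, row.ic50_true) + eta
        curves.append(DoseResponseCurve(
            cell_line_id=row.cell_line_id, compound_id=row.compound_id,
            concentrations=doses.copy(), inhibition=inhib))
    return curves


@dataclass
class Benchmark:
    """A mutually consistent bundle of all pipeline inputs plus the truth."""

    cfg: SimConfig
    expression: SignatureMatrix
    tissues: pd.Series
    perturbations: SignatureMatrix
    curves: list[DoseResponseCurve]
    truth: GroundTruth
    compounds: pd.DataFrame  # compound_id, smiles


def make_benchmark(cfg: SimConfig) -> Benchmark:
    """Generate the full benchmark bundle from one configuration."""
    lat = _Latents(cfg)
    expression, tissues = simulate_cell_lines(cfg, lat)
    perturbations = simulate_perturbations(cfg, lat)
    truth = make_ground_truth(cfg, lat)
    curves = simulate_dose_response(cfg, truth, lat)
    compounds = toy_smiles_library(cfg.n_compounds)
    return Benchmark(cfg=cfg, expression=expression, tissues=tissues,
                     perturbations=perturbations, curves=curves, truth=truth,
                     compounds=compounds)


# ---------------------------------------------------------------------------
# Serialization (deterministic text formats)

def write_benchmark(bench: Benchmark, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dsio.write_matrix_tsv(bench.expression, outdir / "cell_lines.tsv")
    dsio.write_gct(bench.perturbations, outdir / "perturbations.gct")
    dsio.write_meta_tsv(bench.perturbations.meta, outdir / "perturbations_meta.tsv")
    dsio.write_curves_tsv(bench.curves, outdir / "curves.tsv")
    bench.truth.pairs.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                             float_format=dsio.FLOAT_FMT)
    bench.tissues.rename_axis("cell_line_id").to_frame().to_csv(
        outdir / "tissues.tsv", sep="\t")
    dsio.write_smiles(bench.compounds, outdir / "compounds.smi")


def read_benchmark(indir, cfg: SimConfig | None = None) -> Benchmark:
    indir = Path(indir)
    meta = dsio.read_meta_tsv(indir / "perturbations_meta.tsv")
    perturbations = dsio.read_gct(indir / "perturbations.gct", meta=meta)
    expression = dsio.read_matrix_tsv(indir / "cell_lines.tsv")
    tissues_df = pd.read_csv(indir / "tissues.tsv", sep="\t",
                             index_col="cell_line_id")
    tissues = tissues_df["tissue"]
    tissues.index.name = None
    curves = dsio.read_curves_tsv(indir / "curves.tsv")
    pairs = pd.read_csv(indir / "truth.tsv", sep="\t")
    truth = GroundTruth(pairs=pairs, tissues=tissues)
    compounds = dsio.read_smiles(indir / "compounds.smi")
    return Benchmark(cfg=cfg or SimConfig(), expression=expression,
                     tissues=tissues, perturbations=perturbations,
                     curves=curves, truth=truth, compounds=compounds)
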