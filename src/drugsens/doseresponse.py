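"""Dose-response curve scoring.

One viability experiment is a dose-response curve: percent growth inhibition of
one cancer cell line measured over an ascending micromolar concentration grid
of one compound.  This module fits a four-parameter logistic (Hill) model to
such curves and derives the standard potency/efficacy summaries used to label
drug sensitivity:

* ``AUC`` -- area under the inhibition curve over log10 concentration.
* ``DSS1/DSS2/DSS3`` -- drug sensitivity scores, i.e. the inhibition area above
  a minimum-activity threshold ``t``, normalized over the active concentration
  window (DSS1), further normalized by the maximal response (DSS2), and finally
  rescaled by the active window's share of the tested range (DSS3).
* ``AAC`` -- area above the dose-viability curve, equivalently the normalized
  inhibition area, as a fraction of the maximal possible area.
* ``IC50`` -- the fitted half-maximal inhibitory concentration.

Continuous scores are binarized with the field's conventional cutoffs
(``DSS3 > 0.04``, ``AAC > 0.275``, ``IC50 < 5 uM``, dependency / prediction
``>= 0.5``), and agreement between two binarizations is quantified with
Cohen's kappa and its large-sample Z statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigurationError, InputError

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "DSSResult",
    "BinaryLabel",
    "KappaResult",
    "hill_inhibition",
    "fit_hill",
    "compute_auc",
    "compute_aac",
    "compute_dss",
    "binarize",
    "cohens_kappa",
    "score_curves",
    "METRIC_CUTOFFS",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class DoseResponseCurve:
    """One compound x cell line experiment.

    ``concentrations`` are in uM, strictly positive and stored sorted
    ascending; ``inhibition`` is percent inhibition (clipped to [0, 100] only
    at scoring time, not at construction).
    """

    cell_line_id: str
    compound_id: str
    concentrations: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        inhib = np.asarray(self.inhibition, dtype=float)
        if conc.ndim != 1 or inhib.shape != conc.shape:
            raise InputError("concentrations and inhibition must be 1-D and equal length")
        if conc.size < 2 or np.unique(conc).size < 2:
            raise InputError("a dose-response curve needs >= 2 distinct concentrations")
        if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
            raise InputError("concentrations must be finite and strictly positive")
        order = np.argsort(conc, kind="stable")
        object.__setattr__(self, "concentrations", conc[order])
        object.__setattr__(self, "inhibition", inhib[order])

    @property
    def cmin(self) -> float:
        return float(self.concentrations[0])

    @property
    def cmax(self) -> float:
        return float(self.concentrations[-1])

    def clipped_inhibition(self) -> np.ndarray:
        return np.clip(self.inhibition, 0.0, 100.0)


@dataclass(frozen=True)
class HillFit:
    """Four-parameter logistic fit: response(C) = Rmin + (Rmax-Rmin)/(1+(IC50/C)^b)."""

    rmax: float
    rmin: float
    slope: float
    ic50: float
    converged: bool
    censored: str | None = None  # None | "low" | "high"

    def response(self, conc) -> np.ndarray:
        return hill_inhibition(np.asarray(conc, dtype=float),
                               self.rmax, self.rmin, self.slope, self.ic50)


@dataclass(frozen=True)
class DSSResult:
    auc: float
    dss1: float
    dss2: float
    dss3: float
    t: float
    x1: float
    x2: float


@dataclass(frozen=True)
class BinaryLabel:
    value: int
    metric: str
    cutoff: float


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    po: float
    pe: float
    se: float  # NaN when Pe == 1 (degenerate marginals)
    z: float
    n: int


def hill_inhibition(conc, rmax: float, rmin: float, slope: float, ic50: float):
    """Evaluate the 4PL inhibition curve at uM concentrations ``conc``."""
    conc = np.asarray(conc, dtype=float)
    # (IC50/C)^b computed in log space for numerical range
    with np.errstate(over="ignore"):
        ratio = np.exp(slope * (np.log(ic50) - np.log(conc)))
    return rmin + (rmax - rmin) / (1.0 + ratio)


# ---------------------------------------------------------------------------
# Hill fitting


def _interp_crossing(conc: np.ndarray, inhib: np.ndarray, level: float) -> float | None:
    """First linear-interpolation crossing of ``level`` over log10 concentration."""
    x = np.log10(conc)
    y = inhib
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            frac = (level - y0) / (y1 - y0)
            return 10.0 ** (x[i] + frac * (x[i + 1] - x[i]))
        if y0 == level:
            return 10.0 ** x[i]
    return None


def _fallback_fit(curve: DoseResponseCurve) -> HillFit:
    y = curve.clipped_inhibition()
    rmax = float(np.max(y))
    ic50 = _interp_crossing(curve.concentrations, y, 50.0)
    censored = None
    if ic50 is None:
        if rmax >= 50.0:  # saturated everywhere: never crosses downward
            ic50, censored = curve.cmin / 100.0, "low"
        else:
            ic50, censored = curve.cmax * 100.0, "high"
    return HillFit(rmax=rmax, rmin=0.0, slope=1.0, ic50=float(ic50),
                   converged=False, censored=censored)


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Bounded least-squares 4PL fit of a dose-response curve.

    Bounds: Rmin in [0, 50], Rmax in [0, 120], slope in (0, 10],
    IC50 in [Cmin/100, Cmax*100] (optimized as log10 IC50 with an analytic
    Jacobian).  Curves with negligible observed inhibition skip the optimizer
    and censor directly.  When the optimizer fails the fallback is Rmin = 0,
    Rmax = max observed inhibition, slope = 1 and IC50 from the
    linear-interpolated 50% crossing (censored at a bound when never crossed).
    """
    conc = curve.concentrations
    y = curve.clipped_inhibition()
    ic_lo, ic_hi = curve.cmin / 100.0, curve.cmax * 100.0

    ymax = float(np.max(y))
    if ymax < 1.0:  # no measurable response anywhere
        return _fallback_fit(curve)

    x_log = np.log10(conc)
    m_lo, m_hi = math.log10(ic_lo), math.log10(ic_hi)

    def residuals(p):
        rmax, rmin, b, m = p
        s = 1.0 / (1.0 + 10.0 ** np.clip(b * (m - x_log), -300, 300))
        return rmin + (rmax - rmin) * s - y

    def jacobian(p):
        rmax, rmin, b, m = p
        t_ = 10.0 ** np.clip(b * (m - x_log), -300, 300)
        s = 1.0 / (1.0 + t_)
        ds = -s * s * t_ * LN10  # d s / d (b*(m-x))
        return np.stack([s, 1.0 - s,
                         ds * (m - x_log) * (rmax - rmin),
                         ds * b * (rmax - rmin)], axis=1)

    p0_ic = _interp_crossing(conc, y, ymax / 2.0) or math.sqrt(curve.cmin * curve.cmax)
    p0 = np.clip([max(ymax, 1.0), 0.0, 1.0, math.log10(p0_ic)],
                 [0.0, 0.0, 1e-6, m_lo], [120.0, 50.0, 10.0, m_hi])
    try:
        res = least_squares(residuals, p0, jac=jacobian,
                            bounds=([0.0, 0.0, 1e-6, m_lo],
                                    [120.0, 50.0, 10.0, m_hi]),
                            xtol=1e-10, ftol=1e-10, gtol=1e-8, max_nfev=50)
    except ValueError:
        return _fallback_fit(curve)
    if res.status < 0 or not np.all(np.isfinite(res.x)):
        return _fallback_fit(curve)

    rmax, rmin, slope, m = (float(v) for v in res.x)
    ic50 = 10.0 ** m
    if rmin > rmax:
        return _fallback_fit(curve)
    # status 0 = iteration cap on an ill-determined (usually flat) curve:
    # keep the best point found but do not claim convergence
    converged = res.status > 0
    # an IC50 outside the tested range cannot be localized by the data
    censored = None
    if ic50 < curve.cmin:
        censored = "low"
    elif ic50 > curve.cmax:
        censored = "high"
    return HillFit(rmax=rmax, rmin=rmin, slope=slope, ic50=ic50,
                   converged=converged, censored=censored)


# ---------------------------------------------------------------------------
# Area scores

def compute_auc(curve: DoseResponseCurve) -> float:
    """Trapezoidal area of clipped inhibition over log10 concentration.

    Units are %*log10-uM over the full tested range [Cmin, Cmax]."""
    if np.unique(curve.concentrations).size < 2:
        raise InputError("AUC requires at least two distinct concentrations")
    return float(np.trapezoid(curve.clipped_inhibition(),
                              np.log10(curve.concentrations)))


def compute_aac(curve: DoseResponseCurve) -> float:
    """Normalized inhibition area in [0, 1] (area above the viability curve)."""
    width = math.log10(curve.cmax) - math.log10(curve.cmin)
    return compute_auc(curve) / (100.0 * width)


def _hill_log_integral(fit_rmax, rmin, slope, log_ic50, u1, u2) -> float:
    """Closed-form integral of the 4PL response over u = log10(C) in [u1, u2]."""
    def antider(u):
        # int 1/(1+10^{b(m-u)}) du = ln(1+10^{b(u-m)}) / (b ln 10)
        return math.log1p(10.0 ** (slope * (u - log_ic50))) / (slope * LN10) \
            if slope * (u - log_ic50) < 300 else (u - log_ic50)
    return rmin * (u2 - u1) + (fit_rmax - rmin) * (antider(u2) - antider(u1))


def compute_dss(curve: DoseResponseCurve, t: float = 10.0,
                fit: HillFit | None = None, auc: str = "fitted") -> DSSResult:
    """Drug sensitivity scores DSS1-DSS3 from a fitted dose-response curve.

    ``t`` is the minimum activity level in percent (default 10).  The active
    window is [x1, x2] in log10 uM, where x2 = log10(Cmax) and x1 is the
    concentration at which the fitted response crosses ``t`` (floored at
    log10(Cmin)).  Then, with AUC integrated over the active window,

        DSS1 = (AUC - t*(x2-x1)) / ((100-t)*(x2-x1))
        DSS2 = DSS1 / log10(Rmax)
        DSS3 = DSS2 * (x2-x1) / (log10(Cmax) - log10(Cmin))

    all clamped at 0; a response never reaching ``t`` scores 0.  ``auc``
    selects the fitted closed-form integral (default) or the empirical
    trapezoid of the observed clipped inhibition over the same window.
    """
    if not 0.0 < t < 100.0:
        raise ConfigurationError(f"activity threshold t={t} must be in (0, 100)")
    if auc not in ("fitted", "empirical"):
        raise ConfigurationError(f"auc mode {auc!r} not in {{'fitted','empirical'}}")
    if fit is None:
        fit = fit_hill(curve)

    lo, hi = math.log10(curve.cmin), math.log10(curve.cmax)
    x2 = hi
    rmax = min(fit.rmax, 100.0)
    rmin = max(fit.rmin, 0.0)

    def zero(x1: float) -> DSSResult:
        return DSSResult(auc=0.0, dss1=0.0, dss2=0.0, dss3=0.0, t=t, x1=x1, x2=x2)

    if rmax <= t:
        return zero(x2)
    if rmin >= t:
        x1 = lo  # response above threshold everywhere
    else:
        # threshold crossing of the fitted curve (closed form)
        x1 = math.log10(fit.ic50) - math.log10((rmax - t) / (t - rmin)) / fit.slope
        x1 = min(max(x1, lo), x2)
    if x2 - x1 <= 0:
        return zero(x1)

    if auc == "fitted":
        area = _hill_log_integral(rmax, rmin, fit.slope, math.log10(fit.ic50), x1, x2)
    else:
        xs = np.log10(curve.concentrations)
        ys = curve.clipped_inhibition()
        grid = np.unique(np.concatenate([[x1], xs[(xs > x1) & (xs < x2)], [x2]]))
        area = float(np.trapezoid(np.interp(grid, xs, ys), grid))

    width = x2 - x1
    dss1 = max((area - t * width) / ((100.0 - t) * width), 0.0)
    log_rmax = math.log10(rmax)
    dss2 = dss1 / log_rmax if log_rmax > 0 else 0.0
    dss3 = dss2 * width / (hi - lo)
    return DSSResult(auc=float(area), dss1=dss1, dss2=dss2, dss3=dss3,
                     t=t, x1=x1, x2=x2)


# ---------------------------------------------------------------------------
# Binarization and agreement

#: metric -> (default cutoff, comparison); "gt": score > cutoff is sensitive,
#: "lt": score < cutoff, "ge": score >= cutoff.
METRIC_CUTOFFS: dict[str, tuple[float, str]] = {
    "DSS3": (0.04, "gt"),
    "AAC": (0.275, "gt"),
    "IC50": (5.0, "lt"),
    "dependency": (0.5, "ge"),
    "prediction": (0.5, "ge"),
}

_METRIC_ALIASES = {
    "dss3": "DSS3",
    "aac": "AAC",
    "recomputed-aac": "AAC",
    "ic50": "IC50",
    "dependency": "dependency",
    "prediction": "prediction",
}


def _canonical_metric(metric: str) -> str:
    key = metric.strip().lower()
    if key not in _METRIC_ALIASES:
        raise ConfigurationError(f"unknown sensitivity metric {metric!r}")
    return _METRIC_ALIASES[key]


def binarize(score: float, metric: str, cutoff: float | None = None) -> BinaryLabel:
    """Binarize a continuous sensitivity score with its metric's cutoff rule.

    DSS3: sensitive iff score > 0.04; AAC: > 0.275; IC50: < 5.0 uM;
    dependency and prediction estimates: >= 0.5.
    """
    metric = _canonical_metric(metric)
    default_cutoff, op = METRIC_CUTOFFS[metric]
    if cutoff is None:
        cutoff = default_cutoff
    if score is None or (isinstance(score, float) and math.isnan(score)):
        raise InputError(f"NaN score cannot be binarized for metric {metric}")
    score = float(score)
    if op == "gt":
        value = score > cutoff
    elif op == "lt":
        value = score < cutoff
    else:
        value = score >= cutoff
    return BinaryLabel(value=int(value), metric=metric, cutoff=float(cutoff))


def cohens_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> KappaResult:
    """Cohen's kappa between two binary label vectors.

    kappa = (Po - Pe) / (1 - Pe) with Po the observed agreement fraction and
    Pe the chance agreement from the marginals;
    SE(kappa) = sqrt(Po (1-Po) / (N (1-Pe)^2)) and Z = kappa / SE.
    With degenerate marginals (Pe = 1) kappa, SE and Z are reported as NaN.
    """
    a = np.asarray(labels_a, dtype=int).ravel()
    b = np.asarray(labels_b, dtype=int).ravel()
    if a.shape != b.shape:
        raise InputError("label vectors must have equal length")
    n = a.size
    if n < 1:
        raise InputError("kappa requires at least one observation")

    po = float(np.mean(a == b))
    classes = np.union1d(a, b)
    pe = float(sum(np.mean(a == c) * np.mean(b == c) for c in classes))
    if pe >= 1.0 - 1e-15:
        return KappaResult(kappa=math.nan, po=po, pe=pe, se=math.nan,
                           z=math.nan, n=n)
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    z = kappa / se if se > 0 else math.inf * np.sign(kappa) if kappa else math.nan
    return KappaResult(kappa=kappa, po=po, pe=pe, se=se, z=z, n=n)


# ---------------------------------------------------------------------------
# Table-level scoring

def score_curves(curves: Sequence[DoseResponseCurve], t: float = 10.0,
                 auc: str = "fitted") -> pd.DataFrame:
    """Score a batch of curves; one row per experiment.

    Columns: cell_line_id, compound_id, AUC (empirical full-range), AAC,
    DSS1..DSS3, IC50, converged, censored.
    """
    rows = []
    for curve in curves:
        fit = fit_hill(curve)
        dss = compute_dss(curve, t=t, fit=fit, auc=auc)
        rows.append({
            "cell_line_id": curve.cell_line_id,
            "compound_id": curve.compound_id,
            "AUC": compute_auc(curve),
            "AAC": compute_aac(curve),
            "DSS1": dss.dss1,
            "DSS2": dss.dss2,
            "DSS3": dss.dss3,
            "IC50": fit.ic50,
            "converged": fit.converged,
            "censored": fit.censored if fit.censored else "",
        })
    return pd.DataFrame(rows)
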