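"""Dose-response scoring: Hill fits, area scores, DSS chain, binarization,
kappa agreement."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from drugsens.doseresponse import (DoseResponseCurve, HillFit, binarize,
                                   cohens_kappa, compute_aac, compute_auc,
                                   compute_dss, fit_hill, hill_inhibition)
from drugsens.errors import ConfigurationError, InputError

GRID = np.array([0.37, 1.11, 3.33, 10.0, 30.0])


def hill_curve(rmax=100.0, rmin=0.0, slope=1.0, ic50=1.0, conc=GRID,
               noise=None, rng=None):
    y = hill_inhibition(conc, rmax, rmin, slope, ic50)
    if noise:
        y = y + rng.normal(0, noise, size=conc.shape)
    return DoseResponseCurve("CL", "CP", conc.copy(), y)


# ---------------------------------------------------------------------------
# Reference implementation: step-by-step recomputation with brute-force
# root-finding for the threshold crossing and numerical quadrature for the
# active-window area.  Independent of the closed forms in the package.

def reference_dss(fit: HillFit, cmin: float, cmax: float, t: float = 10.0):
    rmax = min(fit.rmax, 100.0)
    rmin = max(fit.rmin, 0.0)
    lo, hi = math.log10(cmin), math.log10(cmax)

    def resp(u):
        return hill_inhibition(10.0 ** u, rmax, rmin, fit.slope, fit.ic50)

    if rmax <= t:
        return 0.0, 0.0, 0.0
    if resp(lo) >= t:
        x1 = lo
    elif resp(hi) <= t:
        x1 = hi
    else:
        x1 = brentq(lambda u: resp(u) - t, lo, hi, xtol=1e-13)
    if hi - x1 <= 0:
        return 0.0, 0.0, 0.0
    area, _ = quad(resp, x1, hi, limit=200, epsabs=1e-11, epsrel=1e-11)
    dss1 = max((area - t * (hi - x1)) / ((100.0 - t) * (hi - x1)), 0.0)
    dss2 = dss1 / math.log10(rmax)
    dss3 = dss2 * (hi - x1) / (hi - lo)
    return dss1, dss2, dss3


class TestHillFit:
    def test_recovers_noise_free_parameters(self):
        curve = hill_curve(rmax=100, rmin=0, slope=1, ic50=1.0)
        fit = fit_hill(curve)
        assert fit.converged
        assert fit.rmax == pytest.approx(100.0, rel=1e-4)
        assert fit.slope == pytest.approx(1.0, rel=1e-4)
        assert fit.ic50 == pytest.approx(1.0, rel=1e-4)
        assert abs(fit.rmin) < 1e-3

    def test_flat_zero_censors_high(self):
        curve = DoseResponseCurve("CL", "CP", GRID, np.zeros(5))
        fit = fit_hill(curve)
        assert not fit.converged
        assert fit.censored == "high"
        assert fit.ic50 == pytest.approx(30.0 * 100)

    def test_flat_saturated_censors_low(self):
        curve = DoseResponseCurve("CL", "CP", GRID, np.full(5, 100.0))
        fit = fit_hill(curve)
        assert fit.censored == "low"
        assert fit.ic50 <= 0.37

    def test_rejects_single_dose(self):
        with pytest.raises(InputError):
            DoseResponseCurve("CL", "CP", np.array([1.0, 1.0]), np.array([0.0, 0.0]))

    def test_unsorted_input_is_sorted(self):
        curve = DoseResponseCurve("CL", "CP", GRID[::-1].copy(),
                                  np.arange(5, dtype=float))
        assert np.all(np.diff(curve.concentrations) > 0)


class TestAreaScores:
    def test_zero_inhibition_zero_auc(self):
        assert compute_auc(DoseResponseCurve("c", "d", GRID, np.zeros(5))) == 0.0

    def test_full_inhibition_rectangle(self):
        conc = np.array([0.3, 3.0, 30.0])  # two decades
        curve = DoseResponseCurve("c", "d", conc, np.full(3, 100.0))
        assert compute_auc(curve) == pytest.approx(200.0)
        assert compute_aac(curve) == pytest.approx(1.0)

    def test_aac_bounds(self):
        assert compute_aac(DoseResponseCurve("c", "d", GRID, np.zeros(5))) == 0.0

    def test_dense_grid_matches_quadrature(self):
        conc = np.logspace(-1, 1.5, 400)
        curve = hill_curve(conc=conc, ic50=2.0)
        brute = np.trapezoid(np.clip(curve.inhibition, 0, 100),
                             np.log10(conc))
        fine = np.logspace(-1, 1.5, 10_000)
        oracle = np.trapezoid(
            np.clip(hill_inhibition(fine, 100, 0, 1, 2.0), 0, 100),
            np.log10(fine))
        assert compute_auc(curve) == pytest.approx(brute, rel=1e-12)
        assert compute_auc(curve) == pytest.approx(oracle, rel=1e-5)

    def test_aac_monotone_under_pointwise_increase(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            y = rng.uniform(-10, 110, size=5)
            base = compute_aac(DoseResponseCurve("c", "d", GRID, y))
            more = compute_aac(DoseResponseCurve("c", "d", GRID,
                                                 np.minimum(y * 2, 100)))
            assert more >= base - 1e-12


class TestDSS:
    def test_inactive_compound_scores_zero(self):
        curve = hill_curve(rmax=8.0, ic50=1.0)  # never reaches t=10
        res = compute_dss(curve)
        assert res.dss1 == res.dss2 == res.dss3 == 0.0

    def test_fully_active_dss3_equals_dss2(self):
        # potent compound: above threshold across the whole tested range
        curve = hill_curve(ic50=0.001)
        res = compute_dss(curve)
        assert res.x1 == pytest.approx(math.log10(0.37))
        assert res.dss3 == pytest.approx(res.dss2, rel=1e-12)

    def test_matches_reference_recomputation(self):
        fit = HillFit(rmax=100.0, rmin=0.0, slope=1.0,
                      ic50=math.sqrt(0.37 * 30.0), converged=True)
        curve = hill_curve(ic50=fit.ic50)
        res = compute_dss(curve, fit=fit)
        d1, d2, d3 = reference_dss(fit, 0.37, 30.0)
        assert res.dss1 == pytest.approx(d1, rel=1e-6)
        assert res.dss2 == pytest.approx(d2, rel=1e-6)
        assert res.dss3 == pytest.approx(d3, rel=1e-6)

    def test_oracle_equivalence_on_simulated_curves(self):
        # 100 random Hill configurations vs the independent step-by-step
        # recomputation (root-finding + quadrature)
        rng = np.random.default_rng(2024)
        for _ in range(100):
            fit = HillFit(rmax=float(rng.uniform(15, 110)),
                          rmin=float(rng.uniform(0, 9)),
                          slope=float(rng.uniform(0.4, 4.0)),
                          ic50=float(10 ** rng.uniform(-2, 3)),
                          converged=True)
            curve = hill_curve(fit.rmax, fit.rmin, fit.slope, fit.ic50)
            res = compute_dss(curve, fit=fit)
            d1, d2, d3 = reference_dss(fit, 0.37, 30.0)
            assert res.dss1 == pytest.approx(d1, rel=1e-6, abs=1e-9)
            assert res.dss2 == pytest.approx(d2, rel=1e-6, abs=1e-9)
            assert res.dss3 == pytest.approx(d3, rel=1e-6, abs=1e-9)

    def test_duplicated_dose_points_do_not_change_fitted_scores(self):
        curve = hill_curve(ic50=2.0)
        dup = DoseResponseCurve("c", "d",
                                np.concatenate([GRID, GRID]),
                                np.concatenate([curve.inhibition,
                                                curve.inhibition]))
        a, b = compute_dss(curve), compute_dss(dup)
        assert b.dss3 == pytest.approx(a.dss3, abs=1e-6)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_dss(hill_curve(), t=0.0)
        with pytest.raises(ConfigurationError):
            compute_dss(hill_curve(), t=100.0)

    def test_empirical_auc_mode(self):
        curve = hill_curve(ic50=1.0)
        fitted = compute_dss(curve, auc="fitted")
        empirical = compute_dss(curve, auc="empirical")
        # noise-free curve on a coarse grid: modes agree approximately
        assert empirical.dss3 == pytest.approx(fitted.dss3, rel=0.05)


class TestBinarize:
    @pytest.mark.parametrize("score,metric,expected", [
        (0.04, "DSS3", 0),      # strict > rule
        (0.0401, "DSS3", 1),
        (0.275, "AAC", 0),
        (0.30, "recomputed-AAC", 1),
        (4.99, "IC50", 1),      # strict < rule
        (5.0, "IC50", 0),
        (0.5, "dependency", 1),  # >= rule
        (0.499, "dependency", 0),
        (0.5, "prediction", 1),
        (0.499, "prediction", 0),
    ])
    def test_cutoff_rules(self, score, metric, expected):
        assert binarize(score, metric).value == expected

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigurationError):
            binarize(0.5, "zscore")

    def test_nan_score_rejected(self):
        with pytest.raises(InputError):
            binarize(float("nan"), "DSS3")

    def test_idempotent_on_own_output(self):
        label = binarize(0.9, "prediction")
        assert binarize(float(label.value), "prediction").value == 1


class TestKappa:
    def test_perfect_agreement(self):
        res = cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1])
        assert res.kappa == pytest.approx(1.0)

    def test_worked_contingency_table(self):
        # 2x2 table [[40, 10], [5, 45]], N = 100
        a = [1] * 50 + [0] * 50
        b = [1] * 40 + [0] * 10 + [1] * 5 + [0] * 45
        res = cohens_kappa(a, b)
        assert res.po == pytest.approx(0.85)
        assert res.pe == pytest.approx(0.50)
        assert res.kappa == pytest.approx(0.70)
        assert res.se == pytest.approx(0.0714, abs=5e-4)
        assert res.z == pytest.approx(9.80, abs=5e-2)

    def test_matches_brute_force_contingency(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            res = cohens_kappa(a, b)
            # brute force from raw counts
            n11 = np.sum((a == 1) & (b == 1))
            n00 = np.sum((a == 0) & (b == 0))
            po = (n11 + n00) / n
            pe = (a.mean() * b.mean()) + ((1 - a.mean()) * (1 - b.mean()))
            assert res.po == pytest.approx(po, abs=1e-12)
            assert res.pe == pytest.approx(pe, abs=1e-12)
            if pe < 1.0 - 1e-12:
                kappa = (po - pe) / (1 - pe)
                assert res.kappa == pytest.approx(kappa, abs=1e-12)
                assert res.kappa == pytest.approx(
                    (res.po - res.pe) / (1 - res.pe), abs=1e-12)
                assert -1.0 - 1e-12 <= res.kappa <= 1.0 + 1e-12
            else:
                assert math.isnan(res.se)

    def test_independent_labels_kappa_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(cohens_kappa(a, b).kappa) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            cohens_kappa([0, 1], [0, 1, 1])
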