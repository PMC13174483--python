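"""Disease table resolution, unit conversion, LHS sampling, calibration."""

import numpy as np
import pytest

from thrombogen.cohort import (
    CalibrationWindow,
    calibrate_cohort,
    cohort_dataframe,
    disease_spec,
    resolve_spec,
    sample_cohort,
    to_molar,
)
from thrombogen.inflammation import CYTOKINES
from thrombogen.tg_metrics import TGMetrics


class TestToMolar:
    def test_prothrombin_conversion(self):
        assert to_molar(100.0, "mg/L", 72_000.0) == pytest.approx(1.389e-6, rel=1e-3)

    def test_tfpi_conversion(self):
        assert to_molar(70.0, "ng/mL", 40_000.0) == pytest.approx(1.75e-9)

    def test_zero_is_zero(self):
        assert to_molar(0.0, "pg/ml", 17_000.0) == 0.0

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unknown unit"):
            to_molar(1.0, "furlongs", 1.0)

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            to_molar(-1.0, "mg/L", 1.0)


class TestResolveSpec:
    def test_covid_vii_percent_band(self, kinetics):
        spec = disease_spec("COVID19", kinetics)
        lo, hi = resolve_spec(spec)["VII"]
        assert lo == pytest.approx(to_molar(0.275, "mg/L", 50_000.0))
        assert hi == pytest.approx(to_molar(0.85, "mg/L", 50_000.0))

    def test_hemophilia_viii_below_one_percent(self, kinetics):
        spec = disease_spec("HemophiliaA", kinetics)
        lo, hi = resolve_spec(spec)["VIII"]
        assert lo == 0.0
        assert hi == pytest.approx(to_molar(0.001, "mg/L", 330_000.0))

    def test_normal_midpoints_match_reference_plasma_structure(self, kinetics):
        """Normal-spec interval midpoints sit at 95% of the printed reference
        (uniform 60-130% band), and cytokines are point masses at baseline."""
        spec = disease_spec("Normal", kinetics)
        mid_ii = np.mean(resolve_spec(spec)["II"])
        assert mid_ii == pytest.approx(0.95 * to_molar(100.0, "mg/L", 72_000.0))
        for c in CYTOKINES:
            d = spec.distributions[c]
            assert d.is_degenerate
            assert d.low == kinetics[c].baseline_conc

    def test_mean_sd_truncated_at_three_sd_and_zero(self, kinetics):
        spec = disease_spec("COVID19", kinetics)
        d = spec.distributions["VIII"]       # SD > mean: lower bound clips at 0
        assert d.kind == "truncnorm"
        assert d.low == 0.0
        assert d.high == pytest.approx(d.mean + 3 * d.sd)

    def test_wide_covid_il6_range_is_log_uniform(self, kinetics):
        d = disease_spec("COVID19", kinetics).distributions["IL6"]
        assert d.kind == "loguniform"
        mid = d.ppf(np.array([0.5]))[0]
        assert mid == pytest.approx(np.sqrt(d.low * d.high), rel=1e-9)

    def test_unknown_disease_rejected(self):
        from thrombogen.network import ConfigurationError
        with pytest.raises(ConfigurationError, match="unknown disease"):
            disease_spec("Scurvy")


class TestSampling:
    def test_lhs_stratification_exact(self, kinetics):
        """n=4 on a uniform parameter: exactly one sample per quartile."""
        spec = disease_spec("Normal", kinetics)
        cohort = sample_cohort(spec, 4, seed=0)
        lo, hi = resolve_spec(spec)["II"]
        u = np.sort([(p.factors["II"] - lo) / (hi - lo) for p in cohort])
        strata = np.floor(u * 4).astype(int)
        assert sorted(strata.tolist()) == [0, 1, 2, 3]

    def test_lhs_stratification_holds_for_every_parameter(self, kinetics):
        spec = disease_spec("COVID19", kinetics)
        n = 16
        cohort = sample_cohort(spec, n, seed=5)
        df = cohort_dataframe(cohort)
        for p, d in spec.distributions.items():
            if d.is_degenerate:
                continue
            u = d.cdf(df[p].to_numpy())
            strata = np.floor(np.clip(u, 0, 1 - 1e-12) * n).astype(int)
            assert sorted(strata.tolist()) == list(range(n)), p

    def test_same_seed_reproduces_cohort(self, kinetics):
        spec = disease_spec("SCD", kinetics)
        a = cohort_dataframe(sample_cohort(spec, 50, seed=9))
        b = cohort_dataframe(sample_cohort(spec, 50, seed=9))
        assert a.equals(b)

    def test_lhs_beats_naive_monte_carlo_on_marginal_ks(self, kinetics):
        """KS distance of the LHS marginal beats naive MC at the same n in
        >= 90% of repeated trials."""
        spec = disease_spec("Normal", kinetics)
        d = spec.distributions["II"]
        n, wins = 200, 0
        trials = 20
        for trial in range(trials):
            lhs_vals = np.array([p.factors["II"] for p in
                                 sample_cohort(spec, n, seed=trial)])
            rng = np.random.default_rng(10_000 + trial)
            mc_vals = d.ppf(rng.uniform(size=n))
            def ks(vals):
                u = np.sort(d.cdf(vals))
                grid = (np.arange(1, n + 1)) / n
                return max(np.max(np.abs(u - grid)),
                           np.max(np.abs(u - (grid - 1 / n))))
            if ks(lhs_vals) < ks(mc_vals):
                wins += 1
        assert wins >= 0.9 * trials

    def test_bounds_respected(self, kinetics):
        spec = disease_spec("COVID19", kinetics)
        bounds = resolve_spec(spec)
        for p in sample_cohort(spec, 100, seed=3):
            for f, v in p.factors.items():
                lo, hi = bounds[f]
                assert lo - 1e-30 <= v <= hi + 1e-30, f


def _surrogate_runner(patient) -> TGMetrics:
    """Closed-form stand-in for the ODE pipeline: peak rises with II and
    falls with ATIII, mimicking the dominant PRCC structure."""
    peak = 3e-4 * patient.factors["II"] - 1e-4 * patient.factors["ATIII"]
    peak = max(peak, 1e-12)
    return TGMetrics(lag_time=300.0, time_to_peak=600.0, peak=peak,
                     etp=peak * 500.0)


class TestCalibration:
    def test_already_satisfied_window_is_a_no_op(self, kinetics):
        spec = disease_spec("Normal", kinetics)
        windows = CalibrationWindow(peak=(0.0, 1.0))
        res = calibrate_cohort(spec, windows, [("II", 0.9), ("ATIII", -0.5)],
                               _surrogate_runner, n=40, seed=1)
        assert res.converged
        assert res.n_iterations == 0
        assert resolve_spec(res.spec) == resolve_spec(spec)

    def test_window_demanding_higher_peak_shifts_ranges_with_prcc_signs(
            self, kinetics):
        spec = disease_spec("Normal", kinetics)
        base = resolve_spec(spec)
        # reachable only in the upper part of the II range
        windows = CalibrationWindow(peak=(1.2e-10, 1e-9))
        res = calibrate_cohort(spec, windows, [("II", 0.9), ("ATIII", -0.5)],
                               _surrogate_runner, n=40, seed=2,
                               target_fraction=0.5, max_iterations=6)
        lo_ii, _ = resolve_spec(res.spec)["II"]
        assert lo_ii > base["II"][0]           # II range moved upward
        assert res.converged
        assert res.acceptance_fraction >= 0.5

    def test_impossible_window_reports_failure(self, kinetics):
        spec = disease_spec("Normal", kinetics)
        windows = CalibrationWindow(peak=(10.0, 11.0))   # unreachable, mol/L
        res = calibrate_cohort(spec, windows, [("II", 0.9), ("ATIII", -0.5)],
                               _surrogate_runner, n=20, seed=3,
                               max_iterations=3)
        assert not res.converged
        assert any("unreachable" in d for d in res.diagnostics)
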