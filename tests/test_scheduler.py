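"""Two-phase protocol: decoupled limits, cycle plumbing, dose scans."""

import numpy as np
import pytest

from thrombogen.coagulation import PerturbationScenario, initial_state
from thrombogen.network import simulate
from thrombogen.scheduler import (
    IL1B_MULTIPLIER_CAP,
    PhaseProtocol,
    dose_scan,
    run_cycles,
    run_two_phase,
)
HOUR = 3600.0


class TestTwoPhase:
    def test_coupling_disabled_equals_bare_coagulation(
            self, reference_patient, coag_model, kinetics, coupling_params):
        res = run_two_phase(reference_patient,
                            PhaseProtocol(coupling_enabled=False),
                            kinetics, coupling_params, coag_model)
        y0 = initial_state(PerturbationScenario({}, 5e-12),
                           reference_patient.factors, coag_model)
        bare = simulate(coag_model, 1200.0, initial_state=y0)
        np.testing.assert_array_equal(
            res.coagulation_trajectory.concentrations, bare.concentrations)

    def test_baseline_cytokines_reproduce_unmodulated_run_exactly(
            self, reference_patient, coag_model, kinetics, coupling_params):
        """End-to-end baseline neutrality: modulation is exactly neutral."""
        res = run_two_phase(reference_patient, PhaseProtocol(),
                            kinetics, coupling_params, coag_model)
        assert res.modulation.induced_tf == 0.0
        assert res.modulation.atiii_scale == 1.0
        assert res.modulation.tfpi_scale == 1.0
        y0 = initial_state(PerturbationScenario({}, 5e-12),
                           reference_patient.factors, coag_model)
        bare = simulate(coag_model, 1200.0, initial_state=y0)
        np.testing.assert_array_equal(
            res.coagulation_trajectory.concentrations, bare.concentrations)

    def test_longer_preconditioning_raises_peak(
            self, reference_patient, coag_model, kinetics, coupling_params):
        patient = reference_patient.with_cytokine_multipliers(
            {"IL6": 10.0, "TNFA": 10.0, "IL1B": 10.0})
        peaks = {}
        for hours in (12, 24):
            proto = PhaseProtocol(inflam_duration=hours * HOUR, sustained=True)
            peaks[hours] = run_two_phase(patient, proto, kinetics,
                                         coupling_params, coag_model).metrics.peak
        assert peaks[24] >= peaks[12]

    def test_deterministic_repeat(self, reference_patient, coag_model,
                                  kinetics, coupling_params):
        a = run_two_phase(reference_patient, PhaseProtocol(), kinetics,
                          coupling_params, coag_model)
        b = run_two_phase(reference_patient, PhaseProtocol(), kinetics,
                          coupling_params, coag_model)
        np.testing.assert_array_equal(a.coagulation_trajectory.concentrations,
                                      b.coagulation_trajectory.concentrations)
        assert a.metrics == b.metrics


class TestCycles:
    def test_single_cycle_equals_two_phase(self, reference_patient, coag_model,
                                           kinetics, coupling_params):
        proto = PhaseProtocol(n_cycles=1)
        solo = run_two_phase(reference_patient, proto, kinetics,
                             coupling_params, coag_model)
        cycles = run_cycles(reference_patient, proto, kinetics,
                            coupling_params, coag_model)
        assert len(cycles) == 1
        assert cycles[0].metrics == solo.metrics

    def test_sustained_inflammation_amplifies_each_cycle(
            self, reference_patient, coag_model, kinetics, coupling_params):
        proto = PhaseProtocol(n_cycles=5, sustained=True)
        cycles = run_cycles(reference_patient, proto, kinetics,
                            coupling_params, coag_model)
        peaks = [c.metrics.peak for c in cycles]
        assert np.all(np.diff(peaks) > 0)

    def test_zero_exposure_stub_makes_cycles_identical(
            self, reference_patient, coag_model, kinetics, coupling_params):
        """With the exposure gain zeroed, no feedback channel exists."""
        proto = PhaseProtocol(n_cycles=3, sustained=True, exposure_gain=0.0)
        cycles = run_cycles(reference_patient, proto, kinetics,
                            coupling_params, coag_model)
        for c in cycles:
            assert c.thrombin_exposure == 0.0
            assert c.metrics == cycles[0].metrics

    def test_no_feedback_and_fixed_cytokines_give_identical_cycles(
            self, reference_patient, coag_model, coupling_params):
        from thrombogen.inflammation import ThrombinFeedbackParams, default_kinetics
        off = ThrombinFeedbackParams(emax=0.0)
        kin = default_kinetics(il6_feedback=off, tnfa_feedback=off,
                               il1b_feedback=off)
        proto = PhaseProtocol(n_cycles=3, sustained=True)
        cycles = run_cycles(reference_patient, proto, kin,
                            coupling_params, coag_model)
        peaks = [c.metrics.peak for c in cycles]
        assert peaks[0] == peaks[1] == peaks[2]

    def test_factors_reset_each_cycle(self, reference_patient, coag_model,
                                      kinetics, coupling_params):
        """Initial factor vector is identical across cycles except the
        TF/ATIII/TFPI modulation."""
        proto = PhaseProtocol(n_cycles=3, sustained=True)
        cycles = run_cycles(reference_patient, proto, kinetics,
                            coupling_params, coag_model)
        modulated = {coag_model.index(s) for s in ("TF", "ATIII", "TFPI")}
        first = cycles[0].coagulation_trajectory.concentrations[0]
        for c in cycles[1:]:
            y0 = c.coagulation_trajectory.concentrations[0]
            for i in range(y0.size):
                if i not in modulated:
                    assert y0[i] == first[i]

    def test_exposure_metric_peak_variant(self, reference_patient, coag_model,
                                          kinetics, coupling_params):
        proto = PhaseProtocol(exposure_metric="peak")
        res = run_two_phase(reference_patient, proto, kinetics,
                            coupling_params, coag_model)
        assert res.thrombin_exposure == pytest.approx(res.metrics.peak)


class TestDoseScan:
    def test_single_multiplier_gives_single_row(
            self, reference_patient, coag_model, kinetics, coupling_params):
        df = dose_scan(reference_patient, (1.0,), PhaseProtocol(),
                       kinetics, coupling_params, coag_model)
        assert len(df) == 1
        assert df.loc[0, "multiplier"] == 1.0

    def test_il1b_capped_at_ten_fold(self, reference_patient, coag_model,
                                     kinetics, coupling_params):
        df = dose_scan(reference_patient, (50.0,), PhaseProtocol(),
                       kinetics, coupling_params, coag_model)
        assert df.loc[0, "il1b_multiplier"] == IL1B_MULTIPLIER_CAP

    def test_nonpositive_multiplier_rejected(self, reference_patient):
        with pytest.raises(ValueError):
            dose_scan(reference_patient, (0.0, 1.0))

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            PhaseProtocol(n_cycles=0)
        with pytest.raises(ValueError):
            PhaseProtocol(exposure_metric="auc")
        with pytest.raises(ValueError):
            PhaseProtocol(coag_duration=-1.0)
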