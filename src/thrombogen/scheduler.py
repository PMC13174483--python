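"""Two-phase inflammation -> coagulation protocol orchestration.

Coagulation unfolds in seconds to minutes while cytokine-mediated factor
modulation evolves over hours, so the two subsystems run phase-split on
separate clocks: an hours-scale inflammation phase sets TF/ATIII/TFPI
conditions via the coupling laws, then a seconds-scale coagulation phase
generates thrombin. Iterating the pair, with each cycle's thrombin
exposure feeding the next cycle's cytokine production and coagulation
factors reset to their initial values between cycles, reproduces the
self-amplifying thromboinflammatory loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coagulation import (
    PerturbationScenario,
    atiii_iia_series,
    build_coagulation_model,
    initial_state,
    total_thrombin,
)
from .coupling import (
    CouplingParams,
    InflammatoryModulation,
    apply_modulation,
    default_coupling_params,
    modulation_from_phase,
)
from .inflammation import (
    CytokineKinetics,
    CytokineState,
    default_kinetics,
    run_inflammation_phase,
    terminal_state,
)
from .network import NetworkModel, SolverOptions, Trajectory, simulate
from .patients import PatientParameters
from .tg_metrics import TGMetrics, compute_tg_metrics

__all__ = [
    "HOUR",
    "PhaseProtocol",
    "CycleResult",
    "run_two_phase",
    "run_cycles",
    "dose_scan",
    "IL1B_MULTIPLIER_CAP",
    "DEFAULT_DOSE_MULTIPLIERS",
]

HOUR = 3600.0

#: Clinical cohort studies report at most ~10-fold IL-1beta elevation, so
#: dose scans cap the IL-1beta multiplier at 10 regardless of the requested
#: scan level.
IL1B_MULTIPLIER_CAP = 10.0

DEFAULT_DOSE_MULTIPLIERS = (0.5, 1.0, 2.0, 5.0, 10.0, 50.0)


@dataclass(frozen=True)
class PhaseProtocol:
    """Protocol constants for one two-phase (or multi-cycle) run.

    ``exposure_metric`` selects how a coagulation phase is condensed into
    the scalar thrombin exposure fed to the next inflammation phase: the
    ETP of the total-thrombin curve rescaled by ``exposure_gain`` (1/s)
    into concentration units, or the raw peak. ``sustained`` holds
    cytokines at (or above) their starting levels during each inflammation
    phase, modelling unresolved inflammation.
    """

    inflam_duration: float = 12 * HOUR
    coag_duration: float = 1200.0
    tf_trigger: float = 5e-12
    n_cycles: int = 1
    exposure_metric: str = "ETP"       # or "peak"
    exposure_gain: float = 1.0 / 600.0
    sustained: bool = False
    coupling_enabled: bool = True

    def __post_init__(self) -> None:
        if self.inflam_duration <= 0 or self.coag_duration <= 0:
            raise ValueError("phase durations must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.exposure_metric not in ("ETP", "peak"):
            raise ValueError(f"unknown exposure metric {self.exposure_metric!r}")


@dataclass(frozen=True)
class CycleResult:
    """Everything produced by one inflammation -> coagulation cycle."""

    cycle_index: int
    cytokine_trajectory: Trajectory
    coagulation_trajectory: Trajectory
    modulation: InflammatoryModulation
    metrics: TGMetrics
    atiii_iia_final: float
    thrombin_exposure: float     # scalar passed forward to the next cycle

    def __post_init__(self) -> None:
        if self.thrombin_exposure < 0:
            raise ValueError("thrombin exposure must be >= 0")


def _coagulation_initial(
    patient: PatientParameters, tf_trigger: float, model: NetworkModel
) -> np.ndarray:
    scenario = PerturbationScenario({}, tf_trigger, "patient")
    return initial_state(scenario, patient.factors, model)


def _exposure(metrics: TGMetrics, protocol: PhaseProtocol) -> float:
    if protocol.exposure_metric == "peak":
        return max(metrics.peak, 0.0)
    return max(metrics.etp * protocol.exposure_gain, 0.0)


def _one_cycle(
    cycle_index: int,
    cytokine_start: CytokineState,
    prior_exposure: float,
    patient: PatientParameters,
    protocol: PhaseProtocol,
    model: NetworkModel,
    kinetics: dict[str, CytokineKinetics],
    coupling: CouplingParams,
    options: SolverOptions | None,
) -> CycleResult:
    try:
        cyto_traj = run_inflammation_phase(
            cytokine_start,
            protocol.inflam_duration,
            thrombin_exposure=prior_exposure,
            kinetics=kinetics,
            clamp_floor=cytokine_start if protocol.sustained else None,
        )
    except Exception as err:
        raise type(err)(f"inflammation phase (cycle {cycle_index}): {err}") from err

    if protocol.coupling_enabled:
        mod = modulation_from_phase(cyto_traj, coupling, kinetics)
    else:
        mod = InflammatoryModulation.neutral()

    y0 = _coagulation_initial(patient, protocol.tf_trigger, model)
    y0 = apply_modulation(y0, model, mod)
    try:
        coag_traj = simulate(model, protocol.coag_duration, options, initial_state=y0)
    except Exception as err:
        raise type(err)(f"coagulation phase (cycle {cycle_index}): {err}") from err

    thrombin = total_thrombin(coag_traj)
    metrics = compute_tg_metrics(coag_traj.times, thrombin)
    return CycleResult(
        cycle_index=cycle_index,
        cytokine_trajectory=cyto_traj,
        coagulation_trajectory=coag_traj,
        modulation=mod,
        metrics=metrics,
        atiii_iia_final=float(atiii_iia_series(coag_traj)[-1]),
        thrombin_exposure=_exposure(metrics, protocol),
    )


def run_two_phase(
    patient: PatientParameters,
    protocol: PhaseProtocol | None = None,
    kinetics: dict[str, CytokineKinetics] | None = None,
    coupling: CouplingParams | None = None,
    model: NetworkModel | None = None,
    options: SolverOptions | None = None,
) -> CycleResult:
    """One inflammation phase at the patient's cytokine levels, then one
    coagulation phase from the modulated initial state.

    Fully deterministic: repeated calls are bit-identical.
    """
    protocol = protocol or PhaseProtocol()
    kinetics = kinetics or default_kinetics()
    coupling = coupling or default_coupling_params(kinetics)
    model = model or build_coagulation_model()
    return _one_cycle(1, patient.cytokines, 0.0, patient, protocol,
                      model, kinetics, coupling, options)


def run_cycles(
    patient: PatientParameters,
    protocol: PhaseProtocol,
    kinetics: dict[str, CytokineKinetics] | None = None,
    coupling: CouplingParams | None = None,
    model: NetworkModel | None = None,
    options: SolverOptions | None = None,
) -> list[CycleResult]:
    """Iterate ``protocol.n_cycles`` inflammation -> coagulation cycles.

    Cytokine state persists across cycles; coagulation factors are restored
    to the patient's values at every cycle. Cycle k's inflammation phase
    uses the thrombin exposure from cycle k-1 (cycle 1 starts cold at 0).
    """
    kinetics = kinetics or default_kinetics()
    coupling = coupling or default_coupling_params(kinetics)
    model = model or build_coagulation_model()

    results: list[CycleResult] = []
    cyto_state = patient.cytokines
    exposure = 0.0
    for k in range(1, protocol.n_cycles + 1):
        res = _one_cycle(k, cyto_state, exposure, patient, protocol,
                         model, kinetics, coupling, options)
        results.append(res)
        cyto_state = terminal_state(res.cytokine_trajectory)
        if protocol.sustained:
            # unresolved inflammation: never relax below the patient's levels
            floor = patient.cytokines.as_array()
            cyto_state = CytokineState.from_array(
                np.maximum(cyto_state.as_array(), floor))
        exposure = res.thrombin_exposure
    return results


def dose_scan(
    base_patient: PatientParameters,
    multipliers: tuple[float, ...] = DEFAULT_DOSE_MULTIPLIERS,
    protocol: PhaseProtocol | None = None,
    kinetics: dict[str, CytokineKinetics] | None = None,
    coupling: CouplingParams | None = None,
    model: NetworkModel | None = None,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """Cytokine dose scan: one two-phase run per multiplier.

    All cytokines are scaled together except IL-1beta, whose effective
    multiplier is clamped at 10x. Returns one row per multiplier with the
    TG metrics and final ATIII-IIa level.
    """
    if any(m <= 0 for m in multipliers):
        raise ValueError("multipliers must be > 0")
    protocol = protocol or PhaseProtocol()
    kinetics = kinetics or default_kinetics()
    coupling = coupling or default_coupling_params(kinetics)
    model = model or build_coagulation_model()

    rows = []
    for m in multipliers:
        eff = {"IL6": m, "TNFA": m, "IL1B": min(m, IL1B_MULTIPLIER_CAP)}
        patient = base_patient.with_cytokine_multipliers(eff)
        res = run_two_phase(patient, protocol, kinetics, coupling, model, options)
        rows.append({
            "multiplier": m,
            "il1b_multiplier": eff["IL1B"],
            "lag_s": res.metrics.lag_time,
            "ttp_s": res.metrics.time_to_peak,
            "peak_M": res.metrics.peak,
            "etp_M_s": res.metrics.etp,
            "atiii_iia_final_M": res.atiii_iia_final,
            "induced_tf_M": res.modulation.induced_tf,
            "atiii_scale": res.modulation.atiii_scale,
            "tfpi_scale": res.modulation.tfpi_scale,
        })
    return pd.DataFrame(rows)
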