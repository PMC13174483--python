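"""Plasma cytokine kinetics for IL-6, IL-1beta and TNF-alpha.

Each cytokine follows first-order turnover

    dC/dt = p_basal * m(E) - k_deg * C

where ``k_deg = ln 2 / half_life`` is fixed by the reported plasma
half-life, ``p_basal = k_deg * baseline`` is calibrated so that the
unstimulated system sits exactly at its normal plasma concentration
(homeostatic steady state), and ``m(E)`` is a Hill-type multiplier on
production driven by thrombin exposure E from the coagulation subsystem.

Half-life defaults: one hour for IL-6 and IL-1beta, 4.6 minutes for
TNF-alpha. Normal baseline cytokine concentrations are not authoritative
clinical constants; the defaults below are typical healthy-plasma values
and every downstream behaviour in the package is expressed relative to
baseline, never in absolute pg/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import SimulationError, Trajectory

__all__ = [
    "CYTOKINES",
    "CYTOKINE_MW_G_PER_MOL",
    "ThrombinFeedbackParams",
    "CytokineKinetics",
    "CytokineState",
    "degradation_rate",
    "steady_state_production",
    "feedback_multiplier",
    "cytokine_rhs",
    "run_inflammation_phase",
    "default_kinetics",
    "pg_per_ml_to_molar",
]

CYTOKINES = ("IL6", "IL1B", "TNFA")

#: Monomer molecular weights (g/mol) for pg/ml -> mol/L conversion.
CYTOKINE_MW_G_PER_MOL = {"IL6": 21_000.0, "IL1B": 17_000.0, "TNFA": 17_000.0}

#: Default normal plasma baselines, pg/ml (configurable, non-authoritative).
#: High-sensitivity assays in healthy adults report low-single-digit pg/ml
#: for IL-6 and TNF-alpha and ~0.1 pg/ml for IL-1beta; mildly inflamed
#: disease states (e.g. type 2 diabetes) sit just above these levels.
DEFAULT_BASELINES_PG_ML = {"IL6": 2.0, "IL1B": 0.1, "TNFA": 2.0}

HOUR = 3600.0


def pg_per_ml_to_molar(value_pg_ml: float, mw_g_per_mol: float) -> float:
    """Convert pg/ml to mol/L: 1 pg/ml = 1e-9 g/L."""
    return value_pg_ml * 1e-9 / mw_g_per_mol


def degradation_rate(half_life_s: float) -> float:
    """First-order degradation rate ln2 / half-life (1/s)."""
    if half_life_s <= 0:
        raise ValueError(f"half-life must be > 0, got {half_life_s}")
    return math.log(2.0) / half_life_s


def steady_state_production(baseline_conc: float, k_deg: float) -> float:
    """Basal production rate (mol/(L*s)) holding the baseline steady state."""
    if baseline_conc <= 0 or k_deg <= 0:
        raise ValueError("baseline concentration and k_deg must be > 0")
    return k_deg * baseline_conc


@dataclass(frozen=True)
class ThrombinFeedbackParams:
    """Hill parameters of the thrombin-exposure production multiplier.

    m(E) = 1 + emax * E^hill / (ec50^hill + E^hill): equal to 1 with no
    exposure and saturating at 1 + emax.
    """

    emax: float = 0.0
    ec50: float = 1e-7  # mol/L-equivalent thrombin exposure scale
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.emax < 0:
            raise ValueError("emax must be >= 0")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill < 1:
            raise ValueError("hill must be >= 1")


def feedback_multiplier(exposure: float, params: ThrombinFeedbackParams) -> float:
    """Production multiplier m(E), bounded in [1, 1 + emax]."""
    if exposure <= 0 or params.emax == 0:
        return 1.0
    e_h = exposure ** params.hill
    return 1.0 + params.emax * e_h / (params.ec50 ** params.hill + e_h)


@dataclass(frozen=True)
class CytokineKinetics:
    """Turnover parameters of one cytokine; k_deg and p_basal are derived."""

    name: str
    half_life: float            # seconds
    baseline_conc: float        # mol/L
    feedback: ThrombinFeedbackParams = field(default_factory=ThrombinFeedbackParams)

    def __post_init__(self) -> None:
        if self.name not in CYTOKINES:
            raise ValueError(f"unknown cytokine {self.name!r}; known: {CYTOKINES}")
        if self.half_life <= 0 or self.baseline_conc <= 0:
            raise ValueError("half_life and baseline_conc must be > 0")

    @property
    def k_deg(self) -> float:
        return degradation_rate(self.half_life)

    @property
    def p_basal(self) -> float:
        return steady_state_production(self.baseline_conc, self.k_deg)


@dataclass(frozen=True)
class CytokineState:
    """Plasma cytokine concentrations, mol/L."""

    IL6: float
    IL1B: float
    TNFA: float

    def __post_init__(self) -> None:
        for c in CYTOKINES:
            if getattr(self, c) < 0:
                raise ValueError(f"{c} concentration must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.IL6, self.IL1B, self.TNFA], float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CytokineState":
        return cls(*np.maximum(np.asarray(arr, float), 0.0))

    def scaled(self, multipliers: dict[str, float]) -> "CytokineState":
        return CytokineState(*[getattr(self, c) * multipliers.get(c, 1.0)
                               for c in CYTOKINES])


def default_kinetics(
    baselines_pg_ml: dict[str, float] | None = None,
    il6_feedback: ThrombinFeedbackParams | None = None,
    tnfa_feedback: ThrombinFeedbackParams | None = None,
    il1b_feedback: ThrombinFeedbackParams | None = None,
) -> dict[str, CytokineKinetics]:
    """Default kinetics set: half-lives 1 h (IL-6, IL-1beta), 4.6 min (TNF-alpha).

    Thrombin feedback is applied to IL-6 and TNF-alpha (emax default 4:
    roughly 2-5 fold induction across the physiological thrombin-exposure
    range); IL-1beta feedback defaults to off (emax 0) but is configurable.
    """
    pg = dict(DEFAULT_BASELINES_PG_ML, **(baselines_pg_ml or {}))
    fb = {
        "IL6": il6_feedback or ThrombinFeedbackParams(emax=4.0, ec50=1e-7, hill=1.0),
        "TNFA": tnfa_feedback or ThrombinFeedbackParams(emax=4.0, ec50=1e-7, hill=1.0),
        "IL1B": il1b_feedback or ThrombinFeedbackParams(emax=0.0),
    }
    half_lives = {"IL6": HOUR, "IL1B": HOUR, "TNFA": 4.6 * 60.0}
    return {
        c: CytokineKinetics(
            c, half_lives[c],
            pg_per_ml_to_molar(pg[c], CYTOKINE_MW_G_PER_MOL[c]),
            fb[c])
        for c in CYTOKINES
    }


def baseline_state(kinetics: dict[str, CytokineKinetics]) -> CytokineState:
    return CytokineState(*[kinetics[c].baseline_conc for c in CYTOKINES])


def cytokine_rhs(
    state: np.ndarray,
    thrombin_exposure: float,
    kinetics: dict[str, CytokineKinetics],
) -> np.ndarray:
    """Derivatives dC/dt = p_basal * m(E) - k_deg * C for each cytokine."""
    out = np.empty(3)
    for i, c in enumerate(CYTOKINES):
        k = kinetics[c]
        m = feedback_multiplier(thrombin_exposure, k.feedback)
        out[i] = k.p_basal * m - k.k_deg * state[i]
    return out


def run_inflammation_phase(
    initial: CytokineState,
    duration: float,
    thrombin_exposure: float = 0.0,
    kinetics: dict[str, CytokineKinetics] | None = None,
    report_step: float = 60.0,
    clamp_floor: CytokineState | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-22,
) -> Trajectory:
    """Integrate the cytokine ODEs over ``duration`` seconds.

    ``thrombin_exposure`` is held constant for the whole phase: the
    coagulation burst is seconds-to-minutes fast while cytokine modulation
    evolves over hours, so the exposure carried over from the previous
    coagulation phase is treated as a frozen input, not a co-integrated
    variable.

    ``clamp_floor`` models sustained inflammatory stimulation: cytokine
    levels are not allowed to relax below the floor (elementwise max),
    while thrombin-driven production can still push them above it.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    kin = kinetics or default_kinetics()
    n_pts = max(int(round(duration / report_step)), 1)
    t_eval = np.linspace(0.0, duration, n_pts + 1)
    sol = solve_ivp(
        lambda t, y: cytokine_rhs(y, thrombin_exposure, kin),
        (0.0, duration),
        initial.as_array(),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise SimulationError(
            f"cytokine solver failed at t = {sol.t[-1] if sol.t.size else 0:.6g} s: "
            f"{sol.message}")
    conc = sol.y.T
    if clamp_floor is not None:
        conc = np.maximum(conc, clamp_floor.as_array()[None, :])
    return Trajectory(sol.t, conc, list(CYTOKINES))


def terminal_state(trajectory: Trajectory) -> CytokineState:
    return CytokineState.from_array(trajectory.concentrations[-1])
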