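"""Virtual-patient parameter container shared by the scheduler and cohorts."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .coagulation import PLASMA_FACTORS, mean_plasma_concentrations
from .inflammation import CytokineKinetics, CytokineState, default_kinetics

__all__ = ["PatientParameters", "normal_patient"]


@dataclass(frozen=True)
class PatientParameters:
    """One virtual patient: factor and cytokine concentrations in mol/L.

    ``disease``, ``sample_index`` and ``seed`` record provenance for
    cohort outputs.
    """

    factors: dict[str, float]
    cytokines: CytokineState
    disease: str = "Normal"
    sample_index: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        for f, v in self.factors.items():
            if f not in PLASMA_FACTORS:
                raise ValueError(f"unknown coagulation factor {f!r}")
            if v < 0:
                raise ValueError(f"factor {f} concentration must be >= 0")

    def with_cytokine_multipliers(self, multipliers: dict[str, float]) -> "PatientParameters":
        return replace(self, cytokines=self.cytokines.scaled(multipliers))


def normal_patient(
    kinetics: dict[str, CytokineKinetics] | None = None,
) -> PatientParameters:
    """Mean-plasma factors with baseline cytokines: the reference subject."""
    kin = kinetics or default_kinetics()
    return PatientParameters(
        factors=mean_plasma_concentrations(),
        cytokines=CytokineState(*[kin[c].baseline_conc for c in ("IL6", "IL1B", "TNFA")]),
        disease="Normal",
    )
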