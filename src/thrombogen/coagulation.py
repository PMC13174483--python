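"""TF-initiated coagulation cascade: model construction and readouts.

The cascade follows the Hockin-Mann extrinsic-pathway framework: tissue
factor (TF) complexes circulating VIIa, the TF=VIIa complex activates
factors X and IX, intrinsic tenase (IXa=VIIIa) and prothrombinase (Xa=Va)
amplify Xa and thrombin production, and the anticoagulants TFPI and ATIII
shut the cascade down. Rate constants and mean plasma concentrations ship
in ``data/coagulation_rates.yaml`` with per-constant provenance comments
and are fully editable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .network import (
    ConfigurationError,
    ConservationGroup,
    NetworkModel,
    Reaction,
    SolverOptions,
    Species,
    Trajectory,
    simulate,
)

__all__ = [
    "MOLECULAR_WEIGHTS_G_PER_MOL",
    "MEIZOTHROMBIN_WEIGHT",
    "PerturbationScenario",
    "SCENARIO_PRESETS",
    "load_rate_table",
    "mean_plasma_concentrations",
    "build_coagulation_model",
    "initial_state",
    "run_scenario",
    "total_thrombin",
    "atiii_iia_series",
]

#: Molecular weights (g/mol) used for mg/L -> mol/L conversion of factor
#: levels. Standard literature values; configurable because clinical tables
#: report mass concentrations.
MOLECULAR_WEIGHTS_G_PER_MOL: dict[str, float] = {
    "II": 72_000.0,
    "V": 330_000.0,
    "VII": 50_000.0,
    "VIIa": 50_000.0,
    "VIII": 330_000.0,
    "IX": 55_000.0,
    "X": 59_000.0,
    "ATIII": 58_000.0,
    "TFPI": 40_000.0,
}

#: Weight of meizothrombin in the total-thrombin readout IIa + w*mIIa
#: (the Hockin-lineage convention for meizothrombin's partial activity).
MEIZOTHROMBIN_WEIGHT = 1.2

#: Plasma factors a perturbation scenario may scale.
PLASMA_FACTORS = ("VII", "VIIa", "X", "IX", "II", "VIII", "V", "TFPI", "ATIII")

_TF_TRIGGER_25PM = 25e-12
_TF_TRIGGER_5PM = 5e-12


@dataclass(frozen=True)
class PerturbationScenario:
    """Per-factor multipliers on mean plasma levels plus the TF trigger."""

    multipliers: dict[str, float] = field(default_factory=dict)
    tf_trigger: float = _TF_TRIGGER_25PM
    name: str = "custom"

    def __post_init__(self) -> None:
        for f, m in self.multipliers.items():
            if f not in PLASMA_FACTORS:
                raise ConfigurationError(f"scenario {self.name!r}: unknown factor {f!r}")
            if m < 0:
                raise ConfigurationError(
                    f"scenario {self.name!r}: multiplier for {f} must be >= 0, got {m}"
                )
        if self.tf_trigger < 0:
            raise ConfigurationError("tf_trigger must be >= 0")

    def multiplier(self, factor: str) -> float:
        return self.multipliers.get(factor, 1.0)


_PROCOAG = {"II": 1.5, "V": 1.5, "VIII": 1.5, "IX": 1.5, "X": 1.5,
            "ATIII": 0.5, "TFPI": 0.5}
_ANTICOAG = {"II": 0.5, "V": 0.5, "VIII": 0.5, "IX": 0.5, "X": 0.5,
             "ATIII": 1.5, "TFPI": 1.5}

#: The seven calibration scenarios: 25 pM TF runs probing the anticoagulant
#: arms, and 5 pM TF runs probing procoagulant/anticoagulant dominance.
SCENARIO_PRESETS: dict[str, PerturbationScenario] = {
    "baseline25": PerturbationScenario({}, _TF_TRIGGER_25PM, "baseline25"),
    "no_atiii": PerturbationScenario({"ATIII": 0.0}, _TF_TRIGGER_25PM, "no_atiii"),
    "no_tfpi": PerturbationScenario({"TFPI": 0.0}, _TF_TRIGGER_25PM, "no_tfpi"),
    "no_atiii_tfpi": PerturbationScenario(
        {"ATIII": 0.0, "TFPI": 0.0}, _TF_TRIGGER_25PM, "no_atiii_tfpi"),
    "mean_plasma_5pM": PerturbationScenario({}, _TF_TRIGGER_5PM, "mean_plasma_5pM"),
    "procoagulant_dominant": PerturbationScenario(
        dict(_PROCOAG), _TF_TRIGGER_5PM, "procoagulant_dominant"),
    "anticoagulant_dominant": PerturbationScenario(
        dict(_ANTICOAG), _TF_TRIGGER_5PM, "anticoagulant_dominant"),
}


def load_rate_table() -> dict:
    """Raw reaction/rate/plasma table from the packaged YAML file."""
    text = resources.files("thrombogen.data").joinpath(
        "coagulation_rates.yaml").read_text()
    return yaml.safe_load(text)


def mean_plasma_concentrations() -> dict[str, float]:
    """Mean plasma factor concentrations (mol/L) from the shipped table."""
    return {k: float(v) for k, v in load_rate_table()["mean_plasma"].items()}


def build_coagulation_model(rate_table: dict | None = None) -> NetworkModel:
    """Assemble the cascade network with TF and prothrombin conservation groups.

    Species are inferred from the reaction inventory: zymogens present in
    plasma start at their mean plasma level, every intermediate at zero.
    """
    table = rate_table or load_rate_table()
    plasma = {k: float(v) for k, v in table["mean_plasma"].items()}

    names: list[str] = []
    for r in table["reactions"]:
        for s in (*r["reactants"], *r["products"]):
            if s not in names:
                names.append(s)
    if "TF" not in names:
        raise ConfigurationError("rate table defines no TF species")

    species = []
    for n in names:
        if "=" in n or n.endswith(("a1-L", "a2")) or n in ("IIa", "mIIa"):
            role = "complex" if "=" in n else "coagulation_factor"
        else:
            role = "coagulation_factor"
        species.append(Species(n, plasma.get(n, 0.0), role))

    reactions = [
        Reaction(tuple(r["reactants"]), tuple(r["products"]), float(r["k"]),
                 r.get("name", ""))
        for r in table["reactions"]
    ]

    tf_group = ConservationGroup(
        "total_TF", tuple((n, 1.0) for n in names if n == "TF" or n.startswith("TF=")))
    prothrombin_members = [n for n in ("II", "Xa=Va=II", "mIIa", "IIa",
                                       "mIIa=ATIII", "IIa=ATIII") if n in names]
    ii_group = ConservationGroup(
        "prothrombin_derived", tuple((n, 1.0) for n in prothrombin_members))

    return NetworkModel(species, reactions, [tf_group, ii_group], "coagulation")


def initial_state(
    scenario: PerturbationScenario,
    mean_plasma: dict[str, float] | None = None,
    model: NetworkModel | None = None,
) -> np.ndarray:
    """Initial concentration vector for a perturbation scenario.

    Each plasma factor starts at its mean plasma value times the scenario
    multiplier; every complex and activated intermediate starts at zero
    except VIIa, which circulates at a trace plasma level. TF equals the
    scenario trigger.
    """
    model = model or build_coagulation_model()
    plasma = mean_plasma or mean_plasma_concentrations()
    y0 = np.zeros(len(model.species))
    for factor, level in plasma.items():
        y0[model.index(factor)] = level * scenario.multiplier(factor)
    y0[model.index("TF")] = scenario.tf_trigger
    return y0


def run_scenario(
    scenario: PerturbationScenario | str,
    t_span: float = 1200.0,
    options: SolverOptions | None = None,
    model: NetworkModel | None = None,
    mean_plasma: dict[str, float] | None = None,
) -> Trajectory:
    """Simulate one perturbation scenario for ``t_span`` seconds (default 1,200)."""
    if isinstance(scenario, str):
        try:
            scenario = SCENARIO_PRESETS[scenario]
        except KeyError:
            raise ConfigurationError(
                f"unknown scenario preset {scenario!r}; "
                f"known: {sorted(SCENARIO_PRESETS)}") from None
    model = model or build_coagulation_model()
    y0 = initial_state(scenario, mean_plasma, model)
    return simulate(model, t_span, options, initial_state=y0)


def total_thrombin(
    trajectory: Trajectory, meizothrombin_weight: float = MEIZOTHROMBIN_WEIGHT
) -> np.ndarray:
    """Total thrombin activity series: IIa(t) + w * mIIa(t), mol/L."""
    return trajectory.series("IIa") + meizothrombin_weight * trajectory.series("mIIa")


def atiii_iia_series(trajectory: Trajectory) -> np.ndarray:
    """Thrombin-antithrombin complex (ATIII-IIa) series, mol/L.

    Complex formation is irreversible in the model, so this series is
    monotone nondecreasing and reflects the net amount of thrombin generated.
    """
    return trajectory.series("IIa=ATIII")
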