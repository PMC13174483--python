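"""Scenario configuration: schema-validated YAML/JSON in, resolved objects out.

A scenario file may override any block; omitted keys fall back to package
defaults. Unknown keys are rejected, and every failing key is reported in
one error, not just the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .coupling import CouplingParams, HillBlock, SuppressionBlock, default_coupling_params
from .inflammation import (
    CYTOKINES,
    CytokineKinetics,
    ThrombinFeedbackParams,
    default_kinetics,
)
from .scheduler import HOUR, PhaseProtocol

__all__ = ["ConfigError", "ScenarioConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Schema violation; the message lists every failing key."""


_FEEDBACK_KEYS = {"emax", "ec50", "hill"}
_HILL_KEYS = {"vmax", "ec50", "hill"}
_SUPP_KEYS = {"smax", "ec50", "hill"}

#: key -> (type check, human constraint) for flat numeric fields
_PROTOCOL_SCHEMA = {
    "inflam_duration_h": (lambda v: v > 0, "> 0"),
    "coag_duration_s": (lambda v: v > 0, "> 0"),
    "tf_trigger_pM": (lambda v: v >= 0, ">= 0"),
    "n_cycles": (lambda v: isinstance(v, int) and v >= 1, "integer >= 1"),
    "exposure_metric": (lambda v: v in ("ETP", "peak"), "one of ETP|peak"),
    "exposure_gain": (lambda v: v > 0, "> 0"),
    "sustained": (lambda v: isinstance(v, bool), "boolean"),
    "coupling_enabled": (lambda v: isinstance(v, bool), "boolean"),
}

_TOP_KEYS = {"seed", "scenario", "protocol", "cytokines", "coupling",
             "cohort", "output_dir"}


def _check_block(block: dict, allowed: set[str], path: str, errors: list[str]) -> None:
    for k in block:
        if k not in allowed:
            errors.append(f"{path}.{k}: unknown key")


@dataclass
class ScenarioConfig:
    """A fully resolved scenario: raw dict plus typed accessors."""

    raw: dict = field(default_factory=dict)

    @property
    def seed(self) -> int | None:
        return self.raw.get("seed")

    @property
    def scenario_name(self) -> str:
        return self.raw.get("scenario", "mean_plasma_5pM")

    @property
    def cohort_block(self) -> dict:
        return dict({"disease": "Normal", "n": 2000}, **self.raw.get("cohort", {}))

    def protocol(self) -> PhaseProtocol:
        p = self.raw.get("protocol", {})
        return PhaseProtocol(
            inflam_duration=p.get("inflam_duration_h", 12.0) * HOUR,
            coag_duration=p.get("coag_duration_s", 1200.0),
            tf_trigger=p.get("tf_trigger_pM", 5.0) * 1e-12,
            n_cycles=p.get("n_cycles", 1),
            exposure_metric=p.get("exposure_metric", "ETP"),
            exposure_gain=p.get("exposure_gain", 1.0 / 600.0),
            sustained=p.get("sustained", False),
            coupling_enabled=p.get("coupling_enabled", True),
        )

    def kinetics(self) -> dict[str, CytokineKinetics]:
        c = self.raw.get("cytokines", {})
        kin = default_kinetics(baselines_pg_ml=c.get("baselines_pg_ml"))
        half = c.get("half_lives_s", {})
        feed = c.get("feedback", {})
        out = {}
        for name, k in kin.items():
            fb = k.feedback
            if name in feed:
                fb = ThrombinFeedbackParams(
                    emax=feed[name].get("emax", fb.emax),
                    ec50=feed[name].get("ec50", fb.ec50),
                    hill=feed[name].get("hill", fb.hill))
            out[name] = CytokineKinetics(
                name, half.get(name, k.half_life), k.baseline_conc, fb)
        return out

    def coupling(self) -> CouplingParams:
        kin = self.kinetics()
        base = default_coupling_params(kin)
        c = self.raw.get("coupling", {})
        if not c:
            return base
        ind = dict(base.tf_induction)
        for name, blk in c.get("tf_induction", {}).items():
            ref = ind[name]
            ind[name] = HillBlock(blk.get("vmax", ref.vmax),
                                  blk.get("ec50", ref.ec50),
                                  blk.get("hill", ref.hill))
        def supp(key, ref):
            blk = c.get(key, {})
            return SuppressionBlock(blk.get("smax", ref.smax),
                                    blk.get("ec50", ref.ec50),
                                    blk.get("hill", ref.hill))
        return CouplingParams(
            tf_induction=ind,
            atiii_suppression=supp("atiii_suppression", base.atiii_suppression),
            tfpi_suppression=supp("tfpi_suppression", base.tfpi_suppression),
            tf_basal_production=c.get("tf_basal_production",
                                      base.tf_basal_production),
            tf_clearance_halflife=c.get("tf_clearance_halflife_h",
                                        base.tf_clearance_halflife / HOUR) * HOUR,
        )

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self.raw))  # deep copy, JSON-clean


def _validate(raw: dict) -> None:
    errors: list[str] = []
    _check_block(raw, _TOP_KEYS, "config", errors)

    if "seed" in raw and raw["seed"] is not None and not isinstance(raw["seed"], int):
        errors.append("config.seed: must be an integer")

    proto = raw.get("protocol", {})
    _check_block(proto, set(_PROTOCOL_SCHEMA), "protocol", errors)
    for k, (ok, constraint) in _PROTOCOL_SCHEMA.items():
        if k in proto:
            try:
                valid = ok(proto[k])
            except TypeError:
                valid = False
            if not valid:
                errors.append(f"protocol.{k}: must be {constraint}, got {proto[k]!r}")

    cyto = raw.get("cytokines", {})
    _check_block(cyto, {"baselines_pg_ml", "half_lives_s", "feedback"},
                 "cytokines", errors)
    for sub in ("baselines_pg_ml", "half_lives_s"):
        for k, v in cyto.get(sub, {}).items():
            if k not in CYTOKINES:
                errors.append(f"cytokines.{sub}.{k}: unknown cytokine")
            elif not isinstance(v, (int, float)) or v <= 0:
                errors.append(f"cytokines.{sub}.{k}: must be > 0, got {v!r}")
    for k, blk in cyto.get("feedback", {}).items():
        if k not in CYTOKINES:
            errors.append(f"cytokines.feedback.{k}: unknown cytokine")
        else:
            _check_block(blk, _FEEDBACK_KEYS, f"cytokines.feedback.{k}", errors)

    coup = raw.get("coupling", {})
    _check_block(coup, {"tf_induction", "atiii_suppression", "tfpi_suppression",
                        "tf_basal_production", "tf_clearance_halflife_h"},
                 "coupling", errors)
    for k, blk in coup.get("tf_induction", {}).items():
        if k not in CYTOKINES:
            errors.append(f"coupling.tf_induction.{k}: unknown cytokine")
        else:
            _check_block(blk, _HILL_KEYS, f"coupling.tf_induction.{k}", errors)
    for key in ("atiii_suppression", "tfpi_suppression"):
        _check_block(coup.get(key, {}), _SUPP_KEYS, f"coupling.{key}", errors)

    cohort = raw.get("cohort", {})
    _check_block(cohort, {"disease", "n"}, "cohort", errors)
    if "n" in cohort and (not isinstance(cohort["n"], int) or cohort["n"] < 1):
        errors.append(f"cohort.n: must be a positive integer, got {cohort['n']!r}")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _validate(raw)
    cfg = ScenarioConfig(raw)
    cfg.protocol()          # trigger constructor-level validation too
    cfg.kinetics()
    cfg.coupling()
    return cfg


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
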