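"""Deterministic synthetic fixtures: every module is testable without
external data.

Generators return analytic objects whose ground truth is known in closed
form — thrombin curves with exact TG metrics, toy reaction networks with
closed-form solutions, and monotone input-output tables for PRCC checks.
Regeneration from (name, params, seed) is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkModel, Reaction, Species

__all__ = ["make_fixture", "FIXTURE_GENERATORS"]


def triangle_curve(peak_nM: float = 100.0, tpk_s: float = 600.0,
                   t_end_s: float = 1200.0, n: int = 1201):
    """Piecewise-linear rise/fall thrombin curve.

    Exact metrics: peak = peak_nM, TTP = tpk_s, ETP = peak * t_end / 2,
    lag (relative 10% rule) = 0.1 * tpk_s.
    """
    t = np.linspace(0.0, t_end_s, n)
    peak = peak_nM * 1e-9
    up = peak * t / tpk_s
    down = peak * (t_end_s - t) / (t_end_s - tpk_s)
    return t, np.minimum(up, down)


def logistic_atiii_iia(center_s: float = 800.0, width_s: float = 60.0,
                       final_nM: float = 400.0, t_end_s: float = 1200.0,
                       n: int = 1201):
    """Sigmoid accumulation curve; 50%-of-final crossing ~ center_s.

    The logistic is rebased to start at exactly zero, which moves the true
    half-rise point slightly before center_s (by width * s0/(1+...) — well
    under one reporting step for center/width >= 10).
    """
    t = np.linspace(0.0, t_end_s, n)
    raw = 1.0 / (1.0 + np.exp(-(t - center_s) / width_s))
    raw -= raw[0]
    return t, final_nM * 1e-9 * raw / raw[-1]


def toy_network(kind: str = "decay", k: float = 0.1, a0: float = 1.0,
                b0: float = 0.0, k2: float = 0.05) -> NetworkModel:
    """Tiny networks with known solutions.

    * ``decay``: A -> B at rate k; A(t) = a0 * exp(-k t).
    * ``reversible``: A <-> B (k, k2); closed two-state relaxation.
    * ``bimolecular``: A + B -> C at rate k (1/(M s)); equal start a0:
      C(t) = a0^2 k t / (1 + a0 k t).
    """
    if kind == "decay":
        return NetworkModel(
            [Species("A", a0), Species("B", b0)],
            [Reaction(("A",), ("B",), k, "decay")],
            name="toy_decay")
    if kind == "reversible":
        return NetworkModel(
            [Species("A", a0), Species("B", b0)],
            [Reaction(("A",), ("B",), k, "fwd"), Reaction(("B",), ("A",), k2, "rev")],
            name="toy_reversible")
    if kind == "bimolecular":
        return NetworkModel(
            [Species("A", a0), Species("B", a0), Species("C", 0.0)],
            [Reaction(("A", "B"), ("C",), k, "bind")],
            name="toy_bimolecular")
    raise ValueError(f"unknown toy network kind {kind!r}")


def monotone_sa_dataset(n: int = 500, seed: int = 0, n_params: int = 3,
                        noise: float = 0.0):
    """Design matrix + output with known monotone structure for PRCC tests.

    y depends monotonically (and nonlinearly) on column 0 only; all other
    columns, including an implicit dummy, are independent uniforms.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, n_params))
    y = np.exp(2.0 * X[:, 0]) + noise * rng.normal(size=n)
    return X, y


FIXTURE_GENERATORS = {
    "triangle_curve": triangle_curve,
    "logistic_atiii_iia": logistic_atiii_iia,
    "toy_network": toy_network,
    "monotone_sa_dataset": monotone_sa_dataset,
}


def make_fixture(name: str, params: dict | None = None, seed: int | None = None):
    """Dispatch a fixture generator by name; unknown names error."""
    if name not in FIXTURE_GENERATORS:
        raise ValueError(
            f"unknown fixture generator {name!r}; known: {sorted(FIXTURE_GENERATORS)}")
    params = dict(params or {})
    if name == "monotone_sa_dataset" and seed is not None:
        params.setdefault("seed", seed)
    return FIXTURE_GENERATORS[name](**params)
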