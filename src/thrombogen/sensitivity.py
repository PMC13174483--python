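"""Global sensitivity analysis: Latin hypercube sampling with partial rank
correlation coefficients (PRCC) and a dummy-variable null control.

PRCC measures the monotone association between one input and one output
after removing the linear-in-ranks influence of every other input: both
the input column and the output are rank-transformed, each is residualized
against all other ranked inputs by least squares, and the Pearson
correlation of the two residual vectors is reported. A dummy input that
the model never sees is always appended; its PRCC magnitude estimates the
noise floor below which reported sensitivities are not meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .cohort import CYTOKINES, FACTOR_PARAMS, DiseaseSpec, sample_cohort
from .scheduler import PhaseProtocol, run_two_phase

__all__ = ["prcc", "SensitivityResult", "run_sensitivity", "DUMMY", "METRICS"]

DUMMY = "dummy"
METRICS = ("peak", "ttp", "lag", "etp")


def prcc(X: np.ndarray, y: np.ndarray,
         names: list[str] | None = None) -> dict[str, float]:
    """Partial rank correlation coefficient of each column of X with y.

    Ties receive average ranks. A constant column cannot be ranked against
    the rest of the design; its coefficient is reported as NaN with a
    warning rather than raising.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if n < p + 2:
        raise ValueError(f"need at least parameters+2 = {p + 2} samples, got {n}")
    names = names or [f"x{j}" for j in range(p)]

    Rx = np.column_stack([rankdata(X[:, j]) for j in range(p)])
    ry = rankdata(y)
    constant = np.array([np.ptp(X[:, j]) == 0 for j in range(p)])
    if constant.any():
        warnings.warn(
            f"constant parameter columns {[names[j] for j in np.flatnonzero(constant)]}: "
            "PRCC undefined, reported as NaN", stacklevel=2)

    out: dict[str, float] = {}
    for j in range(p):
        if constant[j]:
            out[names[j]] = float("nan")
            continue
        others = [k for k in range(p) if k != j and not constant[k]]
        A = np.column_stack([np.ones(n), Rx[:, others]])
        res_x = Rx[:, j] - A @ np.linalg.lstsq(A, Rx[:, j], rcond=None)[0]
        res_y = ry - A @ np.linalg.lstsq(A, ry, rcond=None)[0]
        denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
        out[names[j]] = float(res_x @ res_y / denom) if denom > 0 else float("nan")
    return out


@dataclass
class SensitivityResult:
    """PRCC table (parameters + dummy rows, metrics columns) with provenance."""

    prcc: pd.DataFrame
    n_samples: int
    seed: int | None
    disease: str
    n_failed: int = 0

    @property
    def dummy(self) -> pd.Series:
        return self.prcc.loc[DUMMY]

    def ranking(self, metric: str) -> list[tuple[str, float]]:
        """Factors ordered by |PRCC| for one metric, dummy excluded."""
        col = self.prcc[metric].drop(DUMMY).dropna()
        order = col.abs().sort_values(ascending=False).index
        return [(f, float(col[f])) for f in order]

    def to_long_frame(self) -> pd.DataFrame:
        df = self.prcc.reset_index(names="parameter")
        return df.melt(id_vars="parameter", var_name="metric", value_name="prcc")


def run_sensitivity(
    spec: DiseaseSpec,
    n: int = 200,
    protocol: PhaseProtocol | None = None,
    seed: int | None = None,
    max_failure_fraction: float = 0.01,
    **run_kwargs,
) -> SensitivityResult:
    """LHS-PRCC analysis of the TG metrics over a disease's parameter space.

    Draws an n-point Latin hypercube over the disease's coagulation and
    cytokine ranges, appends a uniform dummy column disconnected from the
    model, runs the two-phase protocol on every sample, and computes PRCC
    of each parameter against peak, TTP, lag and ETP.

    The scaled-down default n=200 resolves the dominant sign structure;
    the full 5,000-sample design is one ``n=5000`` away. Failed simulations
    are dropped with a count; if more than ``max_failure_fraction`` of the
    design fails, the run aborts.
    """
    protocol = protocol or PhaseProtocol()
    cohort = sample_cohort(spec, n, seed)
    dummy_rng = np.random.default_rng(
        None if seed is None else np.random.SeedSequence([seed, 0xD0]))
    # stratified like every other column, decoupled from the model
    dummy = qmc.LatinHypercube(d=1, seed=dummy_rng).random(n).ravel()

    params = list(FACTOR_PARAMS) + list(CYTOKINES)
    rows, outputs, failed = [], [], 0
    for patient, d in zip(cohort, dummy):
        try:
            res = run_two_phase(patient, protocol, **run_kwargs)
        except Exception:
            failed += 1
            continue
        m = res.metrics
        vec = [patient.factors[f] for f in FACTOR_PARAMS]
        vec += [getattr(patient.cytokines, c) for c in CYTOKINES]
        vec.append(d)
        rows.append(vec)
        outputs.append({"peak": m.peak, "ttp": m.time_to_peak,
                        "lag": m.lag_time, "etp": m.etp})
    if failed > max_failure_fraction * n:
        raise RuntimeError(
            f"{failed}/{n} simulations failed (> {max_failure_fraction:.0%}); aborting")

    X = np.array(rows)
    names = params + [DUMMY]
    table = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # point-mass disease columns are expected
        for metric in METRICS:
            y = np.array([o[metric] for o in outputs])
            ok = np.isfinite(y)
            table[metric] = prcc(X[ok], y[ok], names)
    df = pd.DataFrame(table, index=names)
    return SensitivityResult(df, n_samples=n, seed=seed,
                             disease=spec.disease, n_failed=failed)
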