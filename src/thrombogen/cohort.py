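"""Virtual-patient cohorts: disease parameter ranges, unit conversion,
Latin hypercube sampling, and TG-metric calibration.

The packaged disease table collects clinical laboratory ranges of nine
coagulation factors and three cytokines for Normal subjects and four
disease groups. Each cell is resolved into a bounded nonnegative sampling
distribution in mol/L, and cohorts are drawn with Latin hypercube
stratification: for each parameter, exactly one sample falls in each of
the n equal-probability strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.stats import qmc

from .coagulation import MOLECULAR_WEIGHTS_G_PER_MOL
from .inflammation import (
    CYTOKINE_MW_G_PER_MOL,
    CYTOKINES,
    CytokineKinetics,
    CytokineState,
    default_kinetics,
)
from .network import ConfigurationError
from .patients import PatientParameters
from .tg_metrics import TGMetrics

__all__ = [
    "DISEASES",
    "FACTOR_PARAMS",
    "to_molar",
    "ParameterDistribution",
    "DiseaseSpec",
    "load_disease_table",
    "disease_spec",
    "resolve_spec",
    "sample_cohort",
    "cohort_dataframe",
    "CalibrationWindow",
    "CalibrationResult",
    "calibrate_cohort",
]

DISEASES = ("COVID19", "T2DM", "SCD", "HemophiliaA", "Normal")
FACTOR_PARAMS = ("II", "V", "VII", "VIIa", "VIII", "IX", "X", "ATIII", "TFPI")
ALL_PARAMS = FACTOR_PARAMS + CYTOKINES

#: grams per liter for one unit of each supported mass-concentration string
_UNIT_G_PER_L = {
    "mg/L": 1e-3,
    "ng/ml": 1e-6,
    "ng/mL": 1e-6,
    "pg/ml": 1e-9,
    "pg/mL": 1e-9,
    "g/L": 1.0,
}


def to_molar(value: float, unit: str, mw_g_per_mol: float) -> float:
    """Unit-aware conversion to mol/L for pg/ml, ng/ml, mg/L (and mol/L).

    Mass concentrations divide by the molecular weight; a value already in
    mol/L passes through unchanged.
    """
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value}")
    if unit == "mol/L":
        return value
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be > 0")
    try:
        scale = _UNIT_G_PER_L[unit]
    except KeyError:
        raise ValueError(
            f"unknown unit {unit!r}; supported: "
            f"{sorted(_UNIT_G_PER_L)} or mol/L") from None
    return value * scale / mw_g_per_mol


def _mw(param: str) -> float:
    if param in MOLECULAR_WEIGHTS_G_PER_MOL:
        return MOLECULAR_WEIGHTS_G_PER_MOL[param]
    return CYTOKINE_MW_G_PER_MOL[param]


@dataclass(frozen=True)
class ParameterDistribution:
    """A resolved, bounded sampling distribution in mol/L.

    kinds: ``uniform``, ``loguniform``, ``truncnorm`` (mean +/- 3 SD,
    clipped at 0), ``point``.
    """

    kind: str
    low: float
    high: float
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.low < 0 or self.high < self.low:
            raise ConfigurationError(
                f"invalid bounds [{self.low}, {self.high}] for {self.kind}")
        if self.kind == "loguniform" and self.low <= 0:
            raise ConfigurationError("loguniform requires low > 0")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF on (0, 1); this is what LHS stratification feeds."""
        u = np.asarray(u, float)
        if self.kind == "point":
            return np.full_like(u, self.low)
        if self.kind == "uniform":
            return self.low + (self.high - self.low) * u
        if self.kind == "loguniform":
            return np.exp(np.log(self.low) + (np.log(self.high) - np.log(self.low)) * u)
        if self.kind == "truncnorm":
            a = (self.low - self.mean) / self.sd
            b = (self.high - self.mean) / self.sd
            return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)
        raise ConfigurationError(f"unknown distribution kind {self.kind!r}")

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.kind == "point":
            return (x >= self.low).astype(float)
        if self.kind == "uniform":
            return np.clip((x - self.low) / (self.high - self.low), 0, 1)
        if self.kind == "loguniform":
            return np.clip((np.log(x) - np.log(self.low))
                           / (np.log(self.high) - np.log(self.low)), 0, 1)
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.cdf(x, a, b, loc=self.mean, scale=self.sd)

    @property
    def is_degenerate(self) -> bool:
        return self.kind == "point" or self.high == self.low

    def narrowed(self, keep: str) -> "ParameterDistribution":
        """Halve the support, keeping the upper or lower half (calibration)."""
        if keep not in ("upper", "lower"):
            raise ValueError("keep must be 'upper' or 'lower'")
        if self.is_degenerate:
            return self
        if self.kind == "loguniform":
            mid = math.exp(0.5 * (math.log(self.low) + math.log(self.high)))
        else:
            mid = 0.5 * (self.low + self.high)
        lo, hi = (mid, self.high) if keep == "upper" else (self.low, mid)
        return replace(self, low=lo, high=hi)


@dataclass
class DiseaseSpec:
    """Per-parameter sampling distributions for one disease cohort."""

    disease: str
    distributions: dict[str, ParameterDistribution]

    def __post_init__(self) -> None:
        missing = set(ALL_PARAMS) - set(self.distributions)
        if missing:
            raise ConfigurationError(
                f"{self.disease}: missing parameters {sorted(missing)}")


def load_disease_table() -> dict:
    text = resources.files("thrombogen.data").joinpath(
        "disease_table.yaml").read_text()
    return yaml.safe_load(text)


def _resolve_cell(param: str, cell: dict,
                  kinetics: dict[str, CytokineKinetics]) -> ParameterDistribution:
    kind = cell["kind"]
    mw = _mw(param)
    if kind == "baseline":
        b = kinetics[param].baseline_conc
        return ParameterDistribution("point", b, b)
    unit = cell["unit"]
    if kind == "point":
        v = to_molar(float(cell["value"]), unit, mw)
        return ParameterDistribution("point", v, v)
    if kind == "range":
        lo = to_molar(float(cell["low"]), unit, mw)
        hi = to_molar(float(cell["high"]), unit, mw)
        if cell.get("log", False):
            return ParameterDistribution("loguniform", lo, hi)
        return ParameterDistribution("uniform", lo, hi)
    if kind == "percent_range":
        ref = to_molar(float(cell["ref"]), unit, mw)
        return ParameterDistribution(
            "uniform", ref * float(cell["low_pct"]) / 100.0,
            ref * float(cell["high_pct"]) / 100.0)
    if kind == "below_percent":
        ref = to_molar(float(cell["ref"]), unit, mw)
        return ParameterDistribution("uniform", 0.0, ref * float(cell["pct"]) / 100.0)
    if kind == "mean_sd":
        mean = to_molar(float(cell["mean"]), unit, mw)
        if "sd_percent" in cell:
            sd = mean * float(cell["sd_percent"]) / 100.0
        else:
            sd = to_molar(float(cell["sd"]), unit, mw)
        lo = max(mean - 3.0 * sd, 0.0)
        hi = mean + 3.0 * sd
        return ParameterDistribution("truncnorm", lo, hi, mean=mean, sd=sd)
    raise ConfigurationError(f"{param}: unknown descriptor kind {kind!r}")


def disease_spec(
    disease: str,
    kinetics: dict[str, CytokineKinetics] | None = None,
    table: dict | None = None,
) -> DiseaseSpec:
    """Resolve one disease's table row block into sampling distributions."""
    if table is None:
        table = load_disease_table()
    if disease not in table:
        raise ConfigurationError(
            f"unknown disease {disease!r}; known: {sorted(table)}")
    kin = kinetics or default_kinetics()
    dists = {p: _resolve_cell(p, cell, kin) for p, cell in table[disease].items()}
    return DiseaseSpec(disease, dists)


def resolve_spec(spec: DiseaseSpec) -> dict[str, tuple[float, float]]:
    """Per-parameter sampling intervals (mol/L bounds) of a resolved spec."""
    return {p: (d.low, d.high) for p, d in spec.distributions.items()}


def sample_cohort(
    spec: DiseaseSpec, n: int = 2000, seed: int | None = None
) -> list[PatientParameters]:
    """Draw an n-patient cohort by Latin hypercube sampling.

    Each parameter gets exactly one sample per equal-probability stratum;
    a fixed seed reproduces the cohort bit-identically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = list(spec.distributions)
    sampler = qmc.LatinHypercube(d=len(params), seed=seed)
    u = sampler.random(n)
    cols = {p: spec.distributions[p].ppf(u[:, j]) for j, p in enumerate(params)}
    patients = []
    for i in range(n):
        factors = {f: float(cols[f][i]) for f in FACTOR_PARAMS}
        cyto = CytokineState(*[float(cols[c][i]) for c in CYTOKINES])
        patients.append(PatientParameters(
            factors=factors, cytokines=cyto, disease=spec.disease,
            sample_index=i, seed=seed))
    return patients


def cohort_dataframe(cohort: list[PatientParameters]) -> pd.DataFrame:
    """One row per patient, molar units, with provenance columns."""
    rows = []
    for p in cohort:
        row = {"disease": p.disease, "sample_index": p.sample_index,
               "seed": p.seed, **p.factors}
        for c in CYTOKINES:
            row[c] = getattr(p.cytokines, c)
        rows.append(row)
    return pd.DataFrame(rows)


# -- calibration against TG-metric windows ----------------------------------

@dataclass(frozen=True)
class CalibrationWindow:
    """Acceptance intervals per TG metric; any metric may be left open."""

    lag_s: tuple[float, float] | None = None
    ttp_s: tuple[float, float] | None = None
    peak: tuple[float, float] | None = None       # mol/L
    etp: tuple[float, float] | None = None        # mol*s/L

    def __post_init__(self) -> None:
        for name in ("lag_s", "ttp_s", "peak", "etp"):
            iv = getattr(self, name)
            if iv is not None and iv[1] < iv[0]:
                raise ValueError(f"empty window for {name}: {iv}")

    def accepts(self, m: TGMetrics) -> bool:
        checks = [(self.lag_s, m.lag_time), (self.ttp_s, m.time_to_peak),
                  (self.peak, m.peak), (self.etp, m.etp)]
        for iv, v in checks:
            if iv is None:
                continue
            if not np.isfinite(v) or not iv[0] <= v <= iv[1]:
                return False
        return True

    def items(self):
        return [(n, iv) for n, iv in (("lag_s", self.lag_s), ("ttp_s", self.ttp_s),
                                      ("peak", self.peak), ("etp", self.etp))
                if iv is not None]


def _metric_value(m: TGMetrics, name: str) -> float:
    return {"lag_s": m.lag_time, "ttp_s": m.time_to_peak,
            "peak": m.peak, "etp": m.etp}[name]


@dataclass
class CalibrationResult:
    spec: DiseaseSpec
    cohort: list[PatientParameters]
    accepted: list[PatientParameters]
    acceptance_fraction: float
    n_iterations: int
    converged: bool
    diagnostics: list[str] = field(default_factory=list)


def calibrate_cohort(
    spec: DiseaseSpec,
    windows: CalibrationWindow,
    sensitivity_ranking: list[tuple[str, float]],
    metric_runner,
    n: int = 200,
    seed: int | None = None,
    target_fraction: float = 0.7,
    max_iterations: int = 8,
) -> CalibrationResult:
    """Narrow the ranges of the most influential factors until the cohort
    satisfies the TG-metric windows.

    ``sensitivity_ranking`` is a list of (factor, PRCC) pairs ordered by
    influence on the driving metric (from the sensitivity module); only the
    top three adjustable factors are touched. Each iteration bisects their
    ranges toward the half that moves the offending median metric into its
    window: the kept half is chosen from the PRCC sign and the direction of
    the miss. ``metric_runner`` maps a patient to TGMetrics.

    If the windows stay unreachable after ``max_iterations``, the result
    reports failure with diagnostics instead of silently clipping.
    """
    top3 = [(f, s) for f, s in sensitivity_ranking
            if f in FACTOR_PARAMS and not spec.distributions[f].is_degenerate][:3]
    if not top3:
        raise ConfigurationError("no adjustable factors in sensitivity ranking")

    spec = DiseaseSpec(spec.disease, dict(spec.distributions))
    diagnostics: list[str] = []
    best: tuple[float, list, list] = (-1.0, [], [])

    for it in range(max_iterations + 1):
        cohort = sample_cohort(spec, n, seed if seed is None else seed + it)
        metrics = [metric_runner(p) for p in cohort]
        accepted = [p for p, m in zip(cohort, metrics) if windows.accepts(m)]
        frac = len(accepted) / n
        if frac > best[0]:
            best = (frac, cohort, accepted)
        if frac >= target_fraction:
            diagnostics.append(f"iteration {it}: acceptance {frac:.2f} >= target")
            return CalibrationResult(spec, cohort, accepted, frac, it, True,
                                     diagnostics)

        # Which window is missed the worst, relative to its width?
        worst_name, worst_dir, worst_score = None, 0.0, 0.0
        for name, (lo, hi) in windows.items():
            vals = np.array([_metric_value(m, name) for m in metrics])
            med = float(np.nanmedian(vals))
            width = max(hi - lo, 1e-300)
            if med < lo:
                score, direction = (lo - med) / width, +1.0
            elif med > hi:
                score, direction = (med - hi) / width, -1.0
            else:
                continue
            if score > worst_score:
                worst_name, worst_dir, worst_score = name, direction, score
        if worst_name is None:
            diagnostics.append(
                f"iteration {it}: medians inside all windows but acceptance "
                f"{frac:.2f} < target (spread too wide for range bisection)")
            break

        diagnostics.append(
            f"iteration {it}: acceptance {frac:.2f}; median {worst_name} off by "
            f"{worst_score:.2f} window-widths, shifting top factors")
        new_dists = dict(spec.distributions)
        for factor, prcc in top3:
            keep = "upper" if prcc * worst_dir > 0 else "lower"
            new_dists[factor] = new_dists[factor].narrowed(keep)
        spec = DiseaseSpec(spec.disease, new_dists)

    diagnostics.append(
        f"window unreachable within physiological bounds after "
        f"{max_iterations} iterations; best acceptance {best[0]:.2f}")
    return CalibrationResult(spec, best[1], best[2], best[0],
                             max_iterations, False, diagnostics)
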