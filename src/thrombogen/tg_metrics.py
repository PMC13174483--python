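"""Thrombin-generation assay metrics.

Summarizes a thrombin curve by the four standard TG-assay readouts: lag
time, time-to-peak (TTP), peak thrombin and endogenous thrombin potential
(ETP, the time integral of the curve over the simulated horizon).

The lag-time rule is configurable: ``relative`` (default) is the earliest
time the curve exceeds 10% of its eventual peak; ``absolute`` is the
earliest time it exceeds a fixed 2 nM threshold, the common experimental
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["TGMetrics", "compute_tg_metrics", "transition_time_50"]

#: Sentinel for lag/TTP when the curve never rises (all-zero input).
UNDEFINED_TIME = float("nan")

ABSOLUTE_LAG_THRESHOLD = 2e-9  # 2 nM, mol/L
RELATIVE_LAG_FRACTION = 0.1


@dataclass(frozen=True)
class TGMetrics:
    """lag_time, time_to_peak (s), peak (mol/L), etp (mol*s/L)."""

    lag_time: float
    time_to_peak: float
    peak: float
    etp: float
    lag_rule: str = "relative"

    def as_dict(self) -> dict[str, float]:
        return {
            "lag_s": self.lag_time,
            "ttp_s": self.time_to_peak,
            "peak_nM": self.peak * 1e9,
            "etp_nM_s": self.etp * 1e9,
            "lag_rule": self.lag_rule,
        }


def _crossing_time(times: np.ndarray, curve: np.ndarray, threshold: float) -> float:
    """Earliest time the curve reaches ``threshold``, linearly interpolated."""
    above = np.nonzero(curve >= threshold)[0]
    if above.size == 0:
        return UNDEFINED_TIME
    i = above[0]
    if i == 0 or curve[i] == curve[i - 1]:
        return float(times[i])
    frac = (threshold - curve[i - 1]) / (curve[i] - curve[i - 1])
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def compute_tg_metrics(
    times: np.ndarray,
    thrombin: np.ndarray,
    lag_rule: str = "relative",
) -> TGMetrics:
    """TG metrics of one thrombin curve (times s, thrombin mol/L).

    An all-zero curve yields peak = etp = 0 with lag/TTP as NaN sentinels
    and a warning, not an exception.
    """
    times = np.asarray(times, float)
    thrombin = np.asarray(thrombin, float)
    if times.size == 0:
        raise ValueError("empty thrombin curve")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if lag_rule not in ("relative", "absolute"):
        raise ValueError(f"unknown lag rule {lag_rule!r}")

    peak = float(thrombin.max(initial=0.0))
    etp = float(np.trapezoid(thrombin, times)) if times.size > 1 else 0.0
    if peak <= 0.0:
        warnings.warn("thrombin curve never rises; lag and TTP are undefined",
                      stacklevel=2)
        return TGMetrics(UNDEFINED_TIME, UNDEFINED_TIME, 0.0, max(etp, 0.0), lag_rule)

    ttp = float(times[int(np.argmax(thrombin))])
    threshold = (RELATIVE_LAG_FRACTION * peak if lag_rule == "relative"
                 else ABSOLUTE_LAG_THRESHOLD)
    lag = _crossing_time(times, thrombin, threshold)
    return TGMetrics(lag, ttp, peak, etp, lag_rule)


def transition_time_50(
    times: np.ndarray,
    series: np.ndarray,
    monotone_tol: float = 1e-6,
) -> float:
    """Earliest time a nondecreasing series reaches 50% of its final value.

    Linearly interpolated between samples. The series must be monotone
    nondecreasing within ``monotone_tol`` (relative to its final value);
    used on ATIII-IIa accumulation curves, whose sigmoidal rise marks the
    thrombin burst.
    """
    times = np.asarray(times, float)
    series = np.asarray(series, float)
    if times.size < 2:
        raise ValueError("need at least two samples")
    final = series[-1]
    if final <= 0:
        raise ValueError("series must end above zero")
    drops = np.diff(series)
    if np.any(drops < -monotone_tol * final):
        worst = float(np.min(drops))
        raise ValueError(
            f"series is not monotone nondecreasing (worst step {worst:.3g})")
    return _crossing_time(times, np.maximum.accumulate(series), 0.5 * final)
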