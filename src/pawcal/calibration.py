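"""Aequorin luminescence -> cytosolic Ca2+ calibration.

Aequorin is consumed irreversibly as it emits light, so the instantaneous
fractional consumption rate

    k(t) = L(t) / L_remaining(t)        [s^-1]

(luminescence rate divided by the total luminescence the well can still emit)
is independent of expression level and detector gain and maps monotonically to
[Ca2+].  The terminal discharge (1 M CaCl2 / 30% ethanol) saturates the
reporter and empties the pool, which is what makes ``L_remaining`` computable
as a tail sum over the recorded counts.

The empirical calibration curve used here is the standard one for plant
cytosolic aequorin,

    pCa = slope * (-log10 k) + intercept ,   [Ca2+] = 10**(-pCa),

with slope 0.332588 and intercept 5.5593 by default.  Both constants are
configuration, not physics: any recalibrated curve can be swapped in through
:class:`CalibrationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "CalibrationError",
    "CalibrationParams",
    "LuminescenceTrace",
    "CalciumTrace",
    "remaining_pool",
    "rate_constant",
    "calibrate",
    "inverse_calibrate",
    "calibrate_trace",
]


class CalibrationError(ValueError):
    """Raised when a trace cannot be calibrated (e.g. no discharge counts)."""


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of the empirical aequorin calibration curve.

    Parameters
    ----------
    slope, intercept
        Coefficients of ``pCa = slope * (-log10 k) + intercept``.
    k_floor
        Rate-constant floor (s^-1) substituted for zero-count samples so that
        calibrated traces stay on the full time grid.
    background
        Constant per-window background counts subtracted before any ratio is
        formed.  Default 0 (no background handling).
    """

    slope: float = 0.332588
    intercept: float = 5.5593
    k_floor: float = 1e-6
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.k_floor <= 0:
            raise ValueError("k_floor must be > 0")


@dataclass
class LuminescenceTrace:
    """Raw photon counts for one well.

    ``counts[i]`` is the number of photons integrated over
    ``integration_window`` seconds around ``times[i]``.  ``discharge_time``
    marks the injection of the discharge solution; samples at or after it
    belong to the terminal pool-consumption phase and are required for
    calibration.
    """

    well_id: str
    times: np.ndarray
    counts: np.ndarray
    integration_window: float
    stimulus_time: float
    discharge_time: float
    flags: set = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape or self.times.ndim != 1:
            raise ValueError("times and counts must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be strictly increasing (well {self.well_id})")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.discharge_time is None or not np.isfinite(self.discharge_time):
            raise CalibrationError(
                f"well {self.well_id}: discharge_time is required for calibration"
            )
        if self.integration_window <= 0:
            raise ValueError("integration_window must be > 0")


@dataclass
class CalciumTrace:
    """Calibrated cytosolic [Ca2+] (molar) on the pre-discharge time grid."""

    well_id: str
    times: np.ndarray
    ca: np.ndarray
    provenance: CalibrationParams | None = None
    flags: set = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if self.times.shape != self.ca.shape or self.times.ndim != 1:
            raise ValueError("times and ca must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ca <= 0):
            raise ValueError("ca must be strictly positive (molar)")


def _net_counts(trace: LuminescenceTrace, params: CalibrationParams) -> np.ndarray:
    return trace.counts - params.background


def remaining_pool(
    trace: LuminescenceTrace, params: CalibrationParams | None = None
) -> np.ndarray:
    """Per-sample remaining luminescence: tail sum of background-subtracted counts.

    ``remaining[i]`` is the total light the well emits from sample ``i``
    (inclusive) to the end of the run.  Because the discharge empties the
    pool, this is the denominator of the aequorin rate constant.
    """
    params = params or CalibrationParams()
    net = _net_counts(trace, params)
    remaining = np.cumsum(net[::-1])[::-1]
    if remaining[0] <= 0:
        raise CalibrationError(
            f"well {trace.well_id}: total counts <= 0 after background subtraction"
        )
    return remaining


def rate_constant(
    trace: LuminescenceTrace, params: CalibrationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Aequorin consumption rate k (s^-1) for every pre-discharge sample.

    Returns ``(times, k)`` restricted to samples strictly before
    ``discharge_time``.  ``k = (counts / integration_window) / remaining``;
    zero-count samples (and any sample where the ratio would be <= 0) are
    floored at ``params.k_floor``.
    """
    params = params or CalibrationParams()
    remaining = remaining_pool(trace, params)
    pre = trace.times < trace.discharge_time
    net = _net_counts(trace, params)[pre]
    rem = remaining[pre]
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (net / trace.integration_window) / rem
    k = np.where((net <= 0) | (rem <= 0) | ~np.isfinite(k), params.k_floor, k)
    k = np.maximum(k, params.k_floor)
    return trace.times[pre], k


def calibrate(k, params: CalibrationParams | None = None):
    """Map rate constant(s) k (s^-1) to [Ca2+] (molar); strictly increasing in k."""
    params = params or CalibrationParams()
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("k must be strictly positive; apply the floor upstream")
    pca = params.slope * (-np.log10(k)) + params.intercept
    return 10.0 ** (-pca)


def inverse_calibrate(ca, params: CalibrationParams | None = None):
    """Exact algebraic inverse of :func:`calibrate`: [Ca2+] (molar) -> k (s^-1)."""
    params = params or CalibrationParams()
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca must be strictly positive")
    pca = -np.log10(ca)
    return 10.0 ** (-(pca - params.intercept) / params.slope)


def calibrate_trace(
    trace: LuminescenceTrace, params: CalibrationParams | None = None
) -> CalciumTrace:
    """Full calibration of one well: tail sum -> rate constant -> [Ca2+].

    The output is truncated at ``discharge_time`` (the discharge phase carries
    no physiological signal) and records the parameters used.
    """
    params = params or CalibrationParams()
    times, k = rate_constant(trace, params)
    ca = calibrate(k, params)
    return CalciumTrace(
        well_id=trace.well_id,
        times=times,
        ca=ca,
        provenance=params,
        flags=set(trace.flags),
        metadata=dict(trace.metadata),
    )
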