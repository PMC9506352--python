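"""Ca2+-signature metrics: peak, onset delay, rise slope, integrated dynamics.

A "Ca2+ signature" is the stimulus-specific kinetic shape of a cytosolic Ca2+
change.  The metrics extracted here are the ones used to compare treatments:

* peak [Ca2+] and its time within an analysis epoch;
* onset delay — time from stimulus to the first sustained crossing of
  baseline + 3 pre-stimulus standard deviations;
* rise slope — least-squares slope of [Ca2+] vs time from onset to peak;
* integrated dynamics (AUC) — trapezoidal integral of the [Ca2+] values over
  a fixed window (30 or 45 min), *without* baseline subtraction;
* baseline — mean [Ca2+] over the 60 s preceding the stimulus.

Two-dose protocols are handled by splitting the trace into one epoch per
injection, each with its own local baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalciumTrace

__all__ = [
    "Epoch",
    "SignatureMetrics",
    "baseline",
    "pre_stimulus_sd",
    "peak",
    "onset_delay",
    "rise_slope",
    "integrate",
    "compute_metrics",
    "two_dose_analysis",
]

BASELINE_WINDOW = 60.0  # s before the stimulus used for baseline statistics
ONSET_THRESHOLD_SD = 3.0
ONSET_PERSISTENCE = 2  # consecutive samples required above threshold


@dataclass(frozen=True)
class Epoch:
    """One analysis window: a stimulus time and the end of its window."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("epoch start must precede end")


@dataclass
class SignatureMetrics:
    """All signature metrics for one trace within one epoch."""

    label: str
    peak_ca: float          # M
    peak_time: float        # s (absolute)
    onset_delay: float      # s from epoch start
    rise_slope: float       # M/s
    auc: float              # M*s
    window: float           # s, integration window actually applied
    baseline_ca: float      # M
    flags: set = field(default_factory=set)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "flags"}
        d["flags"] = ";".join(sorted(self.flags))
        return d


def _pre_window(trace: CalciumTrace, epoch: Epoch) -> np.ndarray:
    sel = (trace.times >= epoch.start - BASELINE_WINDOW) & (trace.times < epoch.start)
    if sel.sum() < 3:
        sel = trace.times < epoch.start
    if not sel.any():
        raise ValueError("no pre-stimulus samples available for baseline")
    return trace.ca[sel]


def baseline(trace: CalciumTrace, epoch: Epoch) -> float:
    """Mean [Ca2+] over the 60 s preceding the epoch start."""
    return float(np.mean(_pre_window(trace, epoch)))


def pre_stimulus_sd(trace: CalciumTrace, epoch: Epoch) -> float:
    """Standard deviation of the pre-stimulus window (ddof=1 when possible)."""
    w = _pre_window(trace, epoch)
    return float(np.std(w, ddof=1)) if w.size > 1 else 0.0


def _epoch_mask(trace: CalciumTrace, epoch: Epoch) -> np.ndarray:
    return (trace.times >= epoch.start) & (trace.times <= epoch.end)


def peak(trace: CalciumTrace, epoch: Epoch) -> tuple[float, float]:
    """Maximum [Ca2+] in the epoch and its time; ties go to the earliest sample."""
    sel = _epoch_mask(trace, epoch)
    if not sel.any():
        raise ValueError("epoch contains no samples")
    ca, t = trace.ca[sel], trace.times[sel]
    i = int(np.argmax(ca))  # argmax returns the first maximum
    return float(ca[i]), float(t[i])


def _onset_index(
    trace, epoch, threshold_sd: float = ONSET_THRESHOLD_SD
) -> tuple[int | None, set]:
    """Index (into the full trace) of onset, or None if never crossed."""
    flags: set = set()
    base = baseline(trace, epoch)
    sd = pre_stimulus_sd(trace, epoch)
    if sd > 0:
        threshold = base + threshold_sd * sd
    else:
        threshold = base * 1.05
        flags.add("relative_onset_threshold")
    sel = np.flatnonzero(_epoch_mask(trace, epoch))
    above = trace.ca[sel] > threshold
    for j in range(len(sel) - ONSET_PERSISTENCE + 1):
        if above[j : j + ONSET_PERSISTENCE].all():
            return int(sel[j]), flags
    flags.add("onset_censored")
    return None, flags


def onset_delay(
    trace: CalciumTrace, epoch: Epoch, threshold_sd: float = ONSET_THRESHOLD_SD
) -> tuple[float, set]:
    """Delay (s) from epoch start to the first sustained threshold crossing.

    The threshold is baseline + ``threshold_sd`` pre-stimulus standard
    deviations, and must be exceeded by ``ONSET_PERSISTENCE`` consecutive
    samples.  Non-responding traces return the censored value ``end - start``
    with an ``onset_censored`` flag so group statistics stay computable.
    Returns ``(delay, flags)``.
    """
    idx, flags = _onset_index(trace, epoch, threshold_sd)
    if idx is None:
        return epoch.end - epoch.start, flags
    return float(trace.times[idx] - epoch.start), flags


def rise_slope(trace: CalciumTrace, epoch: Epoch) -> float:
    """Least-squares slope (M/s) of [Ca2+] vs time from onset to peak sample."""
    idx, _ = _onset_index(trace, epoch)
    if idx is None:
        return 0.0
    _, peak_t = peak(trace, epoch)
    sel = (trace.times >= trace.times[idx]) & (trace.times <= peak_t)
    t, ca = trace.times[sel], trace.ca[sel]
    if t.size < 2:
        return 0.0
    return float(np.polyfit(t, ca, 1)[0])


def integrate(trace: CalciumTrace, epoch: Epoch, window: float) -> float:
    """Trapezoidal integral (M*s) of the [Ca2+] values over [start, start+window].

    No baseline subtraction: the integrated quantity is the [Ca2+] value
    itself, and the integration stops at the epoch end if that comes first.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    stop = min(epoch.start + window, epoch.end)
    sel = (trace.times >= epoch.start) & (trace.times <= stop)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 samples in the integration window")
    return float(np.trapezoid(trace.ca[sel], trace.times[sel]))


def compute_metrics(trace: CalciumTrace, epoch: Epoch, window: float) -> SignatureMetrics:
    """All signature metrics for one epoch of one calibrated trace."""
    base = baseline(trace, epoch)
    pk, pk_t = peak(trace, epoch)
    delay, flags = onset_delay(trace, epoch)
    slope = rise_slope(trace, epoch)
    applied = min(window, epoch.end - epoch.start)
    auc = integrate(trace, epoch, window)
    return SignatureMetrics(
        label=epoch.label,
        peak_ca=pk,
        peak_time=pk_t,
        onset_delay=delay,
        rise_slope=slope,
        auc=auc,
        window=applied,
        baseline_ca=base,
        flags=flags,
    )


def two_dose_analysis(
    trace: CalciumTrace, dose_times: list[float], window: float
) -> list[SignatureMetrics]:
    """Per-dose signature metrics for consecutive-treatment protocols.

    Each injection opens an epoch ending at the next injection (or the end of
    the trace), so epochs never overlap; every epoch's baseline comes from
    the 60 s preceding its own injection.
    """
    if sorted(dose_times) != list(dose_times):
        raise ValueError("dose_times must be increasing")
    bounds = list(dose_times) + [float(trace.times[-1])]
    out = []
    for i, start in enumerate(dose_times):
        epoch = Epoch(label=f"dose{i + 1}", start=start, end=bounds[i + 1])
        out.append(compute_metrics(trace, epoch, window))
    return out
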