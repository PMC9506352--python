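"""Synthetic ground truth: Ca2+ kinetics, luminescence plate runs, temperature logs.

Every downstream stage (calibration, signature metrics, thermal fitting, group
statistics) is validated against data produced here, because the assay has no
deposited raw datasets.  The generator emulates the three measurement channels
of the experiment:

* cytosolic Ca2+ trajectories — a phenomenological double-exponential
  transient (fast rise, slower decay, "quickly dissipated" regime) plus a
  saturating-exponential sustained term (prolonged-exposure regime);
* aequorin luminescence — photon counts per 500 ms integration window every
  5 s, Poisson-distributed, from a finite reporter pool consumed at the
  Ca2+-dependent rate given by the inverse calibration curve, terminated by a
  discharge injection that empties the pool;
* water temperature during/after plasma activation — the closed-form
  heat-transport solution with i.i.d. Gaussian measurement noise.

Dose structure for whole experiments follows a saturating law
``AUC_true = AUC_max * E / (E + E_half)`` in the transferred energy per unit
mass E, so the saturating dose–response shape is recoverable by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .calibration import (
    CalibrationParams,
    CalciumTrace,
    LuminescenceTrace,
    inverse_calibrate,
)
from .thermal import TemperatureSeries, ThermalParams, solve_temperature

__all__ = [
    "CaKinetics",
    "AequorinPool",
    "PlateRunConfig",
    "TreatmentSpec",
    "ExperimentDesign",
    "PlateRun",
    "make_ca_trajectory",
    "make_luminescence",
    "make_temperature_series",
    "make_experiment",
    "transient_peak_time",
    "saturating_auc",
]

#: [Ca2+] imposed by the discharge solution (1 M CaCl2 / ethanol saturates
#: aequorin; the exact value is irrelevant once the consumption rate is large).
DISCHARGE_CA = 1e-4


@dataclass(frozen=True)
class CaKinetics:
    """Phenomenological parameters of one Ca2+ trajectory (concentrations molar, times s).

    The post-stimulus trajectory is

        Ca(t) = baseline
              + transient_amplitude * norm * (exp(-dt/decay_tau) - exp(-dt/rise_tau))
              + sustained_amplitude * (1 - exp(-dt/sustained_tau)),

    dt = t - stimulus_time, with ``norm`` chosen so the double exponential
    peaks at exactly 1.  Defaults describe the short-exposure (transient)
    regime with a typical plant resting baseline of 1e-7 M.
    """

    baseline: float = 1e-7
    transient_amplitude: float = 4e-7
    rise_tau: float = 15.0
    decay_tau: float = 90.0
    sustained_amplitude: float = 0.0
    sustained_tau: float = 300.0
    stimulus_time: float = 100.0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.transient_amplitude < 0 or self.sustained_amplitude < 0:
            raise ValueError("concentrations must be >= 0")
        if self.baseline > 1e-6:
            raise ValueError("baseline above the resting range (<= 1e-6 M)")
        if min(self.rise_tau, self.decay_tau, self.sustained_tau) <= 0:
            raise ValueError("time constants must be > 0")
        if self.rise_tau == self.decay_tau:
            raise ValueError("rise_tau must differ from decay_tau (degenerate transient)")


def transient_peak_time(kinetics: CaKinetics) -> float:
    """Closed-form argmax of the double-exponential transient (absolute time)."""
    r, d = kinetics.rise_tau, kinetics.decay_tau
    return kinetics.stimulus_time + np.log(d / r) * (r * d) / (d - r)


def _transient_norm(kinetics: CaKinetics) -> float:
    r, d = kinetics.rise_tau, kinetics.decay_tau
    tstar = np.log(d / r) * (r * d) / (d - r)
    peak = np.exp(-tstar / d) - np.exp(-tstar / r)
    return 1.0 / peak


def make_ca_trajectory(kinetics: CaKinetics, times) -> CalciumTrace:
    """Evaluate the ground-truth trajectory on a strictly increasing time grid."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be 1-D and strictly increasing")
    if t[0] >= kinetics.stimulus_time:
        raise ValueError("time grid must start before the stimulus")
    dt = t - kinetics.stimulus_time
    post = dt > 0
    ca = np.full_like(t, kinetics.baseline)
    dtp = dt[post]
    transient = (
        kinetics.transient_amplitude
        * _transient_norm(kinetics)
        * (np.exp(-dtp / kinetics.decay_tau) - np.exp(-dtp / kinetics.rise_tau))
    )
    sustained = kinetics.sustained_amplitude * (1.0 - np.exp(-dtp / kinetics.sustained_tau))
    # both tau orderings give a non-negative normalized transient
    ca[post] = kinetics.baseline + transient + sustained
    return CalciumTrace(
        well_id="truth",
        times=t,
        ca=ca,
        provenance=None,
        metadata={"synthetic": True, "kinetics": asdict(kinetics)},
    )


@dataclass(frozen=True)
class AequorinPool:
    """Finite reporter budget: total integrated counts the well can emit."""

    initial_counts: float = 1e7
    consumed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_counts <= 0:
            raise ValueError("initial_counts must be > 0")
        if not 0.0 <= self.consumed_fraction <= 1.0:
            raise ValueError("consumed_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlateRunConfig:
    """Plate-reader protocol: 500 ms integration every 5 s, stimulus at 100 s."""

    n_wells: int = 6
    sampling_interval: float = 5.0
    integration_window: float = 0.5
    stimulus_time: float = 100.0
    run_duration: float = 2000.0
    discharge_time: float = 1950.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.integration_window > self.sampling_interval:
            raise ValueError("integration_window must not exceed sampling_interval")
        if not (self.stimulus_time < self.discharge_time < self.run_duration):
            raise ValueError("require stimulus_time < discharge_time < run_duration")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.run_duration + 1e-9, self.sampling_interval)


def make_luminescence(
    ca: CalciumTrace,
    pool: AequorinPool,
    config: PlateRunConfig,
    seed: int,
    calibration: CalibrationParams | None = None,
    well_id: str | None = None,
) -> LuminescenceTrace:
    """Forward-model a Ca2+ trajectory into Poisson photon counts.

    Per sample the consumption rate is k = inverse_calibrate(Ca); the pool is
    depleted by the exact exponential decrement exp(-k*w) over the photon
    collection exposure w (the integration window), and the expected counts
    collected are pool * (1 - exp(-k*w)) — equal to k * pool * w to first
    order.  Keeping depletion and collection on the same clock makes the
    forward model the exact inverse of the tail-sum calibration: the sum of
    all emitted counts equals the initial pool once the discharge (a Ca2+
    step to 1e-4 M) has consumed it.
    """
    calibration = calibration or CalibrationParams()
    times = config.time_grid()
    if ca.times[0] > times[0] + 1e-9 or ca.times[-1] < times[-1] - 1e-9:
        raise ValueError("ca trajectory must cover [0, run_duration]")
    ca_s = np.interp(times, ca.times, ca.ca)
    ca_s = np.where(times >= config.discharge_time, np.maximum(ca_s, DISCHARGE_CA), ca_s)
    k = inverse_calibrate(ca_s, calibration)

    w = config.integration_window
    decrement = np.exp(-k * w)
    # pool remaining at the start of each sample (exact telescoping product)
    pool_remaining = pool.initial_counts * np.concatenate(
        ([1.0], np.cumprod(decrement[:-1]))
    )
    expected = pool_remaining * (1.0 - decrement)

    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)

    flags: set = set()
    pre = times < config.discharge_time
    if pool_remaining[pre][-1] < 0.01 * pool.initial_counts:
        flags.add("pool_exhausted_before_discharge")

    return LuminescenceTrace(
        well_id=well_id or ca.well_id,
        times=times,
        counts=counts,
        integration_window=w,
        stimulus_time=config.stimulus_time,
        discharge_time=config.discharge_time,
        flags=flags,
        metadata=dict(ca.metadata),
    )


def make_temperature_series(
    truth: ThermalParams,
    times,
    noise_sd: float,
    seed: int,
    activation_time: float,
) -> TemperatureSeries:
    """Heating then free decay with Gaussian measurement noise (seeded)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    temps = np.empty_like(t)
    heat = t <= activation_time
    temps[heat] = solve_temperature(truth, t[heat])
    if np.any(~heat):
        T_act = float(solve_temperature(truth, np.array([activation_time]))[0])
        cooling = replace(truth, Pin=0.0, T0=T_act)
        temps[~heat] = solve_temperature(cooling, t[~heat] - activation_time)
    rng = np.random.default_rng(seed)
    temps = temps + rng.normal(0.0, noise_sd, size=t.shape)
    return TemperatureSeries(times=t, temps=temps, activation_time=activation_time)


def saturating_auc(energy_per_mass: float, auc_max: float, e_half: float) -> float:
    """Ground-truth above-baseline integrated Ca2+ signal vs energy dose."""
    return auc_max * energy_per_mass / (energy_per_mass + e_half)


@dataclass(frozen=True)
class TreatmentSpec:
    """One experimental condition: a plasma source setting and its energy dose."""

    label: str
    energy_per_mass: float          # J/kg, ground truth dose
    source: str = "DBD"             # DBD or PT
    frequency_khz: float = 20.0
    activation_time: float = 180.0  # s of plasma exposure


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic plate experiment mirroring the assay layout."""

    treatments: tuple
    replicates: int = 6
    seed: int = 0
    auc_max: float = 6e-4           # M*s above baseline, asymptotic response
    e_half: float = 1e5             # J/kg at half-saturation
    window: float = 1800.0          # s, integration window the AUC refers to
    plate: PlateRunConfig = PlateRunConfig()
    pool: AequorinPool = AequorinPool()
    kinetics_template: CaKinetics = CaKinetics(
        transient_amplitude=2e-7, sustained_amplitude=2e-7
    )

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PlateRun:
    """Simulated plate: one luminescence trace per well plus a truth ledger."""

    traces: list
    ledger: list  # one dict per well: well id, kinetics, dose, seed, true AUC

    def ledger_json(self) -> str:
        return json.dumps(self.ledger, indent=2)


def _unit_aucs(k: CaKinetics, window: float) -> tuple[float, float]:
    """Analytic above-baseline integrals per unit amplitude over [0, window]."""
    r, d, s = k.rise_tau, k.decay_tau, k.sustained_tau
    norm = _transient_norm(k)
    it = norm * (d * (1 - np.exp(-window / d)) - r * (1 - np.exp(-window / r)))
    isus = window - s * (1 - np.exp(-window / s))
    return it, isus


def kinetics_for_dose(design: ExperimentDesign, energy_per_mass: float) -> CaKinetics:
    """Scale the template amplitudes so the true AUC follows the saturating law."""
    target = saturating_auc(energy_per_mass, design.auc_max, design.e_half)
    k = design.kinetics_template
    it, isus = _unit_aucs(k, design.window)
    denom = k.transient_amplitude * it + k.sustained_amplitude * isus
    if denom <= 0:
        raise ValueError("kinetics template has zero response amplitude")
    scale = target / denom
    return replace(
        k,
        transient_amplitude=k.transient_amplitude * scale,
        sustained_amplitude=k.sustained_amplitude * scale,
        stimulus_time=design.plate.stimulus_time,
    )


def true_auc_above_baseline(design: ExperimentDesign, kinetics: CaKinetics) -> float:
    it, isus = _unit_aucs(kinetics, design.window)
    return kinetics.transient_amplitude * it + kinetics.sustained_amplitude * isus


def make_experiment(design: ExperimentDesign) -> PlateRun:
    """Simulate every well of the design; deterministic for a fixed master seed."""
    ss = np.random.SeedSequence(design.seed)
    child_seeds = ss.generate_state(len(design.treatments) * design.replicates)
    grid = design.plate.time_grid()
    traces, ledger = [], []
    idx = 0
    for treatment in design.treatments:
        kin = kinetics_for_dose(design, treatment.energy_per_mass)
        truth = make_ca_trajectory(kin, grid)
        for rep in range(design.replicates):
            seed = int(child_seeds[idx] % (2**31))
            idx += 1
            well_id = f"{treatment.label}_r{rep + 1}"
            trace = make_luminescence(
                truth, design.pool, design.plate, seed=seed, well_id=well_id
            )
            trace.metadata.update(
                treatment=treatment.label,
                source=treatment.source,
                frequency_khz=treatment.frequency_khz,
                activation_time=treatment.activation_time,
                dilution="1:2",
            )
            traces.append(trace)
            ledger.append(
                {
                    "well_id": well_id,
                    "treatment": treatment.label,
                    "energy_per_mass": treatment.energy_per_mass,
                    "seed": seed,
                    "kinetics": asdict(kin),
                    "true_auc_above_baseline": true_auc_above_baseline(design, kin),
                }
            )
    return PlateRun(traces=traces, ledger=ledger)
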