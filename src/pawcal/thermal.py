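"""Zero-dimensional heat-transport model of plasma–water energy transfer.

While a cold-plasma source runs, the treated water obeys

    d(m(t) * cs * T(t)) / dt = Pin - Rcond * (T(t) - Tenv)

with ``Pin`` the effective power delivered to the water (W), ``Rcond`` the
thermal conductance toward the environment (W/K), ``cs`` the specific heat of
water and ``m(t)`` its mass (constant for the dielectric-barrier-discharge
set-up; slowly decreasing for the torch, which ejects some water).  For
constant mass the solution is

    T(t) = T0 * exp(-B t) + (A / B) * (1 - exp(-B t)),
    A = (Pin + Rcond * Tenv) / (m0 * cs),   B = Rcond / (m0 * cs),

with the B -> 0 limit T(t) = T0 + Pin * t / (m0 * cs).  Fitting the heating
phase and the subsequent free decay (Pin = 0) to temperature measurements
recovers Pin and Rcond; Pin times the activation time, divided by the water
mass, is the energy dose per unit mass used as the common axis for comparing
plasma sources.

Temperatures are handled in degrees Celsius throughout: only temperature
differences enter the model, so the offset from kelvin cancels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "ThermalParams",
    "TemperatureSeries",
    "ThermalFit",
    "EnergyDose",
    "solve_temperature",
    "simulate_ode",
    "fit_thermal",
    "transferred_energy",
]

# B below this (s^-1) is numerically indistinguishable from lossless heating
_B_TINY = 1e-12


@dataclass(frozen=True)
class ThermalParams:
    """Physical parameters of the heat-transport model (SI; temperatures degC)."""

    Pin: float
    Rcond: float
    Tenv: float
    T0: float
    m0: float
    cs: float = 4186.0
    mass_loss_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.Pin < 0 or self.Rcond < 0:
            raise ValueError("Pin and Rcond must be >= 0")
        if self.m0 <= 0 or self.cs <= 0:
            raise ValueError("m0 and cs must be > 0")
        if self.mass_loss_rate < 0:
            raise ValueError("mass_loss_rate must be >= 0")

    @property
    def A(self) -> float:
        return (self.Pin + self.Rcond * self.Tenv) / (self.m0 * self.cs)

    @property
    def B(self) -> float:
        return self.Rcond / (self.m0 * self.cs)


@dataclass
class TemperatureSeries:
    """Measured (or simulated) water temperature vs time.

    ``activation_time`` is the instant the source was switched off; samples
    with ``times <= activation_time`` are labelled ``"heating"``, later ones
    ``"decay"`` unless explicit phase labels are given.
    """

    times: np.ndarray
    temps: np.ndarray
    activation_time: float
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.shape != self.temps.shape or self.times.ndim != 1:
            raise ValueError("times and temps must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.phase is None:
            self.phase = np.where(
                self.times <= self.activation_time, "heating", "decay"
            )
        else:
            self.phase = np.asarray(self.phase)
            if self.phase.shape != self.times.shape:
                raise ValueError("phase labels must match times")


@dataclass
class ThermalFit:
    """Result of the two-phase fit: recovered power, conductance, residuals."""

    Pin_hat: float
    Rcond_hat: float
    A_hat: float
    B_hat: float
    T0_hat: float
    residual_rms_heating: float
    residual_rms_decay: float
    flags: set = field(default_factory=set)
    covariance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EnergyDose:
    """Energy transferred to the water per unit mass (the PAW dose axis)."""

    energy_per_mass: float  # J / kg
    effective_power: float  # W
    activation_time: float  # s

    def __post_init__(self) -> None:
        if self.energy_per_mass < 0:
            raise ValueError("energy_per_mass must be >= 0")


def solve_temperature(params: ThermalParams, times) -> np.ndarray:
    """Closed-form temperature for constant mass (mass_loss_rate must be 0)."""
    if params.mass_loss_rate != 0:
        raise ValueError("closed form requires constant mass; use simulate_ode")
    t = np.asarray(times, dtype=float)
    B = params.B
    if B < _B_TINY:
        return params.T0 + params.Pin * t / (params.m0 * params.cs)
    e = np.exp(-B * t)
    return params.T0 * e + (params.A / B) * (1.0 - e)


def simulate_ode(params: ThermalParams, times, rtol: float = 1e-10,
                 atol: float = 1e-10) -> np.ndarray:
    """Numerical integration of the heat-transport ODE, allowing mass loss.

    Expanding d(m cs T)/dt with m(t) = m0 - mass_loss_rate * t gives

        dT/dt = (Pin - Rcond (T - Tenv) + mass_loss_rate * cs * T) / (m(t) cs).

    For ``mass_loss_rate = 0`` this agrees with :func:`solve_temperature` to
    integrator tolerance (an independent check of the closed form).
    """
    t = np.asarray(times, dtype=float)
    mdot = params.mass_loss_rate
    if mdot > 0 and params.m0 - mdot * t[-1] <= 0:
        raise ValueError("water mass reaches zero within the requested interval")

    def rhs(ti, T):
        m = params.m0 - mdot * ti
        return (params.Pin - params.Rcond * (T[0] - params.Tenv)
                + mdot * params.cs * T[0]) / (m * params.cs)

    t0 = min(t[0], 0.0)
    sol = solve_ivp(rhs, (t0, t[-1]), [params.T0], t_eval=t,
                    rtol=rtol, atol=atol, method="RK45", dense_output=False)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


def _fit_decay(times: np.ndarray, temps: np.ndarray, Tenv: float):
    """Fit T = Tenv + C exp(-B (t - t0)) on the decay phase; returns (B, cov)."""
    t0 = times[0]
    dt = times - t0
    C0 = temps[0] - Tenv
    span = max(dt[-1], 1.0)
    B0 = 1.0 / span
    if abs(C0) > 1e-12:
        # crude log-linear initial guess where the excess is positive
        excess = temps - Tenv
        pos = excess > 0.05 * abs(C0)
        if pos.sum() >= 2:
            slope = np.polyfit(dt[pos], np.log(np.abs(excess[pos])), 1)[0]
            if slope < 0:
                B0 = -slope

    def model(tt, C, B):
        return Tenv + C * np.exp(-B * tt)

    popt, pcov = curve_fit(model, dt, temps, p0=[C0, B0], maxfev=10000)
    resid = temps - model(dt, *popt)
    return popt[1], pcov, float(np.sqrt(np.mean(resid**2)))


def fit_thermal(series: TemperatureSeries, m0: float, cs: float = 4186.0,
                Tenv: float | None = None) -> ThermalFit:
    """Recover effective power and thermal conductance from a two-phase series.

    Stage 1 estimates B (hence Rcond = B m0 cs) from the free-decay phase,
    where the model reduces to pure exponential relaxation toward ``Tenv``.
    Stage 2, with B fixed, fits the heating phase, which is then *linear* in
    (T0, A); Pin = A m0 cs - Rcond Tenv.  If the decay yields a non-positive
    B the fit falls back to lossless linear heating (Rcond = 0, flagged).

    ``Tenv`` defaults to the last decay temperature if not supplied, but
    should normally be the measured ambient temperature.
    """
    heat = series.phase == "heating"
    decay = series.phase == "decay"
    if heat.sum() < 4 or decay.sum() < 4:
        raise ValueError("need at least 4 samples in each phase to fit")
    if Tenv is None:
        Tenv = float(series.temps[decay][-1])

    flags: set = set()
    cov: dict = {}
    th, Th = series.times[heat], series.temps[heat]
    td, Td = series.times[decay], series.temps[decay]
    t_heat = th - th[0]

    try:
        B_hat, pcov, rms_decay = _fit_decay(td, Td, Tenv)
        cov["decay"] = pcov.tolist()
    except RuntimeError:
        B_hat, rms_decay = -1.0, float("nan")
        flags.add("decay_fit_failed")

    if B_hat <= 0:
        # lossless fallback: straight-line heating
        slope, T0_hat = np.polyfit(t_heat, Th, 1)
        resid = Th - (T0_hat + slope * t_heat)
        flags.add("linear_fallback")
        Pin_hat = slope * m0 * cs
        return ThermalFit(
            Pin_hat=float(Pin_hat), Rcond_hat=0.0,
            A_hat=float(Pin_hat / (m0 * cs)), B_hat=0.0, T0_hat=float(T0_hat),
            residual_rms_heating=float(np.sqrt(np.mean(resid**2))),
            residual_rms_decay=rms_decay, flags=flags, covariance=cov)

    e = np.exp(-B_hat * t_heat)
    X = np.column_stack([e, (1.0 - e) / B_hat])
    (T0_hat, A_hat), res, *_ = np.linalg.lstsq(X, Th, rcond=None)
    fitted = X @ np.array([T0_hat, A_hat])
    rms_heat = float(np.sqrt(np.mean((Th - fitted) ** 2)))

    Rcond_hat = B_hat * m0 * cs
    Pin_hat = A_hat * m0 * cs - Rcond_hat * Tenv
    return ThermalFit(
        Pin_hat=float(Pin_hat), Rcond_hat=float(Rcond_hat),
        A_hat=float(A_hat), B_hat=float(B_hat), T0_hat=float(T0_hat),
        residual_rms_heating=rms_heat, residual_rms_decay=rms_decay,
        flags=flags, covariance=cov)


def transferred_energy(fit: ThermalFit, activation_time: float, m0: float) -> EnergyDose:
    """Energy per unit mass delivered during activation: Pin_hat * t_act / m0."""
    if activation_time < 0:
        raise ValueError("activation_time must be >= 0")
    power = max(fit.Pin_hat, 0.0)
    return EnergyDose(
        energy_per_mass=power * activation_time / m0,
        effective_power=power,
        activation_time=activation_time,
    )
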