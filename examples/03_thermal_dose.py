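"""Fit the heat-transport model to a noisy temperature log and compute the
energy dose.

A 20 mL water sample is heated by a 30 W effective source for 180 s and then
cools freely for 300 s.  The decay phase identifies the thermal conductance
Rcond; the heating phase then identifies the effective power Pin.  The PAW
dose is Pin x activation time / water mass (J/kg).
"""

import numpy as np

from pawcal import (
    ThermalParams,
    fit_thermal,
    make_temperature_series,
    transferred_energy,
)

truth = ThermalParams(Pin=30.0, Rcond=0.5, Tenv=22.0, T0=22.0, m0=0.02)
times = np.arange(0.0, 480.0 + 1e-9, 5.0)
series = make_temperature_series(truth, times, noise_sd=0.1, seed=3,
                                 activation_time=180.0)

fit = fit_thermal(series, m0=truth.m0, Tenv=truth.Tenv)
dose = transferred_energy(fit, activation_time=180.0, m0=truth.m0)

print(f"peak temperature:   {series.temps.max():.1f} degC (ambient 22.0)")
print(f"Pin   recovered:    {fit.Pin_hat:.2f} W   (truth 30.00)")
print(f"Rcond recovered:    {fit.Rcond_hat:.3f} W/K (truth 0.500)")
print(f"residual RMS:       heating {fit.residual_rms_heating:.3f} K, "
      f"decay {fit.residual_rms_decay:.3f} K")
print(f"energy dose:        {dose.energy_per_mass:.3e} J/kg "
      f"(truth {truth.Pin * 180.0 / truth.m0:.3e})")
# Residual RMS should match the 0.1 K measurement noise; both parameters are
# typically recovered within a few percent from a single noisy log.
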