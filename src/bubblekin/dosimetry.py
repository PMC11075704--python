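"""Dose accumulation and adiabatic heating bounds.

The beamline delivers a constant, measured surface dose rate while the
shutter is open, so cumulative dose is simply rate x elapsed irradiation
time.  Because absorbed dose is energy per unit mass (1 Gy = 1 J/kg), an
upper bound on radiation heating follows by assuming every joule stays in
the sample: dT = D / c_p, with c_p the specific heat of the solvent.  Real
samples exchange heat with the hutch, so these are strict upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_DOSE_RATE_GY_S = 36.8
"""Measured surface dose rate of the imaging beam, Gy/s."""


@dataclass(frozen=True)
class SolventProperties:
    """Thermal properties of a candidate solvent."""

    name: str
    specific_heat: float  # J kg^-1 K^-1 at room temperature
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.specific_heat <= 0:
            raise ValueError("specific_heat must be positive")


WATER = SolventProperties("water", 4184.0, "standard c_p of liquid water at 25 C")
ETHANOL = SolventProperties("ethanol", 2440.0, "standard c_p of liquid ethanol at 25 C")


def cumulative_dose(dose_rate: float, t: float, t_ron: float = 0.0) -> float:
    """Accumulated surface dose in Gy after irradiating from ``t_ron`` to ``t``.

    Parameters
    ----------
    dose_rate : float
        Surface dose rate in Gy/s.
    t, t_ron : float
        Current time and radiation-on time, seconds on a common clock.
    """
    if dose_rate < 0:
        raise ValueError("dose_rate must be non-negative")
    elapsed = t - t_ron
    if elapsed < 0:
        raise ValueError(f"time {t} s precedes radiation-on at {t_ron} s")
    return dose_rate * elapsed


def temperature_bound(dose: float, solvent: SolventProperties) -> float:
    """Adiabatic upper bound on the temperature rise, in kelvin (== deg C).

    Assumes no heat exchange and no phase change: dT = D / c_p.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return dose / solvent.specific_heat


@dataclass
class DoseProfile:
    """Cumulative dose history for one irradiation run."""

    dose_rate: float = DEFAULT_DOSE_RATE_GY_S
    t_ron: float = 0.0
    d_at_onset: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.dose_rate < 0:
            raise ValueError("dose_rate must be non-negative")

    def dose_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """D(t) = rate x (t - t_ron); vectorized over time arrays."""
        elapsed = np.asarray(t, dtype=float) - self.t_ron
        if np.any(elapsed < 0):
            raise ValueError("requested time precedes radiation-on")
        out = self.dose_rate * elapsed
        return float(out) if np.isscalar(t) else out

    def mark_onset(self, t_bo: float) -> float:
        """Record and return the dose accumulated at bubble onset."""
        self.d_at_onset = self.dose_at(t_bo)
        return self.d_at_onset
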