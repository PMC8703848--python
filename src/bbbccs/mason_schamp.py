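"""Low-field drift-tube conversion between arrival time and CCS.

Implements the canonical low-field relation for a drift-tube ion-mobility
experiment in a buffer gas (nitrogen by default):

    CCS = (sqrt(18*pi)/16) * (z*e / sqrt(kb*T)) * sqrt(1/m_i + 1/m_B)
          * (t_A*E/L) * (760/P) * (T/273.15) * (1/N0)

with masses converted to kg under the square root, and N0 the gas number
density at 760 Torr / 273.15 K.  Input quantities use instrument-native
units (ms, V/cm, cm, Torr, K, Da); the result is in Å².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "CONSTANTS",
    "DriftConditions",
    "CcsValue",
    "reduced_mass_term",
    "ccs_from_drift",
    "drift_time_from_ccs",
    "N2_MASS",
]

#: Physical constants registry (SI).
CONSTANTS = {
    "elementary_charge": 1.602176634e-19,  # C
    "boltzmann": 1.380649e-23,  # J/K
    "loschmidt": 2.6867811e25,  # m^-3, number density at 760 Torr / 273.15 K
    "dalton": 1.66053907e-27,  # kg
}

#: Mass of molecular nitrogen in Da.
N2_MASS = 28.0134

_M2_TO_A2 = 1e20  # m^2 -> Å^2
_MS_TO_S = 1e-3
_VCM_TO_VM = 1e2
_CM_TO_M = 1e-2


@dataclass(frozen=True)
class DriftConditions:
    """Drift-tube measurement parameters.

    Attributes
    ----------
    t_a : float
        Arrival time in ms.
    field : float
        Applied electric field in V/cm.
    length : float
        Drift tube length in cm.
    pressure : float
        Drift-cell pressure in Torr.
    temperature : float
        Drift-cell temperature in K.
    ion_mass, buffer_gas_mass : float
        Masses in Da.
    z : int
        Charge number (>= 1; sign is irrelevant for the magnitude).
    """

    t_a: float
    field: float
    length: float
    pressure: float
    temperature: float
    ion_mass: float
    buffer_gas_mass: float = N2_MASS
    z: int = 1

    def __post_init__(self) -> None:
        for name in ("t_a", "field", "length", "pressure", "temperature",
                     "ion_mass", "buffer_gas_mass"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if int(self.z) < 1:
            raise ValueError(f"charge number z must be an integer >= 1, got {self.z}")


@dataclass(frozen=True)
class CcsValue:
    """A collision cross section in Å² for a given buffer gas."""

    value: float
    buffer_gas: str = "N2"

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"CCS must be > 0 Å², got {self.value}")


def reduced_mass_term(m_i: float, m_B: float) -> float:
    """sqrt(1/m_i + 1/m_B) for masses in Da (symmetric, decreasing in each)."""
    if m_i <= 0 or m_B <= 0:
        raise ValueError(f"masses must be > 0 Da, got m_i={m_i}, m_B={m_B}")
    return math.sqrt(1.0 / m_i + 1.0 / m_B)


def _ccs_per_ms(c: DriftConditions) -> float:
    """CCS (Å²) contributed per ms of arrival time at the given conditions."""
    e = CONSTANTS["elementary_charge"]
    kb = CONSTANTS["boltzmann"]
    n0 = CONSTANTS["loschmidt"]
    da = CONSTANTS["dalton"]

    mass_term = reduced_mass_term(c.ion_mass, c.buffer_gas_mass) / math.sqrt(da)
    field_si = c.field * _VCM_TO_VM
    length_si = c.length * _CM_TO_M

    per_second = (
        (math.sqrt(18.0 * math.pi) / 16.0)
        * (int(c.z) * e / math.sqrt(kb * c.temperature))
        * mass_term
        * (field_si / length_si)
        * (760.0 / c.pressure)
        * (c.temperature / 273.15)
        / n0
    ) * _M2_TO_A2
    return per_second * _MS_TO_S


def ccs_from_drift(c: DriftConditions) -> CcsValue:
    """Convert an arrival time measured at ``c`` into a CCS in Å²."""
    return CcsValue(value=c.t_a * _ccs_per_ms(c), buffer_gas="N2")


def drift_time_from_ccs(ccs: CcsValue | float, c: DriftConditions) -> float:
    """Arrival time (ms) producing ``ccs`` at conditions ``c`` (t_a ignored).

    Exact algebraic inverse of :func:`ccs_from_drift`.
    """
    value = ccs.value if isinstance(ccs, CcsValue) else float(ccs)
    if value <= 0:
        raise ValueError(f"CCS must be > 0 Å², got {value}")
    return value / _ccs_per_ms(c)


def with_arrival_time(c: DriftConditions, t_a: float) -> DriftConditions:
    """Copy of ``c`` with a different arrival time."""
    return replace(c, t_a=t_a)
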