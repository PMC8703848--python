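"""Hard-sphere conversion of CCS into ion radii/areas and pore comparison.

Under the hard-sphere collision model the CCS equals pi times the squared
sum of the colliding radii, so the projected ion radius is

    r_i = sqrt(CCS / pi) - r_B

with r_B the kinetic radius of the buffer gas (nitrogen: 1.82 Å).  A
measured CCS is in reality a momentum-transfer cross section, which can
exceed the geometric cross section by up to ~40%; the corrected branch
divides the CCS by a correction factor (default 1.4) before the radius
extraction.  The resulting radii are compared against the dimensions of
membrane and tight-junction pores (8-10 Å diameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BufferGasSpec:
    """A buffer gas characterised by its kinetic (hard-sphere) radius in Å."""

    name: str
    kinetic_radius: float

    def __post_init__(self) -> None:
        if not self.kinetic_radius > 0:
            raise ValueError(f"kinetic radius must be > 0 Å, got {self.kinetic_radius}")

    @property
    def min_ccs(self) -> float:
        """Smallest representable CCS (point ion): pi * r_B**2."""
        return math.pi * self.kinetic_radius**2


#: Molecular nitrogen, kinetic diameter 3.64 Å.
NITROGEN = BufferGasSpec("N2", 1.82)

#: Threshold ion radius (Å) corresponding to the 200 Å² CCS cut-off.
R_I_MAX = 6.2

#: Default momentum-transfer correction factor (up to 40% difference).
DEFAULT_CORRECTION = 1.4


@dataclass(frozen=True)
class PoreModel:
    """A pore in the barrier, with a fixed diameter or a diameter range (Å)."""

    name: str
    diameter: float | tuple[float, float]

    def __post_init__(self) -> None:
        low, high = self.bounds
        if not (low > 0 and high >= low):
            raise ValueError(f"invalid pore diameter {self.diameter!r}")

    @property
    def bounds(self) -> tuple[float, float]:
        if isinstance(self.diameter, tuple):
            return self.diameter
        return (self.diameter, self.diameter)


#: Transient pore formed by lipid alkyl-chain kinks during membrane crossing.
MEMBRANE_KINK_PORE = PoreModel("membrane_kink", 10.0)
#: Tight-junction claudin assemblies.
CLAUDIN_PORE = PoreModel("claudin", (8.0, 10.0))

BUILTIN_PORES = (MEMBRANE_KINK_PORE, CLAUDIN_PORE)


@dataclass(frozen=True)
class SphereProjection:
    """Radii and areas derived from one CCS, uncorrected and corrected."""

    ccs: float
    r_i: float
    a_i: float
    r_con: float
    a_con: float
    correction_factor: float

    def __post_init__(self) -> None:
        if not math.isclose(self.a_i, math.pi * self.r_i**2, rel_tol=1e-9):
            raise ValueError("a_i must equal pi * r_i**2")
        if not math.isclose(self.a_con, math.pi * self.r_con**2, rel_tol=1e-9):
            raise ValueError("a_con must equal pi * r_con**2")
        if self.correction_factor >= 1 and self.r_con > self.r_i + 1e-12:
            raise ValueError("corrected radius exceeds uncorrected radius")


def ion_radius_from_ccs(ccs: float, gas: BufferGasSpec = NITROGEN) -> float:
    """Projected ion radius (Å) from a CCS (Å²): sqrt(ccs/pi) - r_B."""
    if ccs < gas.min_ccs:
        raise ValueError(
            f"CCS {ccs} Å² below the minimum representable "
            f"{gas.min_ccs:.3f} Å² for buffer gas {gas.name} (r_B={gas.kinetic_radius} Å)"
        )
    return math.sqrt(ccs / math.pi) - gas.kinetic_radius


def ccs_from_ion_radius(r_i: float, gas: BufferGasSpec = NITROGEN) -> float:
    """CCS (Å²) of an ion of radius r_i (Å): pi * (r_i + r_B)**2."""
    if r_i < 0:
        raise ValueError(f"ion radius must be >= 0 Å, got {r_i}")
    return math.pi * (r_i + gas.kinetic_radius) ** 2


def projection_from_ccs(
    ccs: float,
    gas: BufferGasSpec = NITROGEN,
    correction_factor: float = DEFAULT_CORRECTION,
) -> SphereProjection:
    """Full hard-sphere projection of a CCS, with momentum correction.

    The corrected branch pushes ``ccs / correction_factor`` through the
    same radius formula.
    """
    if correction_factor < 1:
        raise ValueError(f"correction factor must be >= 1, got {correction_factor}")
    r_i = ion_radius_from_ccs(ccs, gas)
    r_con = ion_radius_from_ccs(ccs / correction_factor, gas)
    return SphereProjection(
        ccs=ccs,
        r_i=r_i,
        a_i=math.pi * r_i**2,
        r_con=r_con,
        a_con=math.pi * r_con**2,
        correction_factor=correction_factor,
    )


def propagate_spread(
    ccs_mean: float,
    ccs_sd: float,
    gas: BufferGasSpec = NITROGEN,
    correction_factor: float = DEFAULT_CORRECTION,
    method: str = "endpoint",
) -> dict[str, float]:
    """Spread of the derived radii/areas induced by a CCS spread.

    ``endpoint`` (default): spread of f = f(mean + sd) - f(mean), the
    one-sided endpoint propagation.  ``delta``: first-order delta method
    |f'(mean)| * sd.  Returns spreads keyed ``r_i``, ``a_i``, ``r_con``,
    ``a_con``.
    """
    if ccs_sd < 0:
        raise ValueError(f"ccs_sd must be >= 0, got {ccs_sd}")

    def values(ccs: float) -> dict[str, float]:
        p = projection_from_ccs(ccs, gas, correction_factor)
        return {"r_i": p.r_i, "a_i": p.a_i, "r_con": p.r_con, "a_con": p.a_con}

    at_mean = values(ccs_mean)
    if method == "endpoint":
        at_hi = values(ccs_mean + ccs_sd)
        return {k: at_hi[k] - at_mean[k] for k in at_mean}
    if method == "delta":
        h = max(ccs_mean * 1e-6, 1e-9)
        lo, hi = values(ccs_mean - h), values(ccs_mean + h)
        return {k: abs(hi[k] - lo[k]) / (2 * h) * ccs_sd for k in at_mean}
    raise ValueError(f"unknown spread method {method!r}")


def fits_pore(r: float, pore: PoreModel) -> dict[str, object]:
    """Does a sphere of radius r (Å) pass a pore?  2r <= diameter counts as fitting.

    For a range pore the verdicts at both diameter endpoints are reported;
    the overall verdict is ``"fits"`` (both), ``"does_not_fit"`` (neither)
    or ``"within_range_band"`` (fits the wide end only).
    """
    if r < 0:
        raise ValueError(f"radius must be >= 0 Å, got {r}")
    low, high = pore.bounds
    fits_low = 2 * r <= low
    fits_high = 2 * r <= high
    if fits_low:
        verdict = "fits"
    elif fits_high:
        verdict = "within_range_band"
    else:
        verdict = "does_not_fit"
    return {
        "pore": pore.name,
        "diameter_low": low,
        "diameter_high": high,
        "fits_low": fits_low,
        "fits_high": fits_high,
        "verdict": verdict,
    }
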