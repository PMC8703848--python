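"""Charge-aware adduct selection and adduct mass arithmetic.

The ionic species considered for a compound follows its predominant charge
at physiological pH: positively charged and neutral compounds are taken as
protonated (M+H)+ ions, negatively charged compounds as deprotonated
(M-H)- ions.  Compounds of unknown charge fall back to (M+H)+ (logged),
the convention used when no charge annotation is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .compound_model import ChargeClass

logger = logging.getLogger(__name__)

#: Proton mass in Da (CODATA).
PROTON_MASS = 1.007276


class AdductKind(str, Enum):
    protonated = "(M+H)+"
    deprotonated = "(M-H)-"


@dataclass(frozen=True)
class AdductSpec:
    """An ionic adduct: kind, charge number and signed mass shift in Da."""

    kind: AdductKind
    z: int
    mass_shift: float

    def __post_init__(self) -> None:
        if self.kind is AdductKind.protonated and (self.z != 1 or self.mass_shift <= 0):
            raise ValueError("protonated adduct requires z=+1 and positive mass shift")
        if self.kind is AdductKind.deprotonated and (self.z != -1 or self.mass_shift >= 0):
            raise ValueError("deprotonated adduct requires z=-1 and negative mass shift")


PROTONATED = AdductSpec(AdductKind.protonated, z=+1, mass_shift=+PROTON_MASS)
DEPROTONATED = AdductSpec(AdductKind.deprotonated, z=-1, mass_shift=-PROTON_MASS)


def select_adduct(
    charge_class: ChargeClass,
    *,
    unknown_fallback: AdductSpec = PROTONATED,
) -> AdductSpec:
    """Choose the adduct from the physiological charge class.

    positive -> (M+H)+; negative -> (M-H)-; neutral -> (M+H)+.  Unknown
    charge uses ``unknown_fallback`` (default (M+H)+) and is logged.
    """
    if charge_class is ChargeClass.positive:
        return PROTONATED
    if charge_class is ChargeClass.negative:
        return DEPROTONATED
    if charge_class is ChargeClass.neutral:
        return PROTONATED
    logger.debug("unknown charge class: falling back to %s", unknown_fallback.kind.value)
    return unknown_fallback


def adduct_mass(neutral_mass: float, spec: AdductSpec) -> float:
    """Ion mass in Da for a neutral mass under an adduct spec."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be > 0 Da, got {neutral_mass}")
    mass = neutral_mass + spec.mass_shift
    if mass <= 0:
        raise ValueError(f"ion mass {mass} Da is non-positive")
    return mass
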