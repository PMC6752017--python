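"""Headspace/dissolved gas partitioning for sealed anoxic microcosm vessels.

Measured headspace mixing ratios are converted into total vessel amounts:
the headspace contribution follows the ideal gas law, the dissolved
contribution Henry's law, and (for CO2 only) the bicarbonate pool follows
from dissolved CO2, the slurry pH and the first carbonic acid dissociation
constant via Henderson-Hasselbalch.  Carbonate (CO3 2-) is neglected: below
pH 7.5 it contributes under 1% of dissolved inorganic carbon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "R_J_PER_MOL_K",
    "ATM_KPA",
    "VesselGeometry",
    "GasConstants",
    "headspace_amount",
    "dissolved_amount",
    "bicarbonate_amount",
    "total_gas",
]

R_J_PER_MOL_K = 8.314
ATM_KPA = 101.325


@dataclass(frozen=True)
class VesselGeometry:
    """27-ml crimp-seal tube holding a 10-ml slurry.

    The default absolute pressure reads the 60 kPa N2 pressurization as an
    overpressure on 1 atm; the default temperature matches the 25 degC
    reference of the solubility constants.  Both are explicit knobs because
    neither is uniquely fixed by the vessel description (incubation was at
    ambient 21-24 degC and the pressure could be read as absolute).
    """

    total_volume_ml: float = 27.0
    liquid_volume_ml: float = 10.0
    temperature_k: float = 298.15
    pressure_kpa: float = ATM_KPA + 60.0

    def __post_init__(self) -> None:
        if self.temperature_k <= 0 or self.pressure_kpa <= 0:
            raise ValueError("temperature and pressure must be positive")
        if self.headspace_volume_ml <= 0:
            raise ValueError("headspace volume (total - liquid) must be positive")

    @property
    def headspace_volume_ml(self) -> float:
        return self.total_volume_ml - self.liquid_volume_ml


@dataclass(frozen=True)
class GasConstants:
    """Henry solubility constants (mol/L/atm) and carbonic acid pKa1 at 25 degC."""

    henry: dict = field(
        default_factory=lambda: {"CO2": 3.39e-2, "H2": 7.8e-4}
    )
    pka1: float = 6.35

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.henry.values()) or self.pka1 <= 0:
            raise ValueError("gas constants must be positive")


def _check_mixing_ratio(x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"mixing ratio must be in [0, 1], got {x}")


def headspace_amount(mixing_ratio: float, geom: VesselGeometry = VesselGeometry()) -> float:
    """Ideal-gas amount (umol) of a gas in the vessel headspace."""
    _check_mixing_ratio(mixing_ratio)
    pressure_pa = geom.pressure_kpa * 1e3
    volume_m3 = geom.headspace_volume_ml * 1e-6
    mol = mixing_ratio * pressure_pa * volume_m3 / (R_J_PER_MOL_K * geom.temperature_k)
    return mol * 1e6


def dissolved_amount(
    mixing_ratio: float,
    gas: str,
    geom: VesselGeometry = VesselGeometry(),
    k: GasConstants = GasConstants(),
) -> float:
    """Henry's-law amount (umol) of a gas dissolved in the liquid phase."""
    _check_mixing_ratio(mixing_ratio)
    try:
        henry = k.henry[gas]
    except KeyError:
        raise KeyError(f"no Henry constant for gas {gas!r}") from None
    partial_atm = mixing_ratio * geom.pressure_kpa / ATM_KPA
    mol = henry * partial_atm * geom.liquid_volume_ml * 1e-3
    return mol * 1e6


def bicarbonate_amount(
    dissolved_co2: float, ph: float, k: GasConstants = GasConstants()
) -> float:
    """Bicarbonate (umol) in equilibrium with dissolved CO2 at the given pH."""
    if dissolved_co2 < 0:
        raise ValueError("dissolved CO2 must be >= 0")
    return dissolved_co2 * 10.0 ** (ph - k.pka1)


def total_gas(
    mixing_ratio: float,
    gas: str,
    ph: float | None = None,
    geom: VesselGeometry = VesselGeometry(),
    k: GasConstants = GasConstants(),
    g_fresh_weight: float = 1.0,
) -> tuple[float, float]:
    """Total vessel amount of a gas and its per-gFW value.

    H2: headspace + dissolved.  CO2: headspace + dissolved + bicarbonate
    (requires a pH).  Returns ``(umol, umol_per_gFW)``.
    """
    total = headspace_amount(mixing_ratio, geom) + dissolved_amount(
        mixing_ratio, gas, geom, k
    )
    if gas.upper() == "CO2":
        if ph is None:
            raise ValueError("a pH is required to account for bicarbonate CO2")
        total += bicarbonate_amount(dissolved_amount(mixing_ratio, gas, geom, k), ph, k)
    if g_fresh_weight <= 0:
        raise ValueError("fresh weight must be positive")
    return total, total / g_fresh_weight
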