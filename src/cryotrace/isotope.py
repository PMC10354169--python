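"""Stateless isotope and gas-phase arithmetic.

This module holds the conversions every downstream stage relies on:
delta-notation to atom-fraction transforms, atom-percent-excess with
below-background handling, the ideal-gas conversion from a headspace CO2
mixing ratio to a carbon mass, headspace respiration rates with the
sampling/gas-replacement correction, and the wetting/labelling arithmetic
used when soils are brought to a target water content and target tracer
enrichment.

All functions are pure; quality-control conditions are reported as flags
on small result records rather than silently clipped away.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .config import MOLAR_MASS_C, R_GAS_L_ATM, Settings, DEFAULT_SETTINGS
from .errors import (
    DomainError,
    IncompleteObservationError,
    InvalidIsotopeValueError,
)

__all__ = [
    "IsotopeValue",
    "HeadspaceObservation",
    "ExcessResult",
    "RespirationResult",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "atom_percent_excess",
    "ppm_to_mass_c",
    "respiration_rate",
    "water_and_label_addition",
    "water_content",
]

_KINDS = ("delta_permil", "atom_percent", "atom_fraction")


def delta_to_atom_fraction(delta: float, reference_ratio: float) -> float:
    """Convert a delta value (permil) to a heavy-isotope atom fraction.

    Parameters
    ----------
    delta : float
        Isotopic composition in permil relative to the standard.
    reference_ratio : float
        Heavy/light isotope ratio of the standard (e.g. VPDB 13C/12C).
    """
    if delta <= -1000:
        raise InvalidIsotopeValueError(
            f"delta must exceed -1000 permil (got {delta}); the atom fraction "
            "limit at -1000 is zero"
        )
    if reference_ratio <= 0:
        raise InvalidIsotopeValueError("reference ratio must be positive")
    r = reference_ratio * (delta / 1000.0 + 1.0)
    return r / (1.0 + r)


def atom_fraction_to_delta(atom_fraction: float, reference_ratio: float) -> float:
    """Inverse of :func:`delta_to_atom_fraction`."""
    if not 0.0 <= atom_fraction < 1.0:
        raise InvalidIsotopeValueError(
            f"atom fraction must be in [0, 1), got {atom_fraction}"
        )
    if reference_ratio <= 0:
        raise InvalidIsotopeValueError("reference ratio must be positive")
    r = atom_fraction / (1.0 - atom_fraction)
    return (r / reference_ratio - 1.0) * 1000.0


def delta_to_atom_percent(delta: float, reference_ratio: float) -> float:
    """Delta (permil) to atom percent."""
    return 100.0 * delta_to_atom_fraction(delta, reference_ratio)


def atom_percent_to_delta(atom_percent: float, reference_ratio: float) -> float:
    """Atom percent to delta (permil)."""
    if not 0.0 <= atom_percent < 100.0:
        raise InvalidIsotopeValueError(
            f"atom percent must be in [0, 100), got {atom_percent}"
        )
    return atom_fraction_to_delta(atom_percent / 100.0, reference_ratio)


@dataclass(frozen=True)
class IsotopeValue:
    """An isotopic composition in one of three interchangeable notations.

    ``kind`` is one of ``delta_permil``, ``atom_percent`` or
    ``atom_fraction``; ``reference_ratio`` is only consulted for delta
    conversions.
    """

    kind: str
    value: float
    reference_ratio: float = DEFAULT_SETTINGS.r13_standard

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidIsotopeValueError(f"unknown isotope notation {self.kind!r}")
        if self.kind == "atom_fraction" and not 0.0 <= self.value <= 1.0:
            raise InvalidIsotopeValueError(
                f"atom fraction must be in [0, 1], got {self.value}"
            )
        if self.kind == "atom_percent" and not 0.0 <= self.value <= 100.0:
            raise InvalidIsotopeValueError(
                f"atom percent must be in [0, 100], got {self.value}"
            )
        if self.kind == "delta_permil" and self.value <= -1000.0:
            raise InvalidIsotopeValueError("delta must exceed -1000 permil")

    def as_atom_fraction(self) -> float:
        if self.kind == "atom_fraction":
            return self.value
        if self.kind == "atom_percent":
            return self.value / 100.0
        return delta_to_atom_fraction(self.value, self.reference_ratio)

    def as_atom_percent(self) -> float:
        return 100.0 * self.as_atom_fraction()

    def as_delta(self) -> float:
        if self.kind == "delta_permil":
            return self.value
        return atom_fraction_to_delta(self.as_atom_fraction(), self.reference_ratio)


class ExcessResult(NamedTuple):
    """Atom-percent excess with below-background bookkeeping.

    ``value`` is clipped at zero for downstream mass balance;
    ``raw_difference`` retains the signed difference so QC reports can
    surface vials whose label reads below the natural-abundance control.
    """

    value: float
    below_background: bool
    raw_difference: float


def atom_percent_excess(sample: float, control: float) -> ExcessResult:
    """Atom percent excess of a labelled sample over its control.

    Negative differences are returned as zero with the
    ``below_background`` flag set; the raw difference is preserved.
    """
    for name, v in (("sample", sample), ("control", control)):
        if not 0.0 <= v <= 100.0:
            raise InvalidIsotopeValueError(
                f"{name} atom percent must be in [0, 100], got {v}"
            )
    diff = sample - control
    if diff < 0:
        return ExcessResult(0.0, True, diff)
    return ExcessResult(diff, False, diff)


def ppm_to_mass_c(
    ppm: float,
    headspace_volume_ml: float,
    temperature_c: float,
    pressure_atm: float = 1.0,
) -> float:
    """Carbon mass (µg) held as CO2 in a headspace at a given mixing ratio.

    Ideal-gas conversion: ``mol air = P V / (R T)``; the CO2 mole
    fraction (µmol/mol) then gives µg C via the molar mass of carbon.
    """
    if ppm < 0:
        raise DomainError(f"CO2 mixing ratio must be >= 0, got {ppm}")
    if headspace_volume_ml <= 0:
        raise DomainError(f"headspace volume must be positive, got {headspace_volume_ml}")
    if temperature_c <= -273.15:
        raise DomainError("temperature below absolute zero")
    if pressure_atm <= 0:
        raise DomainError("pressure must be positive")
    mol_air = pressure_atm * (headspace_volume_ml / 1000.0) / (
        R_GAS_L_ATM * (temperature_c + 273.15)
    )
    return ppm * 1e-6 * mol_air * MOLAR_MASS_C * 1e6


@dataclass
class HeadspaceObservation:
    """One vial's paired headspace CO2 measurements over an assay window.

    ``sampled_volume_ml`` is the gas volume removed right after the first
    measurement and replaced with synthetic air of known CO2 content
    (``replacement_co2_ppm``), so the start-of-window CO2 mass must be
    adjusted before differencing.  ``delta13c_t0/t1`` are optional and
    only required for label-derived respiration.
    """

    vial_volume_ml: float
    soil_fresh_mass_g: float
    dry_mass_fraction: float
    co2_ppm_t0: float | None
    co2_ppm_t1: float | None
    duration_h: float
    sampled_volume_ml: float = 0.0
    replacement_co2_ppm: float = 0.0
    replacement_delta13c: float | None = None
    delta13c_t0: float | None = None
    delta13c_t1: float | None = None
    temperature_c: float = 20.0
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise DomainError("assay duration must be positive")
        if not 0 < self.dry_mass_fraction <= 1:
            raise DomainError("dry mass fraction must be in (0, 1]")
        if self.soil_fresh_mass_g <= 0:
            raise DomainError("soil mass must be positive")
        for name in ("co2_ppm_t0", "co2_ppm_t1", "replacement_co2_ppm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def dry_soil_g(self) -> float:
        return self.soil_fresh_mass_g * self.dry_mass_fraction

    def headspace_volume_ml(self, bulk_density: float | None) -> float:
        """Gas volume of the vial: total volume minus the soil volume.

        The soil volume is estimated from the dry mass and a bulk
        density; ``bulk_density=None`` skips the correction.  For small
        soil amounts the correction is at the percent level.
        """
        if bulk_density is None:
            vol = self.vial_volume_ml
        else:
            vol = self.vial_volume_ml - self.dry_soil_g / bulk_density
        if vol <= 0:
            raise DomainError("soil volume exceeds vial volume")
        if self.sampled_volume_ml > vol:
            raise DomainError("sampled volume exceeds headspace volume")
        return vol


class RespirationResult(NamedTuple):
    """A respiration rate in ng C h^-1 g^-1 dry soil plus QC flags."""

    rate: float
    negative: bool


def respiration_rate(
    obs: HeadspaceObservation, settings: Settings = DEFAULT_SETTINGS
) -> RespirationResult:
    """Respiration rate from the CO2 accumulated between two measurements.

    The CO2 mass present right after the first measurement equals the
    measured mass reduced by the sampled fraction plus the CO2 carried
    in by the replacement air.  The rate is the adjusted mass difference
    divided by the window length and the dry-soil mass.  Negative rates
    are flagged, not clipped.
    """
    if obs.co2_ppm_t0 is None or obs.co2_ppm_t1 is None:
        raise IncompleteObservationError("both CO2 measurements are required")
    vol = obs.headspace_volume_ml(settings.bulk_density)
    mass_t0 = ppm_to_mass_c(obs.co2_ppm_t0, vol, obs.temperature_c, obs.pressure_atm)
    mass_t1 = ppm_to_mass_c(obs.co2_ppm_t1, vol, obs.temperature_c, obs.pressure_atm)
    replaced = 0.0
    if obs.sampled_volume_ml > 0:
        replaced = ppm_to_mass_c(
            obs.replacement_co2_ppm,
            obs.sampled_volume_ml,
            obs.temperature_c,
            obs.pressure_atm,
        )
    mass_t0_adj = mass_t0 * (1.0 - obs.sampled_volume_ml / vol) + replaced
    rate = (mass_t1 - mass_t0_adj) * 1000.0 / obs.duration_h / obs.dry_soil_g
    return RespirationResult(rate, rate < 0)


class WaterAddition(NamedTuple):
    """Water amount and stock enrichment required to hit the targets."""

    water_to_add: float
    required_stock_at_percent: float


def water_and_label_addition(
    current_water: float,
    whc: float,
    target_whc_fraction: float,
    target_at_percent: float,
    natural_at_percent: float,
) -> WaterAddition:
    """Wetting and labelling arithmetic for starting an assay.

    Computes the water to add (g per g dry soil) to reach the target
    fraction of water holding capacity, and the enrichment the added
    stock must have so that the final soil water — the mass-weighted
    mixture of pre-existing water at natural abundance and the added
    stock — hits the target atom percent.
    """
    if whc <= 0 or not 0 < target_whc_fraction <= 1:
        raise DomainError("invalid water holding capacity or target fraction")
    if current_water < 0:
        raise DomainError("current water content must be >= 0")
    if target_at_percent < natural_at_percent:
        raise DomainError("target enrichment below natural abundance")
    target_water = target_whc_fraction * whc
    if current_water >= target_water:
        raise DomainError(
            "soil already at or above the target water content; no addition possible"
        )
    add = target_water - current_water
    stock = (target_at_percent * target_water - natural_at_percent * current_water) / add
    return WaterAddition(add, stock)


def final_water_at_percent(
    current_water: float,
    water_added: float,
    stock_at_percent: float,
    natural_at_percent: float,
) -> float:
    """Forward two-pool mixing: enrichment of the final soil water."""
    total = current_water + water_added
    if total <= 0:
        raise DomainError("no water present")
    return (current_water * natural_at_percent + water_added * stock_at_percent) / total


def water_content(fresh_mass: float, dry_mass: float) -> float:
    """Gravimetric water content as a fraction of dry soil."""
    if dry_mass <= 0:
        raise DomainError("dry mass must be positive")
    if dry_mass > fresh_mass:
        raise DomainError("dry mass exceeds fresh mass")
    return (fresh_mass - dry_mass) / dry_mass
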