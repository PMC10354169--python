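"""13C-tracing stage: fumigation-extraction MBC and tracer partitioning.

Microbial biomass carbon (MBC) is the fumigated-minus-unfumigated
extractable organic carbon difference divided by the extraction
efficiency k_EC = 0.45.  Glucose-derived carbon in any pool follows the
two-pool mixing model: the fraction of pool carbon that is
tracer-derived is the pool's enrichment above background divided by the
tracer's enrichment above background.  Label in microbial biomass is the
difference of the label amounts in the fumigated and non-fumigated
extracts; label-derived respiration applies the same mixing model to the
headspace CO2 at both timepoints with the sampling/replacement
correction (replacement air carries natural-abundance CO2, hence no
label).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .config import Settings, DEFAULT_SETTINGS
from .errors import (
    ConfigError,
    DomainError,
    IncompleteObservationError,
)
from .isotope import HeadspaceObservation, delta_to_atom_percent, ppm_to_mass_c

__all__ = [
    "FumigationPair",
    "TracerDose",
    "mbc",
    "label_fraction",
    "label_in_pool",
    "label_in_mbc",
    "label_respiration",
    "dose_as_fraction_of_mbc",
    "extract_to_soil_basis",
]


@dataclass
class FumigationPair:
    """Extract C and 13C enrichment for a fumigated/non-fumigated pair.

    C amounts are µg C per g dry soil; enrichments are atom percent of
    the extract carbon.
    """

    eoc_fumigated: float
    eoc_nonfumigated: float
    c13_fumigated_at_percent: float | None = None
    c13_nonfumigated_at_percent: float | None = None
    extraction_efficiency: float = 0.45

    def __post_init__(self) -> None:
        if self.eoc_fumigated < 0 or self.eoc_nonfumigated < 0:
            raise DomainError("extract C amounts must be >= 0")
        if not 0 < self.extraction_efficiency <= 1:
            raise ConfigError(
                f"extraction efficiency must be in (0, 1], got {self.extraction_efficiency}"
            )


@dataclass(frozen=True)
class TracerDose:
    """A glucose tracer addition: amount and isotopic enrichment."""

    c_added_ug_per_g: float
    tracer_at_percent: float = 10.0
    natural_at_percent: float = DEFAULT_SETTINGS.natural_13c_at_percent

    def __post_init__(self) -> None:
        if self.c_added_ug_per_g <= 0:
            raise DomainError("tracer C dose must be positive")
        if self.tracer_at_percent <= self.natural_at_percent:
            raise DomainError("tracer enrichment must exceed natural abundance")


class MbcResult(NamedTuple):
    """MBC (µg C g^-1 dry soil); None with flag when the flush is negative."""

    value: float | None
    negative_flush: bool


def mbc(pair: FumigationPair) -> MbcResult:
    """Microbial biomass C from a fumigation-extraction pair.

    (fumigated - non-fumigated) extractable C divided by the extraction
    efficiency.  A negative flush is a flagged missing value, not a
    negative biomass.
    """
    diff = pair.eoc_fumigated - pair.eoc_nonfumigated
    if diff < 0:
        return MbcResult(None, True)
    return MbcResult(diff / pair.extraction_efficiency, False)


class LabelFraction(NamedTuple):
    """Tracer-derived fraction of a pool's C, clipped to [0, 1] with flags."""

    value: float
    below_background: bool
    above_tracer: bool


def label_fraction(
    pool_at_percent: float, control_at_percent: float, dose: TracerDose
) -> LabelFraction:
    """Fraction of pool C derived from the tracer (two-pool mixing).

    f = (at%_pool - at%_control) / (at%_tracer - at%_control), clipped
    to [0, 1] with the out-of-range direction flagged.
    """
    denom = dose.tracer_at_percent - control_at_percent
    if denom <= 0:
        raise DomainError(
            "control enrichment must lie below the tracer enrichment"
        )
    f = (pool_at_percent - control_at_percent) / denom
    if f < 0:
        return LabelFraction(0.0, True, False)
    if f > 1:
        return LabelFraction(1.0, False, True)
    return LabelFraction(f, False, False)


def label_in_pool(pool_c: float, fraction: float) -> float:
    """Tracer-derived C in a pool: pool C times tracer fraction."""
    if pool_c < 0:
        raise DomainError("pool C must be >= 0")
    return pool_c * fraction


class LabelInMbc(NamedTuple):
    """Tracer C in microbial biomass (µg C g^-1 dry soil) plus flags."""

    value: float
    below_background: bool


def label_in_mbc(
    pair: FumigationPair,
    dose: TracerDose,
    control_fumigated_at: float | None = None,
    control_nonfumigated_at: float | None = None,
    kec_correct: bool = False,
) -> LabelInMbc:
    """Tracer incorporation into microbial biomass.

    The difference between tracer-derived C in the fumigated and
    non-fumigated extracts.  Backgrounds default to the pair's own
    ``natural_at_percent`` via the dose; passing the paired water-only
    control's measured enrichments is preferred.  By default the result
    is NOT divided by the extraction efficiency — that correction
    applies to bulk MBC; ``kec_correct=True`` enables it.
    """
    if pair.c13_fumigated_at_percent is None or pair.c13_nonfumigated_at_percent is None:
        raise IncompleteObservationError(
            "both extract enrichments are required for label incorporation"
        )
    bg_f = dose.natural_at_percent if control_fumigated_at is None else control_fumigated_at
    bg_nf = (
        dose.natural_at_percent
        if control_nonfumigated_at is None
        else control_nonfumigated_at
    )
    f_fum = label_fraction(pair.c13_fumigated_at_percent, bg_f, dose)
    f_nf = label_fraction(pair.c13_nonfumigated_at_percent, bg_nf, dose)
    value = label_in_pool(pair.eoc_fumigated, f_fum.value) - label_in_pool(
        pair.eoc_nonfumigated, f_nf.value
    )
    below = value < 0
    if below:
        value = 0.0
    if kec_correct:
        value /= pair.extraction_efficiency
    return LabelInMbc(value, below)


class LabelRespiration(NamedTuple):
    """Tracer-derived respiration rate (ng C h^-1 g^-1) plus QC flag."""

    rate: float
    negative: bool


def label_respiration(
    obs: HeadspaceObservation,
    dose: TracerDose,
    control_at_percent: float | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> LabelRespiration:
    """Tracer-derived respiration from headspace CO2 and its delta 13C.

    Each timepoint's CO2 carbon mass is split into tracer-derived and
    native carbon with the mixing model; the start-of-window tracer mass
    is reduced by the sampled fraction (replacement air is at natural
    abundance and carries no tracer).  The rate is the tracer-mass
    difference over window length and dry-soil mass.
    """
    if obs.delta13c_t0 is None or obs.delta13c_t1 is None:
        raise IncompleteObservationError(
            "delta 13C at both timepoints is required for label respiration"
        )
    if obs.co2_ppm_t0 is None or obs.co2_ppm_t1 is None:
        raise IncompleteObservationError("both CO2 measurements are required")
    bg = dose.natural_at_percent if control_at_percent is None else control_at_percent
    vol = obs.headspace_volume_ml(settings.bulk_density)
    mass_t0 = ppm_to_mass_c(obs.co2_ppm_t0, vol, obs.temperature_c, obs.pressure_atm)
    mass_t1 = ppm_to_mass_c(obs.co2_ppm_t1, vol, obs.temperature_c, obs.pressure_atm)
    ap_t0 = delta_to_atom_percent(obs.delta13c_t0, settings.r13_standard)
    ap_t1 = delta_to_atom_percent(obs.delta13c_t1, settings.r13_standard)
    label_t0 = mass_t0 * label_fraction(ap_t0, bg, dose).value
    label_t1 = mass_t1 * label_fraction(ap_t1, bg, dose).value
    label_t0_adj = label_t0 * (1.0 - obs.sampled_volume_ml / vol)
    rate = (label_t1 - label_t0_adj) * 1000.0 / obs.duration_h / obs.dry_soil_g
    return LabelRespiration(rate, rate < 0)


def dose_as_fraction_of_mbc(dose: TracerDose, mbc_ug_per_g: float) -> float:
    """Tracer C dose as a percentage of microbial biomass C."""
    if mbc_ug_per_g <= 0:
        raise DomainError("MBC must be positive")
    return 100.0 * dose.c_added_ug_per_g / mbc_ug_per_g


def extract_to_soil_basis(
    concentration_ug_per_ml: float,
    extract_volume_ml: float,
    soil_fresh_mass_g: float,
    dry_mass_fraction: float,
) -> float:
    """Convert an extract C concentration to µg C per g dry soil.

    Uses the extraction geometry (e.g. 15 mL of 0.5 M K2SO4 on 2 g of
    fresh soil) and the subsample's dry-mass fraction.
    """
    if extract_volume_ml <= 0 or soil_fresh_mass_g <= 0:
        raise DomainError("extract volume and soil mass must be positive")
    if not 0 < dry_mass_fraction <= 1:
        raise DomainError("dry mass fraction must be in (0, 1]")
    dry = soil_fresh_mass_g * dry_mass_fraction
    return concentration_ug_per_ml * extract_volume_ml / dry
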