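"""18O-tracing stage: DNA production, microbial growth, CUE, response ratios.

Microbial growth is measured by the incorporation of 18O from labelled
soil water into DNA.  The amount of DNA newly synthesised over the assay
window follows from the 18O excess of the labelled extract over its
natural-abundance pair, scaled by the extract oxygen amount, the soil
water enrichment and the mean oxygen content of DNA.  Growth in carbon
units divides new DNA by the total DNA pool and multiplies by microbial
biomass carbon; carbon use efficiency is growth over growth plus
respiration.  Cooling sensitivity is summarised by the response ratio,
the value of a parameter at 11 °C over its value at 1 °C in the same
field plot.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .config import Settings, DEFAULT_SETTINGS
from .errors import DomainError, InvalidIsotopeValueError
from .isotope import atom_percent_excess

__all__ = [
    "DnaIsotopeObservation",
    "RateResult",
    "ResponseRatio",
    "dna_produced",
    "growth_rate",
    "cue",
    "response_ratio",
]


@dataclass
class DnaIsotopeObservation:
    """Paired labelled / natural-abundance DNA isotope measurements.

    ``o_dna_extract_ug`` is the total oxygen (µg) in the DNA extract of
    the labelled vial; ``dna_total_ug_per_g`` the DNA pool per g dry
    soil; ``at_percent_soil_water`` the 18O enrichment of the final soil
    water in the labelled vial.
    """

    o_dna_extract_ug: float
    at_percent_labeled: float
    at_percent_natural: float
    at_percent_soil_water: float
    dna_total_ug_per_g: float
    duration_h: float
    dry_soil_g: float

    def __post_init__(self) -> None:
        for name in ("o_dna_extract_ug", "dna_total_ug_per_g", "dry_soil_g"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.duration_h <= 0:
            raise DomainError("duration must be positive")
        for name in ("at_percent_labeled", "at_percent_natural", "at_percent_soil_water"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise InvalidIsotopeValueError(f"{name} must be in [0, 100], got {v}")


class DnaProduced(NamedTuple):
    """New DNA over the window (µg, same basis as the extract oxygen)."""

    amount: float
    below_background: bool


def dna_produced(
    obs: DnaIsotopeObservation, settings: Settings = DEFAULT_SETTINGS
) -> DnaProduced:
    """DNA newly produced during the assay, from 18O incorporation.

    new DNA = O_extract * (at%_labelled - at%_natural) / at%_soil_water
              * 100 / 31.21

    where 31.21 is the mean oxygen mass percent of DNA.  A labelled
    enrichment below the natural-abundance pair yields zero with the
    below-background flag set.
    """
    if obs.at_percent_soil_water <= 0:
        raise DomainError("soil water enrichment must be positive")
    excess = atom_percent_excess(obs.at_percent_labeled, obs.at_percent_natural)
    amount = (
        obs.o_dna_extract_ug
        * excess.value
        / obs.at_percent_soil_water
        * 100.0
        / settings.dna_oxygen_percent
    )
    return DnaProduced(amount, excess.below_background)


def growth_rate(
    dna_prod_ug: float,
    dna_total_ug: float,
    mbc_ug_per_g: float,
    duration_h: float,
) -> float:
    """Microbial growth in ng C h^-1 g^-1 dry soil.

    New DNA divided by the total DNA pool gives the fraction of the
    microbial biomass produced over the window; multiplying by MBC and
    dividing by the window length yields a carbon growth rate.  The DNA
    amounts must share a basis (both per g dry soil, or both totals for
    the same soil mass).
    """
    if dna_total_ug <= 0:
        raise DomainError("total DNA must be positive")
    if duration_h <= 0:
        raise DomainError("duration must be positive")
    if dna_prod_ug < 0 or mbc_ug_per_g < 0:
        raise DomainError("DNA produced and MBC must be >= 0")
    return dna_prod_ug / dna_total_ug * mbc_ug_per_g * 1000.0 / duration_h


def cue(growth: float, respiration: float) -> float | None:
    """Carbon use efficiency: growth / (growth + respiration).

    Computed per replicate; returns ``None`` (undefined, a missing
    value rather than zero) when both rates are zero.
    """
    if growth < 0 or respiration < 0:
        raise DomainError("CUE requires non-negative growth and respiration")
    total = growth + respiration
    if total == 0:
        return None
    return growth / total


@dataclass(frozen=True)
class ResponseRatio:
    """Cooling response ratio of one parameter: value at 11 °C over 1 °C."""

    parameter: str
    r11: float
    r1: float
    rr: float | None
    undefined: bool = False


def response_ratio(parameter: str, r11: float, r1: float) -> ResponseRatio:
    """Response ratio RR = R11 / R1 for one matched plot replicate.

    A zero denominator yields an undefined ratio (flagged missing value).
    Summaries (mean ± SE over plots) are computed downstream.
    """
    if r1 == 0:
        return ResponseRatio(parameter, r11, r1, None, undefined=True)
    return ResponseRatio(parameter, r11, r1, r11 / r1)
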