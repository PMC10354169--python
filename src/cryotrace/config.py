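"""Physical constants and run configuration.

The defaults are the values used throughout the pipeline; every one of
them can be overridden from a flat TOML file (``[constants]`` table or
top-level keys) so that alternative reference ratios, bulk densities or
pressures can be supplied without touching code.
"""
from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

#: Gas constant in L atm mol^-1 K^-1.
R_GAS_L_ATM = 0.082057

#: Molar mass of carbon, g mol^-1.
MOLAR_MASS_C = 12.011

#: 13C/12C ratio of the VPDB standard.
R13_VPDB = 0.0111802

#: Natural-abundance 18O atom percent of terrestrial water/biomass.
NATURAL_18O_AT_PERCENT = 0.2005

#: Natural-abundance 13C atom percent (corresponds to roughly -26 permil).
NATURAL_13C_AT_PERCENT = 1.08

#: Mean oxygen mass content of DNA, percent.
DNA_OXYGEN_PERCENT = 31.21

#: Chloroform fumigation extraction efficiency k_EC for microbial biomass C.
KEC_DEFAULT = 0.45

#: Soil bulk density used to estimate soil volume inside vials, g cm^-3.
BULK_DENSITY_DEFAULT = 1.3


@dataclasses.dataclass
class Settings:
    """Run-wide constants for the pipeline.

    Attributes
    ----------
    r13_standard : float
        13C/12C isotope ratio of the delta reference standard (VPDB).
    natural_18o_at_percent : float
        18O natural-abundance background, atom percent.
    natural_13c_at_percent : float
        13C natural-abundance background used as a fallback when no
        paired water-only control is available, atom percent.
    dna_oxygen_percent : float
        Average oxygen content of DNA, mass percent.
    kec : float
        Fumigation extraction efficiency applied to bulk MBC.
    bulk_density : float or None
        Soil bulk density (g cm^-3) for the headspace-volume correction;
        ``None`` disables the correction and treats the vial volume as
        the headspace volume.
    pressure_atm : float
        Headspace pressure assumed for ideal-gas conversions.
    kec_correct_label : bool
        Whether the biomass label increment is also divided by ``kec``
        (off by default: the efficiency correction is applied to bulk
        MBC only).
    """

    r13_standard: float = R13_VPDB
    natural_18o_at_percent: float = NATURAL_18O_AT_PERCENT
    natural_13c_at_percent: float = NATURAL_13C_AT_PERCENT
    dna_oxygen_percent: float = DNA_OXYGEN_PERCENT
    kec: float = KEC_DEFAULT
    bulk_density: float | None = BULK_DENSITY_DEFAULT
    pressure_atm: float = 1.0
    kec_correct_label: bool = False

    def __post_init__(self) -> None:
        from .errors import ConfigError

        if self.kec <= 0 or self.kec > 1:
            raise ConfigError(f"extraction efficiency must be in (0, 1], got {self.kec}")
        if self.r13_standard <= 0:
            raise ConfigError("reference isotope ratio must be positive")
        if self.pressure_atm <= 0:
            raise ConfigError("pressure must be positive")
        if self.bulk_density is not None and self.bulk_density <= 0:
            raise ConfigError("bulk density must be positive or None")

    @classmethod
    def from_toml(cls, path: str | Path) -> "Settings":
        """Load settings from a flat TOML file.

        Keys may live at the top level or under a ``[constants]`` table;
        unknown keys are rejected so typos do not silently fall back to
        defaults.
        """
        from .errors import ConfigError

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "constants" in raw and isinstance(raw["constants"], dict):
            raw = {**{k: v for k, v in raw.items() if k != "constants"}, **raw["constants"]}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


DEFAULT_SETTINGS = Settings()
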