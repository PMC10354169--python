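"""Seeded forward simulator of the two-site soil-cooling experiment.

The simulator generates the five raw measurement tables (sample
metadata, headspace CO2 for both isotope assays, DNA 18O isotopes,
fumigation-extraction pairs, PLFA marker profiles) from a set of known
truth parameters, so that every pipeline stage can be verified by
parameter recovery: at zero noise the pipeline inverts the generative
model exactly, and under instrument noise replicate means converge to
the truth.

The design it emulates: two sites (an agricultural cropland and a beech
forest differing ~5–14x in pools and rates), two incubation
temperatures (1 and 11 °C), two 42-h assay windows (an immediate 0–42 h
response and a 144–186 h acclimation window), four field-plot
replicates, glucose or water amendment, an 18O-water arm paired with a
natural-abundance arm (27 mL vials), and a 13C-glucose arm paired with
a water-only control (50 mL vials, 15 mL headspace sampling replaced
with synthetic air).

Noise is multiplicative lognormal (mean-preserving) for amounts, CO2
mixing ratios and detector areas, and additive Gaussian on the
atom-percent scale for isotope values; between-plot variability is a
per-plot lognormal multiplier shared across temperatures, mirroring the
fact that each field plot was split between incubators.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .config import DEFAULT_SETTINGS, MOLAR_MASS_C
from .errors import ConfigError
from .isotope import (
    HeadspaceObservation,
    atom_percent_to_delta,
    ppm_to_mass_c,
)

__all__ = [
    "SiteTruth",
    "NoiseModel",
    "TruthParameters",
    "SyntheticExperiment",
    "default_truth",
    "simulate",
    "reference_site_summary",
    "RATE_PARAMETERS",
]

#: Rate parameters carried per site (ng C h^-1 g^-1 dry soil at 11 °C).
RATE_PARAMETERS = (
    "respiration",
    "growth",
    "label_respiration",
    "label_mbc",
    "label_plfa",
)

TEMPERATURES = (1.0, 11.0)
WINDOWS = (42.0, 186.0)
ASSAY_DURATION_H = 42.0

# Vial geometry per assay: (vial volume mL, fresh soil g, sampled mL)
GEOMETRY_18O = (27.0, 0.4, 5.0)
GEOMETRY_13C = (50.0, 10.0, 15.0)
AMBIENT_CO2_PPM = 420.0
REPLACEMENT_CO2_PPM = 400.0

# Freeze-dried soil aliquots used for the PLFA extraction (fresh g).
PLFA_SOIL_FRESH_G = {"agricultural": 2.0, "forest": 1.0}
PLFA_IS_AREA = 1.0e6
PLFA_IS_AMOUNT_NMOL = 100.0

#: Within-group biomass composition of the marker profile (fractions of
#: the group's C).  Markers and the grouping itself live in the packaged
#: marker table; these weights only shape the synthetic chromatograms.
MARKER_WEIGHTS = {
    "bacterial": {
        "a15:0": 0.14,
        "i16:0": 0.16,
        "16:1ω7": 0.20,
        "10Me16:0": 0.12,
        "a17:0": 0.08,
        "cy17:0": 0.12,
        "10Me18:0": 0.08,
        "cy19:0": 0.10,
    },
    "fungal": {"18:1ω9cis": 0.55, "18:2ω6,9": 0.45},
    "general": {
        "15:0": 0.06,
        "16:0": 0.40,
        "16:1ω5": 0.10,
        "16:1ω9": 0.08,
        "17:0": 0.08,
        "18:1ω9trans": 0.14,
        "19:1ω9": 0.14,
    },
}
UNSATURATED_MARKERS = {
    "16:1ω5",
    "16:1ω7",
    "16:1ω9",
    "18:1ω9cis",
    "18:1ω9trans",
    "18:2ω6,9",
    "19:1ω9",
}


def _check_simplex(d: dict, name: str, tol: float = 1e-9) -> None:
    vals = np.array(list(d.values()), dtype=float)
    if (vals < 0).any() or abs(vals.sum() - 1.0) > tol:
        raise ConfigError(f"{name} must be a simplex (non-negative, summing to 1): {d}")


@dataclass
class SiteTruth:
    """Ground-truth pools, rates and effect structure for one site.

    Rates are the glucose-amended values at 11 °C in the immediate
    window; the 1 °C values follow from the response ratios, the
    acclimation-window values from the 11 °C acclimation multipliers,
    and the water-amended values from the glucose-effect multipliers.
    """

    name: str
    # pools
    soc_ug_per_g: float
    mbc_ug_per_g: float
    eoc_ug_per_g: float
    dna_total_ug_per_g: float
    total_plfa_nmol_per_g: float
    whc_g_per_g: float
    glucose_dose_ug_per_g: float
    # reference rates (11 C, immediate window, glucose-amended)
    rate_11: dict[str, float] = field(default_factory=dict)
    # response ratios (11 C / 1 C) per parameter and window
    rr42: dict[str, float] = field(default_factory=dict)
    rr186: dict[str, float] = field(default_factory=dict)
    # multiplier on the 11 C rate for the acclimation window
    acclim11: dict[str, float] = field(default_factory=dict)
    # glucose-over-water effect on the bulk rates
    glucose_effect: dict[str, float] = field(
        default_factory=lambda: {"respiration": 1.2, "growth": 1.1}
    )
    # biomass composition across the disjoint marker groups
    group_biomass: dict[str, float] = field(default_factory=dict)
    # tracer allocation simplex across marker groups, per temperature
    label_groups: dict[float, dict[str, float]] = field(default_factory=dict)
    # share of a group's tracer placed on its unsaturated markers
    unsat_weight: dict[float, dict[str, float]] = field(default_factory=dict)
    # fraction of the dose remaining as non-biomass extractable C
    residual_label_eoc_fraction: float = 0.30

    def __post_init__(self) -> None:
        for pool in (
            "soc_ug_per_g",
            "mbc_ug_per_g",
            "eoc_ug_per_g",
            "dna_total_ug_per_g",
            "total_plfa_nmol_per_g",
            "whc_g_per_g",
            "glucose_dose_ug_per_g",
        ):
            if getattr(self, pool) <= 0:
                raise ConfigError(f"{pool} must be positive")
        for p in RATE_PARAMETERS:
            if self.rate_11.get(p, 0) <= 0:
                raise ConfigError(f"rate_11[{p!r}] must be positive")
            for d, label in ((self.rr42, "rr42"), (self.rr186, "rr186")):
                if d.get(p, 0) <= 0:
                    raise ConfigError(f"{label}[{p!r}] must be positive")
        _check_simplex(self.group_biomass, f"{self.name} group_biomass")
        for temp, simplex in self.label_groups.items():
            _check_simplex(simplex, f"{self.name} label_groups[{temp}]")
        if not 0 <= self.residual_label_eoc_fraction < 1:
            raise ConfigError("residual label fraction must be in [0, 1)")

    @property
    def dry_mass_fraction(self) -> float:
        """Dry/fresh mass ratio of soil wetted to 60% WHC."""
        return 1.0 / (1.0 + 0.6 * self.whc_g_per_g)

    def design_rate(
        self, parameter: str, temperature: float, window: float, amendment: str
    ) -> float:
        """Noiseless design value of a rate for one condition."""
        if parameter.startswith("label") and amendment != "glucose":
            return 0.0
        base = self.rate_11[parameter]
        if window == 186.0:
            base *= self.acclim11.get(parameter, 1.0)
        if amendment == "water" and parameter in self.glucose_effect:
            base /= self.glucose_effect[parameter]
        if temperature == 1.0:
            rr = (self.rr42 if window == 42.0 else self.rr186)[parameter]
            base /= rr
        return base

    def unsaturated_share(self, temperature: float) -> float:
        """Tracer fraction landing on unsaturated markers (derived)."""
        g = self.label_groups[temperature]
        w = self.unsat_weight[temperature]
        return g["fungal"] + g["bacterial"] * w["bacterial"] + g["general"] * w["general"]


@dataclass
class NoiseModel:
    """Instrument and between-plot variability (coefficients of variation).

    ``cv_gas`` applies to CO2 mixing ratios, ``cv_extract`` to extract C
    and DNA amounts, ``cv_area`` to chromatogram areas (all
    mean-preserving lognormal); ``sd_at_percent`` is the absolute
    Gaussian standard deviation of isotope readings on the atom-percent
    scale; ``plot_cv`` is the between-plot lognormal CV shared across
    temperatures within a plot.
    """

    cv_gas: float = 0.03
    sd_at_percent: float = 0.02
    cv_extract: float = 0.05
    cv_area: float = 0.05
    plot_cv: float = 0.10

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class TruthParameters:
    """Complete specification of one synthetic experiment."""

    sites: tuple[SiteTruth, ...]
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_plots: int = 4
    soil_water_at_percent: float = 20.0
    tracer_at_percent: float = 10.0
    natural_18o_at_percent: float = DEFAULT_SETTINGS.natural_18o_at_percent
    natural_13c_at_percent: float = DEFAULT_SETTINGS.natural_13c_at_percent

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ConfigError("need at least one plot")
        if self.tracer_at_percent <= self.natural_13c_at_percent:
            raise ConfigError("tracer enrichment must exceed natural abundance")

    def zero_noise(self) -> "TruthParameters":
        return dataclasses.replace(self, noise=NoiseModel.zero())


@dataclass
class SyntheticExperiment:
    """A generated experiment: raw tables plus the truth that made them."""

    truth: TruthParameters
    tables: dict[str, pd.DataFrame]
    truth_values: pd.DataFrame

    def truth_dict(self) -> dict:
        """Nested truth values for JSON serialisation."""
        out: dict = {}
        for row in self.truth_values.itertuples(index=False):
            key = f"{row.site}|T{row.temperature_c:g}|w{row.window_h:g}|{row.amendment}"
            out.setdefault(key, {})[row.parameter] = row.value
        return out


def default_truth() -> TruthParameters:
    """Truth parameters matching the published site contrasts.

    Pools and reference rates reproduce the published 11 °C / immediate
    window site means; the response-ratio structure reproduces the
    published cooling response ratios for both windows.  Quantities not
    published numerically (PLFA-bound tracer, allocation simplices,
    acclimation multipliers) are set to plausible values with the
    published direction of change.
    """
    agricultural = SiteTruth(
        name="agricultural",
        soc_ug_per_g=8864.0,
        mbc_ug_per_g=45.15,
        eoc_ug_per_g=40.0,
        dna_total_ug_per_g=8.0,
        total_plfa_nmol_per_g=145.3,
        whc_g_per_g=0.385,
        glucose_dose_ug_per_g=10.0,
        rate_11={
            "respiration": 119.9,
            "growth": 87.98,
            "label_respiration": 23.11,
            "label_mbc": 58.29,
            "label_plfa": 5.0,
        },
        rr42={
            "respiration": 3.30,
            "growth": 2.74,
            "label_respiration": 1.41,
            "label_mbc": 0.78,
            "label_plfa": 1.51,
        },
        rr186={
            "respiration": 2.61,
            "growth": 5.92,
            "label_respiration": 1.36,
            "label_mbc": 0.97,
            "label_plfa": 1.42,
        },
        acclim11={
            "respiration": 0.85,
            "growth": 0.90,
            "label_respiration": 1.00,
            "label_mbc": 1.25,
            "label_plfa": 0.90,
        },
        group_biomass={"bacterial": 0.45, "fungal": 0.15, "general": 0.40},
        label_groups={
            11.0: {"bacterial": 0.50, "fungal": 0.18, "general": 0.32},
            1.0: {"bacterial": 0.50, "fungal": 0.22, "general": 0.28},
        },
        unsat_weight={
            11.0: {"bacterial": 0.50, "general": 0.50},
            1.0: {"bacterial": 0.70, "general": 0.70},
        },
    )
    forest = SiteTruth(
        name="forest",
        soc_ug_per_g=45641.0,
        mbc_ug_per_g=294.3,
        eoc_ug_per_g=250.0,
        dna_total_ug_per_g=55.0,
        total_plfa_nmol_per_g=1975.0,
        whc_g_per_g=0.75,
        glucose_dose_ug_per_g=50.0,
        rate_11={
            "respiration": 975.2,
            "growth": 569.9,
            "label_respiration": 101.1,
            "label_mbc": 229.4,
            "label_plfa": 40.0,
        },
        rr42={
            "respiration": 3.28,
            "growth": 4.26,
            "label_respiration": 1.20,
            "label_mbc": 1.04,
            "label_plfa": 1.60,
        },
        rr186={
            "respiration": 2.79,
            "growth": 3.43,
            "label_respiration": 1.34,
            "label_mbc": 0.98,
            "label_plfa": 1.19,
        },
        acclim11={
            "respiration": 0.85,
            "growth": 0.85,
            "label_respiration": 1.00,
            "label_mbc": 1.00,
            "label_plfa": 0.75,
        },
        group_biomass={"bacterial": 0.35, "fungal": 0.30, "general": 0.35},
        label_groups={
            11.0: {"bacterial": 0.40, "fungal": 0.30, "general": 0.30},
            1.0: {"bacterial": 0.50, "fungal": 0.28, "general": 0.22},
        },
        unsat_weight={
            11.0: {"bacterial": 0.50, "general": 0.50},
            1.0: {"bacterial": 0.70, "general": 0.70},
        },
    )
    return TruthParameters(sites=(agricultural, forest))


def reference_site_summary() -> pd.DataFrame:
    """Published site-comparison summary (means ± SE, 11 °C, immediate window).

    Bundled as package data and used by the ratio benchmarks; not a
    simulated quantity.
    """
    with resources.files("cryotrace.data").joinpath("reference_site_summary.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# forward simulation


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-preserving multiplicative lognormal noise factor(s)."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _at_noise(rng: np.random.Generator, sd: float) -> float:
    return float(rng.normal(0.0, sd)) if sd > 0 else 0.0


def _headspace_forward(
    rng: np.random.Generator,
    *,
    geometry: tuple[float, float, float],
    dry_mass_fraction: float,
    temperature: float,
    rate_total: float,
    rate_label: float | None,
    tracer_at: float,
    natural_at: float,
    r13: float,
    noise: NoiseModel,
) -> dict:
    """Generate one vial's headspace record from true rates."""
    vial, fresh, sampled = geometry
    m_dry = fresh * dry_mass_fraction
    obs = HeadspaceObservation(
        vial_volume_ml=vial,
        soil_fresh_mass_g=fresh,
        dry_mass_fraction=dry_mass_fraction,
        co2_ppm_t0=AMBIENT_CO2_PPM,
        co2_ppm_t1=AMBIENT_CO2_PPM,
        duration_h=ASSAY_DURATION_H,
        sampled_volume_ml=sampled,
        replacement_co2_ppm=REPLACEMENT_CO2_PPM,
        temperature_c=temperature,
    )
    vol = obs.headspace_volume_ml(DEFAULT_SETTINGS.bulk_density)
    mass0 = ppm_to_mass_c(AMBIENT_CO2_PPM, vol, temperature)
    mass0_adj = mass0 * (1.0 - sampled / vol) + ppm_to_mass_c(
        REPLACEMENT_CO2_PPM, sampled, temperature
    )
    mass1 = mass0_adj + rate_total * ASSAY_DURATION_H * m_dry / 1000.0
    ug_per_ppm = ppm_to_mass_c(1.0, vol, temperature)
    ppm1 = mass1 / ug_per_ppm
    rec = {
        "vial_volume_ml": vial,
        "soil_fresh_mass_g": fresh,
        "dry_mass_fraction": dry_mass_fraction,
        "co2_ppm_t0": AMBIENT_CO2_PPM * _lognormal_factor(rng, noise.cv_gas),
        "co2_ppm_t1": ppm1 * _lognormal_factor(rng, noise.cv_gas),
        "sampled_volume_ml": sampled,
        "replacement_co2_ppm": REPLACEMENT_CO2_PPM,
        "gas_temperature_c": temperature,
        "pressure_atm": 1.0,
        "duration_h": ASSAY_DURATION_H,
        "delta13c_t0": np.nan,
        "delta13c_t1": np.nan,
        "replacement_delta13c": np.nan,
    }
    if rate_label is not None:
        label1 = rate_label * ASSAY_DURATION_H * m_dry / 1000.0
        ap1 = natural_at + (label1 / mass1) * (tracer_at - natural_at)
        ap0_meas = max(natural_at + _at_noise(rng, noise.sd_at_percent), 1e-6)
        ap1_meas = max(ap1 + _at_noise(rng, noise.sd_at_percent), 1e-6)
        rec["delta13c_t0"] = atom_percent_to_delta(ap0_meas, r13)
        rec["delta13c_t1"] = atom_percent_to_delta(ap1_meas, r13)
        rec["replacement_delta13c"] = atom_percent_to_delta(natural_at, r13)
    return rec


def simulate(truth: TruthParameters, seed: int) -> SyntheticExperiment:
    """Generate the raw measurement tables for one experiment.

    Deterministic given ``(truth, seed)``.  Returns the tables keyed
    ``sample_meta``, ``headspace``, ``dna_isotope``, ``fumigation`` and
    ``plfa`` plus a tidy table of true condition-level values for
    recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise = truth.noise
    r13 = DEFAULT_SETTINGS.r13_standard
    nat13 = truth.natural_13c_at_percent
    nat18 = truth.natural_18o_at_percent

    meta_rows: list[dict] = []
    headspace_rows: list[dict] = []
    dna_rows: list[dict] = []
    fum_rows: list[dict] = []
    plfa_rows: list[dict] = []
    truth_rows: list[dict] = []

    pool_keys = ("mbc", "eoc", "dna", "plfa", "resp", "growth", "lresp", "lmbc", "lplfa")

    for site in truth.sites:
        dmf = site.dry_mass_fraction
        dose = site.glucose_dose_ug_per_g
        # per-plot multipliers, shared across temperatures and windows
        plot_eff = {
            plot: {k: float(_lognormal_factor(rng, noise.plot_cv)) for k in pool_keys}
            for plot in range(1, truth.n_plots + 1)
        }
        for temp in TEMPERATURES:
            for window in WINDOWS:
                # condition-level truth (design values)
                for amendment in ("glucose", "water"):
                    resp = site.design_rate("respiration", temp, window, amendment)
                    grow = site.design_rate("growth", temp, window, amendment)
                    rows = {
                        "respiration": resp,
                        "growth": grow,
                        "cue": grow / (grow + resp),
                        "mbc": site.mbc_ug_per_g,
                        "total_plfa": site.total_plfa_nmol_per_g,
                    }
                    if amendment == "glucose":
                        rows.update(
                            {
                                p: site.design_rate(p, temp, window, amendment)
                                for p in (
                                    "label_respiration",
                                    "label_mbc",
                                    "label_plfa",
                                )
                            }
                        )
                        rows.update(
                            {
                                f"allocation_{g}": site.label_groups[temp][g]
                                for g in ("bacterial", "fungal", "general")
                            }
                        )
                        rows["allocation_unsaturated"] = site.unsaturated_share(temp)
                    for param, value in rows.items():
                        truth_rows.append(
                            {
                                "site": site.name,
                                "temperature_c": temp,
                                "window_h": window,
                                "amendment": amendment,
                                "parameter": param,
                                "value": value,
                            }
                        )

                for plot in range(1, truth.n_plots + 1):
                    eff = plot_eff[plot]
                    mbc_p = site.mbc_ug_per_g * eff["mbc"]
                    eoc_p = site.eoc_ug_per_g * eff["eoc"]
                    dna_p = site.dna_total_ug_per_g * eff["dna"]
                    plfa_p = site.total_plfa_nmol_per_g * eff["plfa"]
                    base = {
                        "site": site.name,
                        "plot": plot,
                        "temperature_c": temp,
                        "window_h": window,
                    }

                    # ---- 18O assay: 2 amendments x 2 label arms -------
                    for amendment in ("glucose", "water"):
                        resp_p = (
                            site.design_rate("respiration", temp, window, amendment)
                            * eff["resp"]
                        )
                        for arm in ("18O", "na"):
                            sid = (
                                f"{site.name[:3]}-p{plot}-T{temp:g}-w{window:g}-"
                                f"{amendment}-{arm}-18O"
                            )
                            rec = _headspace_forward(
                                rng,
                                geometry=GEOMETRY_18O,
                                dry_mass_fraction=dmf,
                                temperature=temp,
                                rate_total=resp_p,
                                rate_label=None,
                                tracer_at=truth.tracer_at_percent,
                                natural_at=nat13,
                                r13=r13,
                                noise=noise,
                            )
                            meta_rows.append(
                                {
                                    "sample_id": sid,
                                    **base,
                                    "amendment": amendment,
                                    "label_arm": arm,
                                    "assay": "18O",
                                }
                            )
                            headspace_rows.append(
                                {"sample_id": sid, **base, "amendment": amendment,
                                 "label_arm": arm, "assay": "18O", **rec}
                            )

                        # DNA isotope record (labelled/natural pair)
                        grow_p = (
                            site.design_rate("growth", temp, window, amendment)
                            * eff["growth"]
                        )
                        m_dry = GEOMETRY_18O[1] * dmf
                        excess = (
                            grow_p
                            * ASSAY_DURATION_H
                            * truth.soil_water_at_percent
                            / (mbc_p * 1000.0)
                        )
                        dna_rows.append(
                            {
                                "sample_id": (
                                    f"{site.name[:3]}-p{plot}-T{temp:g}-w{window:g}-"
                                    f"{amendment}-18O-18O"
                                ),
                                **base,
                                "amendment": amendment,
                                "o_dna_extract_ug": dna_p
                                * m_dry
                                * (DEFAULT_SETTINGS.dna_oxygen_percent / 100.0)
                                * float(_lognormal_factor(rng, noise.cv_extract)),
                                "at_percent_labeled": max(
                                    nat18 + excess + _at_noise(rng, noise.sd_at_percent),
                                    0.0,
                                ),
                                "at_percent_natural": max(
                                    nat18 + _at_noise(rng, noise.sd_at_percent), 0.0
                                ),
                                "at_percent_soil_water": truth.soil_water_at_percent,
                                "dna_total_ug_per_g": dna_p
                                * float(_lognormal_factor(rng, noise.cv_extract)),
                                "duration_h": ASSAY_DURATION_H,
                                "dry_soil_g": m_dry,
                            }
                        )

                    # ---- 13C assay: glucose (labelled) + water control -
                    for amendment, arm in (("glucose", "13C"), ("water", "na")):
                        resp_p = (
                            site.design_rate("respiration", temp, window, amendment)
                            * eff["resp"]
                        )
                        lresp_p = (
                            site.design_rate("label_respiration", temp, window, amendment)
                            * eff["lresp"]
                            if amendment == "glucose"
                            else None
                        )
                        sid = (
                            f"{site.name[:3]}-p{plot}-T{temp:g}-w{window:g}-"
                            f"{amendment}-{arm}-13C"
                        )
                        rec = _headspace_forward(
                            rng,
                            geometry=GEOMETRY_13C,
                            dry_mass_fraction=dmf,
                            temperature=temp,
                            rate_total=resp_p,
                            rate_label=lresp_p if amendment == "glucose" else 0.0,
                            tracer_at=truth.tracer_at_percent,
                            natural_at=nat13,
                            r13=r13,
                            noise=noise,
                        )
                        meta_rows.append(
                            {
                                "sample_id": sid,
                                **base,
                                "amendment": amendment,
                                "label_arm": arm,
                                "assay": "13C",
                            }
                        )
                        headspace_rows.append(
                            {"sample_id": sid, **base, "amendment": amendment,
                             "label_arm": arm, "assay": "13C", **rec}
                        )

                        # fumigation-extraction pair
                        if amendment == "glucose":
                            residual = site.residual_label_eoc_fraction * dose
                            lmbc_amt = (
                                site.design_rate("label_mbc", temp, window, amendment)
                                * eff["lmbc"]
                                * ASSAY_DURATION_H
                                / 1000.0
                            )
                        else:
                            residual = 0.0
                            lmbc_amt = 0.0
                        eoc_nf = eoc_p + residual
                        eoc_f = eoc_nf + mbc_p * DEFAULT_SETTINGS.kec
                        label_nf = residual
                        label_f = residual + lmbc_amt
                        ap_nf = nat13 + (label_nf / eoc_nf) * (
                            truth.tracer_at_percent - nat13
                        )
                        ap_f = nat13 + (label_f / eoc_f) * (
                            truth.tracer_at_percent - nat13
                        )
                        fum_rows.append(
                            {
                                "sample_id": sid,
                                **base,
                                "amendment": amendment,
                                "label_arm": arm,
                                "eoc_fumigated": eoc_f
                                * float(_lognormal_factor(rng, noise.cv_extract)),
                                "eoc_nonfumigated": eoc_nf
                                * float(_lognormal_factor(rng, noise.cv_extract)),
                                "c13_fumigated_at_percent": max(
                                    ap_f + _at_noise(rng, noise.sd_at_percent), 1e-6
                                ),
                                "c13_nonfumigated_at_percent": max(
                                    ap_nf + _at_noise(rng, noise.sd_at_percent), 1e-6
                                ),
                                "extraction_efficiency": DEFAULT_SETTINGS.kec,
                            }
                        )

                        # PLFA profile
                        lp_rate = (
                            site.design_rate("label_plfa", temp, window, amendment)
                            * eff["lplfa"]
                            if amendment == "glucose"
                            else 0.0
                        )
                        lam_total = lp_rate * ASSAY_DURATION_H / MOLAR_MASS_C
                        plfa_dry = PLFA_SOIL_FRESH_G[site.name] * dmf
                        for group, weights in MARKER_WEIGHTS.items():
                            group_c = plfa_p * site.group_biomass[group]
                            lam_group = (
                                lam_total * site.label_groups[temp][group]
                                if amendment == "glucose"
                                else 0.0
                            )
                            unsat = {
                                m: w for m, w in weights.items() if m in UNSATURATED_MARKERS
                            }
                            sat = {
                                m: w
                                for m, w in weights.items()
                                if m not in UNSATURATED_MARKERS
                            }
                            if group == "fungal":
                                w_unsat = 1.0
                            else:
                                w_unsat = site.unsat_weight[temp]["bacterial" if group == "bacterial" else "general"]
                            for subset, lam_subset in (
                                (unsat, lam_group * w_unsat),
                                (sat, lam_group * (1.0 - w_unsat)),
                            ):
                                wsum = sum(subset.values())
                                for marker, w in subset.items():
                                    amount = group_c * w
                                    lam_i = lam_subset * w / wsum if wsum > 0 else 0.0
                                    ap_i = nat13 + (lam_i / amount) * (
                                        truth.tracer_at_percent - nat13
                                    )
                                    plfa_rows.append(
                                        {
                                            "sample_id": sid,
                                            **base,
                                            "amendment": amendment,
                                            "label_arm": arm,
                                            "marker": marker,
                                            "area": amount
                                            * plfa_dry
                                            / PLFA_IS_AMOUNT_NMOL
                                            * PLFA_IS_AREA
                                            * float(
                                                _lognormal_factor(rng, noise.cv_area)
                                            ),
                                            "c13_at_percent": max(
                                                ap_i
                                                + _at_noise(rng, noise.sd_at_percent),
                                                1e-6,
                                            ),
                                            "is_area": PLFA_IS_AREA,
                                            "is_amount_nmol": PLFA_IS_AMOUNT_NMOL,
                                            "dry_soil_g": plfa_dry,
                                        }
                                    )

    tables = {
        "sample_meta": pd.DataFrame(meta_rows),
        "headspace": pd.DataFrame(headspace_rows),
        "dna_isotope": pd.DataFrame(dna_rows),
        "fumigation": pd.DataFrame(fum_rows),
        "plfa": pd.DataFrame(plfa_rows),
    }
    return SyntheticExperiment(truth, tables, pd.DataFrame(truth_rows))
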