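"""Model-style front end over the tracing pipeline.

``CoolingExperiment`` wraps the five raw measurement tables of one
soil-cooling incubation; ``fit()`` runs the full computation chain and
returns a ``CoolingExperimentResults`` carrying the per-sample
estimates, condition means ± standard errors, cooling response ratios
and QC flags, with a printable ``summary()``.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import Settings, DEFAULT_SETTINGS
from .summarize import (
    PipelineResult,
    process_tables,
    site_ratio,
    summarize,
    validate_tables,
    REQUIRED_COLUMNS,
)

__all__ = ["CoolingExperiment", "CoolingExperimentResults"]

HEADLINE_PARAMETERS = (
    "respiration",
    "growth",
    "cue",
    "mbc",
    "total_plfa",
    "label_respiration",
    "label_mbc",
)


class CoolingExperiment:
    """A soil-cooling isotope-tracing experiment ready to be evaluated.

    Parameters
    ----------
    sample_meta, headspace, dna_isotope, fumigation, plfa : DataFrame
        The five raw measurement tables (see the column dictionaries in
        ``summarize.REQUIRED_COLUMNS``).
    settings : Settings
        Physical constants and conventions.
    doses : dict, optional
        Glucose-C dose per site (µg C g^-1 dry soil), for dose
        bookkeeping.
    """

    def __init__(
        self,
        sample_meta: pd.DataFrame,
        headspace: pd.DataFrame,
        dna_isotope: pd.DataFrame,
        fumigation: pd.DataFrame,
        plfa: pd.DataFrame,
        settings: Settings = DEFAULT_SETTINGS,
        doses: dict[str, float] | None = None,
    ) -> None:
        self.tables = {
            "sample_meta": sample_meta,
            "headspace": headspace,
            "dna_isotope": dna_isotope,
            "fumigation": fumigation,
            "plfa": plfa,
        }
        validate_tables(self.tables)
        self.settings = settings
        self.doses = doses

    @classmethod
    def from_tables(
        cls, tables: dict[str, pd.DataFrame], settings: Settings = DEFAULT_SETTINGS,
        doses: dict[str, float] | None = None,
    ) -> "CoolingExperiment":
        return cls(*(tables[name] for name in REQUIRED_COLUMNS), settings, doses)

    @classmethod
    def from_csv_dir(
        cls, input_dir: str | Path, settings: Settings = DEFAULT_SETTINGS,
        doses: dict[str, float] | None = None,
    ) -> "CoolingExperiment":
        input_dir = Path(input_dir)
        tables = {
            name: pd.read_csv(input_dir / f"{name}.csv") for name in REQUIRED_COLUMNS
        }
        return cls.from_tables(tables, settings, doses)

    def fit(self) -> "CoolingExperimentResults":
        """Run the computation chain and return the results object."""
        bundle = process_tables(self.tables, self.settings, self.doses)
        return CoolingExperimentResults(self, bundle)


@dataclass
class CoolingExperimentResults:
    """Estimates from one experiment.

    Attributes mirror the pipeline bundle: ``per_sample`` (tidy
    parameter/value rows per vial), ``summary_table`` (means ± SE per
    site x temperature x window x amendment), ``response_ratios``
    (plot-paired 11 °C / 1 °C ratios) and ``qc`` (flagged records).
    """

    model: CoolingExperiment
    bundle: PipelineResult

    @property
    def per_sample(self) -> pd.DataFrame:
        return self.bundle.per_sample

    @property
    def summary_table(self) -> pd.DataFrame:
        return self.bundle.summary

    @property
    def response_ratios(self) -> pd.DataFrame:
        return self.bundle.response_ratios

    @property
    def qc(self) -> pd.DataFrame:
        return self.bundle.qc

    def response_ratio_summary(self) -> pd.DataFrame:
        """Mean ± SE of the plot-paired response ratios."""
        rr = self.response_ratios
        if rr.empty:
            return rr
        grouped = rr.groupby(["site", "window_h", "amendment", "parameter"], sort=True)["rr"]
        out = grouped.agg(mean="mean", n="count", sd="std").reset_index()
        out["se"] = out["sd"] / out["n"].pow(0.5)
        return out[["site", "window_h", "amendment", "parameter", "mean", "se", "n"]]

    def site_ratios(
        self, parameters: tuple[str, ...] = HEADLINE_PARAMETERS
    ) -> pd.DataFrame:
        """One-decimal forest/agricultural ratios of condition means."""
        recs = []
        for p in parameters:
            try:
                recs.append(site_ratio(self.summary_table, p))
            except Exception:
                continue
        return pd.DataFrame(recs)

    def summary(self, parameters: tuple[str, ...] = HEADLINE_PARAMETERS) -> str:
        """Human-readable summary of the headline condition means."""
        df = self.summary_table
        sel = df[df["parameter"].isin(parameters)]
        lines = ["Soil-cooling isotope tracing results", "=" * 54]
        for (site, temp, window), grp in sel.groupby(
            ["site", "temperature_c", "window_h"], sort=True
        ):
            lines.append(f"\n{site} | {temp:g} degC | window {window:g} h")
            for _, row in grp.iterrows():
                lines.append(
                    f"  {row['parameter']:<20s} ({row['amendment']:<7s}) "
                    f"{row['mean']:>10.3f} +/- {row['se']:.3f} (n={int(row['n'])})"
                )
        n_flagged = len(self.qc)
        lines.append(f"\nflagged records: {n_flagged}")
        return "\n".join(lines)
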