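"""Pipeline orchestration, condition summaries and headline ratios.

``process_tables`` runs the full computation chain on the five raw
measurement tables and returns one tidy per-sample result table
(parameter/value rows keyed by site, plot, temperature, window and
amendment) plus a QC log of flagged records.  ``summarize`` collapses
the per-sample results to condition means ± standard errors over field
plots; ``response_ratios`` pairs plots across temperatures;
``site_ratio`` reproduces the one-decimal forest/agricultural headline
ratios.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Settings, DEFAULT_SETTINGS
from .errors import DomainError, IncompleteObservationError
from . import growth as growth_mod
from . import partition as part_mod
from . import plfa as plfa_mod
from .isotope import (
    HeadspaceObservation,
    RespirationResult,
    delta_to_atom_percent,
    respiration_rate,
)

__all__ = [
    "process_tables",
    "process_directory",
    "summarize",
    "response_ratios",
    "site_ratio",
    "round_half_away",
    "PipelineResult",
    "GROUP_KEYS",
    "REQUIRED_COLUMNS",
]

GROUP_KEYS = ["site", "plot", "temperature_c", "window_h", "amendment"]
CONDITION_KEYS = ["site", "temperature_c", "window_h", "amendment"]

REQUIRED_COLUMNS = {
    "sample_meta": ["sample_id", *GROUP_KEYS, "label_arm", "assay"],
    "headspace": [
        "sample_id", *GROUP_KEYS, "label_arm", "assay",
        "vial_volume_ml", "soil_fresh_mass_g", "dry_mass_fraction",
        "co2_ppm_t0", "co2_ppm_t1", "sampled_volume_ml",
        "replacement_co2_ppm", "gas_temperature_c", "pressure_atm",
        "duration_h",
    ],
    "dna_isotope": [
        "sample_id", *GROUP_KEYS,
        "o_dna_extract_ug", "at_percent_labeled", "at_percent_natural",
        "at_percent_soil_water", "dna_total_ug_per_g", "duration_h",
        "dry_soil_g",
    ],
    "fumigation": [
        "sample_id", *GROUP_KEYS, "label_arm",
        "eoc_fumigated", "eoc_nonfumigated",
        "c13_fumigated_at_percent", "c13_nonfumigated_at_percent",
        "extraction_efficiency",
    ],
    "plfa": [
        "sample_id", *GROUP_KEYS, "label_arm", "marker", "area",
        "c13_at_percent", "is_area", "is_amount_nmol", "dry_soil_g",
    ],
}


def validate_tables(tables: dict[str, pd.DataFrame]) -> None:
    """Check that every table carries its required columns."""
    problems = []
    for name, cols in REQUIRED_COLUMNS.items():
        if name not in tables:
            problems.append(f"missing table {name!r}")
            continue
        missing = [c for c in cols if c not in tables[name].columns]
        if missing:
            problems.append(f"table {name!r} lacks columns {missing}")
    if problems:
        raise IncompleteObservationError("; ".join(problems))


@dataclass
class PipelineResult:
    """Bundle returned by :func:`process_tables`."""

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    response_ratios: pd.DataFrame
    qc: pd.DataFrame
    relative_abundance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_sample.to_csv(outdir / "per_sample_results.csv", index=False)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        self.response_ratios.to_csv(outdir / "response_ratios.csv", index=False)
        self.qc.to_csv(outdir / "qc_report.csv", index=False)
        self.relative_abundance.to_csv(outdir / "plfa_relative_abundance.csv", index=False)


def _obs_from_row(row: pd.Series) -> HeadspaceObservation:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    return HeadspaceObservation(
        vial_volume_ml=row["vial_volume_ml"],
        soil_fresh_mass_g=row["soil_fresh_mass_g"],
        dry_mass_fraction=row["dry_mass_fraction"],
        co2_ppm_t0=_opt(row["co2_ppm_t0"]),
        co2_ppm_t1=_opt(row["co2_ppm_t1"]),
        duration_h=row["duration_h"],
        sampled_volume_ml=row["sampled_volume_ml"],
        replacement_co2_ppm=row["replacement_co2_ppm"],
        delta13c_t0=_opt(row.get("delta13c_t0", np.nan)),
        delta13c_t1=_opt(row.get("delta13c_t1", np.nan)),
        temperature_c=row["gas_temperature_c"],
        pressure_atm=row["pressure_atm"],
    )


def process_tables(
    tables: dict[str, pd.DataFrame],
    settings: Settings = DEFAULT_SETTINGS,
    doses: dict[str, float] | None = None,
) -> PipelineResult:
    """Run the full computation chain on the raw measurement tables.

    ``doses`` maps site name to the glucose-C dose (µg C g^-1 dry
    soil); when omitted, the tracer enrichment alone is used via the
    mixing model (the dose only matters for bookkeeping, not for the
    rates).  Tracer enrichment is fixed at 10 atom percent unless a
    ``tracer_at_percent`` column is present.
    """
    validate_tables(tables)
    rows: list[dict] = []
    qc: list[dict] = []

    def emit(key: dict, parameter: str, value: float, flag: str | None = None) -> None:
        rows.append({**key, "parameter": parameter, "value": value, "flag": flag or ""})
        if flag:
            qc.append({**key, "parameter": parameter, "flag": flag})

    headspace = tables["headspace"]
    fum = tables["fumigation"]
    dna = tables["dna_isotope"]
    plfa_tab = tables["plfa"]
    marker_table = plfa_mod.load_marker_table()

    # ---- total respiration from the 18O-assay vials --------------------
    # both label arms of a pair measure the same respiration; averaging
    # them uses every vial and halves the gas-noise variance
    resp_lookup: dict[tuple, float] = {}
    arm_rates: dict[tuple, list[RespirationResult]] = {}
    for _, row in headspace[headspace["assay"] == "18O"].iterrows():
        res = respiration_rate(_obs_from_row(row), settings)
        key = tuple(row[k] for k in GROUP_KEYS)
        arm_rates.setdefault(key, []).append(res)
    for key, results in arm_rates.items():
        rate = float(np.mean([r.rate for r in results]))
        negative = any(r.negative for r in results)
        resp_lookup[key] = rate
        emit(
            dict(zip(GROUP_KEYS, key)),
            "respiration",
            rate,
            "negative_respiration" if negative else None,
        )

    # ---- fumigation: MBC and biomass label increment -------------------
    fum_idx = {tuple(r[k] for k in GROUP_KEYS): r for _, r in fum.iterrows()}
    # water-only control pairs, keyed without amendment, for backgrounds
    ctrl_idx = {
        (r["site"], r["plot"], r["temperature_c"], r["window_h"]): r
        for _, r in fum.iterrows()
        if r["amendment"] == "water"
    }
    dur_lookup = {
        tuple(r[k] for k in GROUP_KEYS): r["duration_h"]
        for _, r in headspace[headspace["assay"] == "13C"].iterrows()
    }
    mbc_lookup: dict[tuple, float] = {}
    for key, row in fum_idx.items():
        keyd = dict(zip(GROUP_KEYS, key))
        pair = part_mod.FumigationPair(
            eoc_fumigated=row["eoc_fumigated"],
            eoc_nonfumigated=row["eoc_nonfumigated"],
            c13_fumigated_at_percent=row["c13_fumigated_at_percent"],
            c13_nonfumigated_at_percent=row["c13_nonfumigated_at_percent"],
            extraction_efficiency=row["extraction_efficiency"],
        )
        res = part_mod.mbc(pair)
        if res.value is None:
            qc.append({**keyd, "parameter": "mbc", "flag": "negative_flush"})
        else:
            mbc_lookup[key] = res.value
            emit(keyd, "mbc", res.value)
        emit(keyd, "eoc", row["eoc_nonfumigated"])
        if row["amendment"] == "glucose":
            dose = part_mod.TracerDose(
                c_added_ug_per_g=(doses or {}).get(row["site"], 1.0) or 1.0,
                natural_at_percent=settings.natural_13c_at_percent,
            )
            ctrl = ctrl_idx.get((row["site"], row["plot"], row["temperature_c"], row["window_h"]))
            lab = part_mod.label_in_mbc(
                pair,
                dose,
                control_fumigated_at=None if ctrl is None else ctrl["c13_fumigated_at_percent"],
                control_nonfumigated_at=None if ctrl is None else ctrl["c13_nonfumigated_at_percent"],
                kec_correct=settings.kec_correct_label,
            )
            duration = dur_lookup.get(key, 42.0)
            emit(
                keyd,
                "label_mbc",
                lab.value * 1000.0 / duration,
                "label_mbc_below_background" if lab.below_background else None,
            )
            label_nf = part_mod.label_in_pool(
                row["eoc_nonfumigated"],
                part_mod.label_fraction(
                    row["c13_nonfumigated_at_percent"],
                    settings.natural_13c_at_percent
                    if ctrl is None
                    else ctrl["c13_nonfumigated_at_percent"],
                    dose,
                ).value,
            )
            emit(keyd, "label_eoc", label_nf)

    # ---- 13C assay: total and label-derived respiration ----------------
    c13 = headspace[headspace["assay"] == "13C"]
    gas_ctrl = {
        (r["site"], r["plot"], r["temperature_c"], r["window_h"]): r
        for _, r in c13.iterrows()
        if r["amendment"] == "water"
    }
    for _, row in c13.iterrows():
        keyd = {k: row[k] for k in GROUP_KEYS}
        obs = _obs_from_row(row)
        res = respiration_rate(obs, settings)
        emit(
            keyd,
            "respiration_13c_assay",
            res.rate,
            "negative_respiration" if res.negative else None,
        )
        if row["amendment"] != "glucose":
            continue
        dose = part_mod.TracerDose(
            c_added_ug_per_g=(doses or {}).get(row["site"], 1.0) or 1.0,
            natural_at_percent=settings.natural_13c_at_percent,
        )
        ctrl = gas_ctrl.get((row["site"], row["plot"], row["temperature_c"], row["window_h"]))
        background = None
        if ctrl is not None and not pd.isna(ctrl["delta13c_t0"]):
            background = 0.5 * (
                delta_to_atom_percent(ctrl["delta13c_t0"], settings.r13_standard)
                + delta_to_atom_percent(ctrl["delta13c_t1"], settings.r13_standard)
            )
        lab = part_mod.label_respiration(obs, dose, background, settings)
        emit(
            keyd,
            "label_respiration",
            lab.rate,
            "negative_label_respiration" if lab.negative else None,
        )

    # ---- growth, CUE ----------------------------------------------------
    for _, row in dna.iterrows():
        keyd = {k: row[k] for k in GROUP_KEYS}
        key = tuple(row[k] for k in GROUP_KEYS)
        obs = growth_mod.DnaIsotopeObservation(
            o_dna_extract_ug=row["o_dna_extract_ug"],
            at_percent_labeled=row["at_percent_labeled"],
            at_percent_natural=row["at_percent_natural"],
            at_percent_soil_water=row["at_percent_soil_water"],
            dna_total_ug_per_g=row["dna_total_ug_per_g"],
            duration_h=row["duration_h"],
            dry_soil_g=row["dry_soil_g"],
        )
        produced = growth_mod.dna_produced(obs, settings)
        mbc_val = mbc_lookup.get(key)
        if mbc_val is None:
            qc.append({**keyd, "parameter": "growth", "flag": "missing_mbc"})
            continue
        g = growth_mod.growth_rate(
            produced.amount / obs.dry_soil_g,
            obs.dna_total_ug_per_g,
            mbc_val,
            obs.duration_h,
        )
        emit(
            keyd,
            "growth",
            g,
            "growth_below_background" if produced.below_background else None,
        )
        resp = resp_lookup.get(key)
        if resp is None:
            qc.append({**keyd, "parameter": "cue", "flag": "missing_respiration"})
            continue
        if resp < 0:
            qc.append({**keyd, "parameter": "cue", "flag": "negative_respiration"})
            continue
        c = growth_mod.cue(g, resp)
        if c is None:
            qc.append({**keyd, "parameter": "cue", "flag": "undefined_cue"})
        else:
            emit(keyd, "cue", c)

    # ---- PLFA ------------------------------------------------------------
    rel_rows: list[dict] = []
    plfa_groups = dict(tuple(plfa_tab.groupby(GROUP_KEYS, sort=True)))
    plfa_ctrl = {
        key[:4]: grp
        for key, grp in plfa_groups.items()
        if key[4] == "water"
    }
    for key, grp in plfa_groups.items():
        keyd = dict(zip(GROUP_KEYS, key))
        grp = grp.set_index("marker")
        amounts = plfa_mod.quantify_markers(
            grp["area"],
            float(grp["is_area"].iloc[0]),
            float(grp["is_amount_nmol"].iloc[0]),
            float(grp["dry_soil_g"].iloc[0]),
        )
        emit(keyd, "total_plfa", plfa_mod.total_plfa(amounts))
        rel = plfa_mod.relative_abundance(amounts)
        for marker, frac in rel.items():
            rel_rows.append({**keyd, "marker": marker, "fraction": frac})
        if keyd["amendment"] != "glucose":
            continue
        ctrl = plfa_ctrl.get(key[:4])
        if ctrl is not None:
            background = ctrl.set_index("marker")["c13_at_percent"]
        else:
            background = settings.natural_13c_at_percent
        duration = dur_lookup.get(key, 42.0)
        for grouping, prefix in (("primary_groups", ""), ("saturation", "")):
            alloc = plfa_mod.label_allocation(
                amounts,
                grp["c13_at_percent"],
                background,
                table=marker_table,
                grouping=grouping,
            )
            if alloc is None:
                qc.append({**keyd, "parameter": f"allocation_{grouping}",
                           "flag": "no_label_in_plfa"})
                continue
            for group_name, frac in alloc.items():
                emit(keyd, f"allocation_{group_name}", frac)
        # total tracer C in PLFAs as a rate (ng C h^-1 g^-1)
        bg = background if isinstance(background, pd.Series) else pd.Series(
            background, index=amounts.index
        )
        frac = ((grp["c13_at_percent"] - bg) / (10.0 - bg)).clip(lower=0.0)
        label_ng = float((amounts * frac).sum()) * 12.011
        emit(keyd, "label_plfa", label_ng / duration)

    per_sample = pd.DataFrame(rows)
    qc_df = pd.DataFrame(qc, columns=[*GROUP_KEYS, "parameter", "flag"])
    summary = summarize(per_sample)
    rr = response_ratios(per_sample)
    return PipelineResult(per_sample, summary, rr, qc_df, pd.DataFrame(rel_rows))


def process_directory(
    input_dir: str | Path,
    settings: Settings = DEFAULT_SETTINGS,
    doses: dict[str, float] | None = None,
) -> PipelineResult:
    """Read the five raw CSV tables from a directory and process them."""
    input_dir = Path(input_dir)
    tables = {}
    for name in REQUIRED_COLUMNS:
        path = input_dir / f"{name}.csv"
        if not path.exists():
            raise IncompleteObservationError(f"missing input table {path}")
        tables[name] = pd.read_csv(path)
    return process_tables(tables, settings, doses)


def summarize(per_sample: pd.DataFrame, exclude_flagged: bool = False) -> pd.DataFrame:
    """Condition means ± SE (sample SD / sqrt(n)) over field plots.

    Rows carrying a QC flag are counted in ``n_flagged`` and optionally
    excluded from the mean.
    """
    df = per_sample.copy()
    if "flag" not in df.columns:
        df["flag"] = ""
    df["flagged"] = df["flag"].fillna("").astype(str) != ""
    used = df[~df["flagged"]] if exclude_flagged else df
    if used.empty:
        return pd.DataFrame(
            columns=[*CONDITION_KEYS, "parameter", "mean", "se", "n", "n_flagged"]
        )
    grouped = used.groupby([*CONDITION_KEYS, "parameter"], sort=True)["value"]
    out = grouped.agg(mean="mean", n="count", sd="std").reset_index()
    out["se"] = (out["sd"] / np.sqrt(out["n"])).fillna(0.0)
    flags = (
        df.groupby([*CONDITION_KEYS, "parameter"], sort=True)["flagged"]
        .sum()
        .reset_index(name="n_flagged")
    )
    out = out.merge(flags, on=[*CONDITION_KEYS, "parameter"], how="left")
    return out[[*CONDITION_KEYS, "parameter", "mean", "se", "n", "n_flagged"]]


def response_ratios(per_sample: pd.DataFrame, warm: float = 11.0, cold: float = 1.0) -> pd.DataFrame:
    """Cooling response ratios paired by field plot.

    For every (site, window, amendment, parameter, plot) with values at
    both temperatures, RR = value(warm) / value(cold); undefined ratios
    (zero denominator) are dropped with a flag column count.
    """
    keys = ["site", "window_h", "amendment", "parameter", "plot"]
    wide = per_sample.pivot_table(
        index=keys, columns="temperature_c", values="value", aggfunc="first"
    )
    if warm not in wide.columns or cold not in wide.columns:
        return pd.DataFrame(columns=[*keys, "r11", "r1", "rr"])
    wide = wide.dropna(subset=[warm, cold]).reset_index()
    recs = []
    for _, row in wide.iterrows():
        rr = growth_mod.response_ratio(row["parameter"], row[warm], row[cold])
        recs.append(
            {
                **{k: row[k] for k in keys},
                "r11": rr.r11,
                "r1": rr.r1,
                "rr": np.nan if rr.undefined else rr.rr,
                "undefined": rr.undefined,
            }
        )
    return pd.DataFrame(recs)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the printed ratios)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def site_ratio(
    summary: pd.DataFrame,
    parameter: str,
    numerator_site: str = "forest",
    denominator_site: str = "agricultural",
    temperature_c: float = 11.0,
    window_h: float = 42.0,
    amendment: str | None = "glucose",
) -> dict:
    """One-decimal forest/agricultural ratio of condition means.

    Accepts either a pipeline summary table (with condition columns) or
    the packaged reference summary (``<site>_mean`` columns).
    """
    if {"agricultural_mean", "forest_mean"} <= set(summary.columns):
        row = summary[summary["parameter"] == parameter]
        if row.empty:
            raise DomainError(f"parameter {parameter!r} not in reference summary")
        num = float(row[f"{numerator_site}_mean"].iloc[0])
        den = float(row[f"{denominator_site}_mean"].iloc[0])
    else:
        sel = summary[
            (summary["parameter"] == parameter)
            & (summary["temperature_c"] == temperature_c)
            & (summary["window_h"] == window_h)
        ]
        if amendment is not None:
            sel = sel[sel["amendment"] == amendment]
        means = sel.set_index("site")["mean"]
        if numerator_site not in means.index or denominator_site not in means.index:
            raise DomainError(
                f"both sites required for {parameter!r}; found {list(means.index)}"
            )
        num = float(means[numerator_site])
        den = float(means[denominator_site])
    if den == 0:
        raise DomainError("denominator site mean is zero")
    return {
        "parameter": parameter,
        f"{numerator_site}_mean": num,
        f"{denominator_site}_mean": den,
        "ratio": round_half_away(num / den, 1),
    }
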