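"""PLFA quantification, biomarker grouping and 13C allocation.

Phospholipid fatty acid markers are quantified against an internal
standard (19:0), grouped into fungal, bacterial and general biomarkers
(and, orthogonally, saturated vs unsaturated chains), and the glucose
tracer recovered in each group is expressed as a fraction of the tracer
recovered in all markers.

The marker→group assignment ships as an editable package-data CSV.  The
published gram-positive and bacterial marker lists overlap; for the
disjoint allocation partition the bacterial group is their union, and
the overlapping memberships are retained as boolean columns for users
who need the original lists.  Saturation is classified from the marker
name: any marker with one or more C=C double bonds (``Cn:m...`` with
m >= 1) is unsaturated; branched (i/a), mid-methyl (10Me) and
cyclopropane (cy) chains with ``:0`` are saturated — a cyclopropane ring
is not a double bond.
"""
from __future__ import annotations

import re
from importlib import resources

import pandas as pd

from .config import Settings, DEFAULT_SETTINGS
from .errors import DomainError, QuantificationError

__all__ = [
    "load_marker_table",
    "is_unsaturated",
    "quantify_markers",
    "relative_abundance",
    "total_plfa",
    "label_allocation",
    "INTERNAL_STANDARD",
    "PRIMARY_GROUPS",
]

#: Marker used as the internal quantification standard; always excluded
#: from biomarker sums.
INTERNAL_STANDARD = "19:0"

#: Disjoint, exhaustive grouping used for allocation partitions.
PRIMARY_GROUPS = ("bacterial", "fungal", "general")

_DOUBLE_BOND = re.compile(r":(\d+)")


def load_marker_table() -> pd.DataFrame:
    """Load the packaged marker→group assignment table.

    Returns a DataFrame indexed by marker name with boolean membership
    columns (fungal, gram_positive, bacterial, general), the disjoint
    ``primary_group`` used for allocation, and the ``unsaturated`` flag.
    """
    with resources.files("cryotrace.data").joinpath("plfa_markers.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        table = pd.read_csv(fh)
    table = table.set_index("marker")
    for col in ("fungal", "gram_positive", "bacterial", "general", "unsaturated"):
        table[col] = table[col].astype(bool)
    bad = set(table["primary_group"]) - set(PRIMARY_GROUPS)
    if bad:
        raise DomainError(f"unknown primary groups in marker table: {sorted(bad)}")
    return table


def is_unsaturated(marker: str) -> bool:
    """Classify a marker name as unsaturated (>= 1 C=C double bond)."""
    m = _DOUBLE_BOND.search(marker)
    if m is None:
        raise DomainError(f"cannot parse double-bond count from marker name {marker!r}")
    return int(m.group(1)) >= 1


def quantify_markers(
    areas: pd.Series,
    is_area: float,
    is_amount_nmol: float,
    dry_soil_g: float,
    response_factors: pd.Series | None = None,
) -> pd.Series:
    """Marker amounts (nmol C g^-1 dry soil) from detector responses.

    Single-point quantification against the internal standard:
    ``amount_i = area_i / area_IS * amount_IS * rf_i / dry_soil``, with
    per-marker response factors defaulting to 1.  The internal standard
    itself is dropped from the returned profile.
    """
    if is_area <= 0:
        raise QuantificationError("internal standard area must be positive")
    if is_amount_nmol <= 0:
        raise QuantificationError("internal standard amount must be positive")
    if dry_soil_g <= 0:
        raise DomainError("dry soil mass must be positive")
    if (areas < 0).any():
        raise DomainError("detector responses must be >= 0")
    amounts = areas / is_area * is_amount_nmol / dry_soil_g
    if response_factors is not None:
        amounts = amounts * response_factors.reindex(amounts.index).fillna(1.0)
    amounts = amounts.drop(INTERNAL_STANDARD, errors="ignore")
    return amounts


def total_plfa(amounts: pd.Series) -> float:
    """Total biomarker C (nmol C g^-1), internal standard excluded."""
    if len(amounts) == 0:
        raise DomainError("empty profile")
    return float(amounts.drop(INTERNAL_STANDARD, errors="ignore").sum())


def relative_abundance(amounts: pd.Series) -> pd.Series:
    """Per-marker fraction of total biomarker C (sums to 1)."""
    amounts = amounts.drop(INTERNAL_STANDARD, errors="ignore")
    total = amounts.sum()
    if total <= 0:
        raise DomainError("total biomarker C must be positive")
    return amounts / total


def label_allocation(
    amounts: pd.Series,
    at_percent: pd.Series,
    background_at_percent: pd.Series | float,
    tracer_at_percent: float = 10.0,
    table: pd.DataFrame | None = None,
    grouping: str = "primary_groups",
) -> pd.Series | None:
    """Fraction of PLFA-bound tracer C recovered in each marker group.

    Per-marker tracer C is ``amount_i * (at%_i - at%_bg,i) /
    (at%_tracer - at%_bg,i)`` (negative excess floored at zero); the
    group fraction divides each group's tracer C by the tracer C summed
    over all markers.  ``grouping`` selects the disjoint primary
    partition (bacterial/fungal/general) or the saturation classes.
    Returns ``None`` when no marker carries label (undefined
    allocation).
    """
    if table is None:
        table = load_marker_table()
    if grouping not in ("primary_groups", "saturation"):
        raise DomainError(f"unknown grouping {grouping!r}")
    amounts = amounts.drop(INTERNAL_STANDARD, errors="ignore")
    at_percent = at_percent.reindex(amounts.index)
    if isinstance(background_at_percent, pd.Series):
        bg = background_at_percent.reindex(amounts.index)
    else:
        bg = pd.Series(background_at_percent, index=amounts.index)
    denom = tracer_at_percent - bg
    if (denom <= 0).any():
        raise DomainError("background enrichment at or above tracer enrichment")
    frac = ((at_percent - bg) / denom).clip(lower=0.0)
    label_c = amounts * frac
    total = label_c.sum()
    if total <= 0:
        return None
    if grouping == "primary_groups":
        keys = table["primary_group"].reindex(amounts.index)
        if keys.isna().any():
            missing = sorted(amounts.index[keys.isna()])
            raise DomainError(f"markers missing from the group table: {missing}")
        out = label_c.groupby(keys).sum() / total
        return out.reindex(PRIMARY_GROUPS, fill_value=0.0)
    keys = table["unsaturated"].reindex(amounts.index)
    if keys.isna().any():
        missing = sorted(amounts.index[keys.isna()])
        raise DomainError(f"markers missing from the group table: {missing}")
    keys = keys.map({True: "unsaturated", False: "saturated"})
    out = label_c.groupby(keys).sum() / total
    return out.reindex(["saturated", "unsaturated"], fill_value=0.0)
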