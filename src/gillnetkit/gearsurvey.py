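"""Derelict fishing gear densities from shoreline transect surveys.

Lost and abandoned gear washed up on the shoreline is an indirect sign of
fishing pressure.  Because transect widths vary, densities are linear
(items per km of shoreline) rather than areal.  The module classifies raw
beach finds into gillnet and hook-and-line categories, computes per-
transect count and weight densities, pools them weighted by transect
length, summarises the mesh-size composition of net material, and measures
between-year re-accumulation at re-surveyed (previously cleared) sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GILLNET_CATEGORIES",
    "HOOK_LINE_CATEGORIES",
    "Transect",
    "DebrisItem",
    "DensityRecord",
    "classify_gear",
    "transect_density",
    "pooled_density",
    "mesh_composition",
    "accumulation_change",
]

GILLNET_CATEGORIES = (
    "whole_net",
    "net_fragment",
    "float_line",
    "lead_line",
    "foam_float",
    "bottle_float",
)
HOOK_LINE_CATEGORIES = ("rod", "monofilament", "lure", "bobber")
GEAR_CATEGORIES = GILLNET_CATEGORIES + HOOK_LINE_CATEGORIES

# raw labels that are fishing gear only when mesh/floats/weights/lines are
# attached; bare they are ordinary debris
_AMBIGUOUS_LABELS = ("bottle", "string", "rope", "stake")


@dataclass(frozen=True)
class Transect:
    """One censused shoreline segment."""

    transect_id: str
    site: str
    year: int
    length_km: float

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise ValueError(f"transect {self.transect_id}: length must be positive")


@dataclass(frozen=True)
class DebrisItem:
    """One collected item, already classified."""

    transect_id: str
    category: str
    weight_g: float | None = None
    mesh_cm: float | None = None

    def __post_init__(self) -> None:
        if self.category not in GEAR_CATEGORIES + ("non_gear",):
            raise ValueError(f"unknown category {self.category!r}")
        if self.weight_g is not None and self.weight_g < 0:
            raise ValueError("weight must be non-negative")
        if self.mesh_cm is not None:
            if self.category not in ("whole_net", "net_fragment"):
                raise ValueError("mesh size only valid for whole_net/net_fragment")
            if self.mesh_cm <= 0:
                raise ValueError("mesh size must be positive")


@dataclass(frozen=True)
class DensityRecord:
    """Linear debris density on one transect (or pooled)."""

    transect_id: str
    scope: str
    count: int
    count_density: float  # items per km
    weight_density: float  # g per km
    length_km: float


def classify_gear(
    label: str,
    has_mesh: bool = False,
    has_floats: bool = False,
    has_weights: bool = False,
    has_lines: bool = False,
) -> str:
    """Map a raw beach find to a gear category, or ``non_gear``.

    Items already labelled with a gear category pass through.  Bottles,
    string/rope and stakes count as fishing gear only when mesh, floats,
    weights or lines are attached; bare, they are ordinary debris.  An
    attached bottle is a bottle float; string or rope becomes a net
    fragment if mesh is attached, a lead line if weighted, otherwise a
    float line.
    """
    label = label.strip().lower()
    if label in GEAR_CATEGORIES:
        return label
    if label in _AMBIGUOUS_LABELS:
        if not (has_mesh or has_floats or has_weights or has_lines):
            return "non_gear"
        if label == "bottle":
            return "bottle_float"
        if has_mesh:
            return "net_fragment"
        if has_weights:
            return "lead_line"
        return "float_line"
    permitted = ", ".join(GEAR_CATEGORIES + _AMBIGUOUS_LABELS)
    raise ValueError(f"unknown item label {label!r}; permitted: {permitted}")


def _scope_mask(items: pd.DataFrame, scope: str) -> pd.Series:
    if scope == "all":
        return items["category"] != "non_gear"
    if scope == "gillnet":
        return items["category"].isin(GILLNET_CATEGORIES)
    if scope == "hook_line":
        return items["category"].isin(HOOK_LINE_CATEGORIES)
    if scope in GEAR_CATEGORIES:
        return items["category"] == scope
    raise ValueError(
        f"unknown scope {scope!r}; use 'all', 'gillnet', 'hook_line' or a category"
    )


def transect_density(
    items: pd.DataFrame, transect: Transect, scope: str = "all"
) -> DensityRecord:
    """Count and weight density of gear on a single transect.

    ``items`` must reference only this transect.  ``scope`` selects all
    gear, gillnet material only, hook-and-line only, or one category.
    Items with missing weights still count toward the count density; they
    are dropped from the weight density with a logged tally.
    """
    if len(items) and not (items["transect_id"] == transect.transect_id).all():
        raise ValueError("items reference a different transect")
    sel = items[_scope_mask(items, scope)] if len(items) else items
    n = len(sel)
    weights = sel["weight_g"] if n else pd.Series(dtype=float)
    n_missing = int(weights.isna().sum()) if n else 0
    if n_missing:
        log.info(
            "transect %s: %d item(s) without weight excluded from weight density",
            transect.transect_id,
            n_missing,
        )
    total_w = float(weights.fillna(0.0).sum()) if n else 0.0
    return DensityRecord(
        transect_id=transect.transect_id,
        scope=scope,
        count=n,
        count_density=n / transect.length_km,
        weight_density=total_w / transect.length_km,
        length_km=transect.length_km,
    )


def pooled_density(records: Sequence[DensityRecord]) -> DensityRecord:
    """Pool per-transect densities, weighting by transect length.

    The pooled count density Σ(dᵢ·Lᵢ)/ΣLᵢ equals total items over total
    km, so splitting any transect into contiguous sub-transects leaves the
    pooled value unchanged.
    """
    if not records:
        raise ValueError("no density records to pool")
    ids = [r.transect_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transects in pooled_density")
    scopes = {r.scope for r in records}
    if len(scopes) != 1:
        raise ValueError(f"cannot pool mixed scopes: {sorted(scopes)}")
    total_km = sum(r.length_km for r in records)
    count = sum(r.count for r in records)
    weight = sum(r.weight_density * r.length_km for r in records)
    return DensityRecord(
        transect_id="pooled",
        scope=scopes.pop(),
        count=count,
        count_density=count / total_km,
        weight_density=weight / total_km,
        length_km=total_km,
    )


def mesh_composition(
    items: pd.DataFrame, bin_edges: Sequence[float] | None = None
) -> pd.DataFrame:
    """Histogram of net material by bar mesh size, in count and weight.

    Only items carrying a mesh measurement (whole nets and net fragments)
    enter.  Bins are half-open ``[lo, hi)``; the default is 1-cm bins
    spanning 2-8 cm, the range shoreline gillnet debris typically covers.
    Returns a tidy frame with columns ``bin_lo, bin_hi, count, weight_g``.
    """
    if bin_edges is None:
        bin_edges = np.arange(2.0, 9.0, 1.0)
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 values")
    withmesh = items.dropna(subset=["mesh_cm"]) if len(items) else items
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if len(withmesh):
            inbin = withmesh[(withmesh["mesh_cm"] >= lo) & (withmesh["mesh_cm"] < hi)]
            rows.append(
                {
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "count": len(inbin),
                    "weight_g": float(inbin["weight_g"].fillna(0.0).sum()),
                }
            )
        else:
            rows.append({"bin_lo": lo, "bin_hi": hi, "count": 0, "weight_g": 0.0})
    return pd.DataFrame(rows)


def accumulation_change(
    densities_a: pd.DataFrame, densities_b: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Between-year change in density at sites surveyed in both years.

    Input frames need columns ``site`` and ``density`` (first year A, then
    year B).  For each shared site the difference B - A and the ratio B/A
    are returned; where A = 0 the ratio is NaN with ``ratio_defined``
    False rather than infinity.  The second return value is the number of
    sites whose density increased.
    """
    a = densities_a.set_index("site")["density"]
    b = densities_b.set_index("site")["density"]
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("no sites shared between the two years")
    rows = []
    for site in shared:
        da, db = float(a[site]), float(b[site])
        defined = da > 0
        rows.append(
            {
                "site": site,
                "density_a": da,
                "density_b": db,
                "diff": db - da,
                "ratio": db / da if defined else np.nan,
                "ratio_defined": defined,
            }
        )
    out = pd.DataFrame(rows)
    return out, int((out["diff"] > 0).sum())
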