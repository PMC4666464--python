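"""Sustainable-yield scenarios: F_MSY, MSY, and the effort to reach them.

Given a natural mortality estimate M, the proxy F_MSY = 0.87 M converts
it to a target fishing mortality; applied to the hydroacoustic stock
biomass B (areal density x habitat area) this gives an annual maximum
sustainable yield MSY = (1 - exp(-F_MSY)) B.  The effort scenarios then
express that yield in units managers and rangers can picture: how many
net-nights of 50-m optimal-mesh gillnet, how many fishers at a plausible
annual effort, and what share of resident families that implies.

All chained values are carried at full precision; rounding to display
precision (round-half-up) happens only in the reporting twin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Mapping, Sequence

import pandas as pd

from gillnetkit.mortality import fishing_mortality
from gillnetkit.synthio import LifeHistory
from gillnetkit import mortality as _mortality

__all__ = [
    "AssessmentInputs",
    "EffortScenario",
    "SpawningRunReport",
    "round_half_up",
    "fmsy_from_m",
    "stock_biomass",
    "msy",
    "effort_requirements",
    "scenario_from_m",
    "assessment_table",
    "assessment_report",
    "spawning_run_removal",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero upward),
    matching how assessment tables are conventionally printed; Python's
    built-in banker's rounding would flip some displayed cells."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssessmentInputs:
    """The input vector of the effort-scenario calculation.

    Defaults describe the study fishery: a hydroacoustic grayling biomass
    density of 4.4 kg/ha over 276,000 ha of lake habitat, total mortality
    Z = 0.42/yr, fishers landing ~15 kg per night on 50 m of optimal-mesh
    gillnet, 100 fishing nights per fisher-year, and a resident park
    population of 5,440 people in households of 3.6.
    """

    z: float = 0.42
    biomass_density_kg_ha: float = 4.4
    area_ha: float = 276_000.0
    catch_per_night_kg: float = 15.0
    nights_per_fisher_year: float = 100.0
    population: float = 5_440.0
    household_size: float = 3.6

    def __post_init__(self) -> None:
        for name in (
            "z", "biomass_density_kg_ha", "area_ha", "catch_per_night_kg",
            "nights_per_fisher_year", "population", "household_size",
        ):
            if getattr(self, name) <= 0 and name != "z":
                raise ValueError(f"{name} must be positive")
        if self.z < 0:
            raise ValueError("z must be non-negative")

    @property
    def families(self) -> float:
        """Number of resident families, kept at full precision
        (population / household size) rather than pre-rounded."""
        return self.population / self.household_size

    @property
    def biomass_kg(self) -> float:
        return stock_biomass(self.biomass_density_kg_ha, self.area_ha)


@dataclass(frozen=True)
class EffortScenario:
    """One method's harvest and effort row, at full precision."""

    method: str
    m: float
    f: float
    f_negative: bool
    f_msy: float
    msy_kg: float
    nights: float
    fishers: float
    percent_families: float
    nights_per_family: float

    def display(self) -> dict:
        """The row at conventional display precision (round-half-up):
        rates to 2 decimals, yield and nights whole, fishers and percent
        to 1 decimal."""
        return {
            "method": self.method,
            "m": round_half_up(self.m, 2),
            "f": round_half_up(self.f, 2),
            "f_msy": round_half_up(self.f_msy, 2),
            "msy_kg": round_half_up(self.msy_kg, 0),
            "nights": round_half_up(self.nights, 0),
            "fishers": round_half_up(self.fishers, 1),
            "percent_families": round_half_up(self.percent_families, 1),
            "nights_per_family": round_half_up(self.nights_per_family, 1),
        }


def fmsy_from_m(m: float) -> float:
    """Proxy target fishing mortality F_MSY = 0.87 M."""
    if m < 0:
        raise ValueError("m must be non-negative")
    return 0.87 * m


def stock_biomass(
    density: float, area: float, area_unit: Literal["ha", "km2"] = "ha"
) -> float:
    """Stock biomass (kg) from areal density (kg/ha) and habitat area.

    Areas in km² are accepted with an explicit unit flag (x100 to ha).
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if area <= 0:
        raise ValueError("area must be positive")
    if area_unit == "km2":
        area *= 100.0
    elif area_unit != "ha":
        raise ValueError("area_unit must be 'ha' or 'km2'")
    return density * area


def msy(f_msy: float, biomass_kg: float) -> float:
    """Annual maximum sustainable yield (kg/yr): (1 - exp(-F_MSY)) x B.

    The Baranov-style fraction keeps MSY strictly below the standing
    biomass for any finite F_MSY.
    """
    if f_msy < 0 or biomass_kg < 0:
        raise ValueError("f_msy and biomass must be non-negative")
    return -math.expm1(-f_msy) * biomass_kg


def effort_requirements(msy_kg: float, inputs: AssessmentInputs) -> dict:
    """Effort needed to land a given annual yield.

    nights = MSY / catch-per-night; fishers = nights / nights-per-fisher-
    year; percent of families = 100 x fishers / families; nights per
    family = nights / families (the effort if every family shared the
    fishing equally).  All at full precision.
    """
    if msy_kg < 0:
        raise ValueError("msy must be non-negative")
    if inputs.catch_per_night_kg <= 0:
        raise ValueError("catch_per_night_kg must be positive")
    nights = msy_kg / inputs.catch_per_night_kg
    fishers = nights / inputs.nights_per_fisher_year
    families = inputs.families
    return {
        "nights": nights,
        "fishers": fishers,
        "percent_families": 100.0 * fishers / families,
        "nights_per_family": nights / families,
    }


def scenario_from_m(
    method: str, m: float, inputs: AssessmentInputs, msy_kg: float | None = None
) -> EffortScenario:
    """Full chain for one M: F = Z - M, F_MSY, MSY, effort columns.

    ``msy_kg`` overrides the computed MSY — useful to regenerate the
    effort columns of a published table from its printed MSY value.
    """
    f = fishing_mortality(inputs.z, m)
    f_msy = fmsy_from_m(m)
    msy_val = msy(f_msy, inputs.biomass_kg) if msy_kg is None else msy_kg
    eff = effort_requirements(msy_val, inputs)
    return EffortScenario(
        method=method,
        m=m,
        f=float(f),
        f_negative=f.m_exceeds_z,
        f_msy=f_msy,
        msy_kg=msy_val,
        **eff,
    )


def assessment_table(
    m_estimates: Mapping[str, float] | LifeHistory,
    inputs: AssessmentInputs,
    methods: Sequence[str] = _mortality.M_METHODS,
) -> pd.DataFrame:
    """One effort-scenario row per natural-mortality method.

    ``m_estimates`` is either a mapping method -> M, or a
    :class:`LifeHistory` from which every requested method's M is
    computed.  Returns the full-precision table; pair each row with
    ``EffortScenario.display()`` for the printable twin (see
    :func:`assessment_report`).
    """
    if isinstance(m_estimates, LifeHistory):
        m_map = {
            meth: _mortality.natural_mortality(m_estimates, meth).m
            for meth in methods
        }
    else:
        m_map = {k: m_estimates[k] for k in methods if k in m_estimates}
    if not m_map:
        raise ValueError("no natural-mortality estimates available")
    rows = [scenario_from_m(meth, m, inputs) for meth, m in m_map.items()]
    return pd.DataFrame([r.__dict__ for r in rows])


def assessment_report(table: pd.DataFrame) -> pd.DataFrame:
    """Display-precision twin of :func:`assessment_table` output."""
    out = table.copy()
    for col, nd in (
        ("m", 2), ("f", 2), ("f_msy", 2), ("msy_kg", 0), ("nights", 0),
        ("fishers", 1), ("percent_families", 1), ("nights_per_family", 1),
    ):
        out[col] = out[col].map(lambda x, nd=nd: round_half_up(float(x), nd))
    return out


@dataclass(frozen=True)
class SpawningRunReport:
    """Ranger-reported structure of a spawning-run fishery.

    ``periods`` is a list of (days, low daily removal, high daily
    removal); optional context fields record the reported nets per day
    and catch per net ranges.
    """

    periods: Sequence[tuple[float, float, float]]
    nets_per_day: tuple[float, float] | None = None
    catch_per_net: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.periods:
            raise ValueError("report needs at least one period")
        for days, lo, hi in self.periods:
            if days < 0:
                raise ValueError("days must be non-negative")
            if lo > hi:
                raise ValueError("low daily removal exceeds high")


def spawning_run_removal(
    report: SpawningRunReport, rule: Literal["low", "mid", "high"] = "mid"
) -> tuple[float, tuple[float, float]]:
    """Annual fish removed by a reported spawning-run fishery.

    Sums days x daily removal over the reported periods, using the low,
    midpoint or high end of each period's reported range as the point
    value.  Returns ``(point estimate, (low total, high total))`` — the
    envelope is the honest summary when reported rates are ranges.
    """
    if rule not in ("low", "mid", "high"):
        raise ValueError("rule must be 'low', 'mid' or 'high'")
    lo_total = sum(days * lo for days, lo, _ in report.periods)
    hi_total = sum(days * hi for days, _, hi in report.periods)
    if rule == "low":
        point = lo_total
    elif rule == "high":
        point = hi_total
    else:
        point = 0.5 * (lo_total + hi_total)
    return point, (lo_total, hi_total)
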