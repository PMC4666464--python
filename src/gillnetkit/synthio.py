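"""Synthetic populations, gillnet surveys and debris fields.

The generators here emulate the statistical structure the analysis modules
assume, so the whole pipeline can be exercised end to end without field
data:

* an age-structured fish population declining at total mortality rate Z,
  with von Bertalanffy (VB) growth and multiplicative length-at-age noise;
* a multi-mesh gillnet monitoring survey (several sites x years x nets,
  each net a sequence of mesh panels) in which species-specific expected
  catch follows a log-linear year trend with site random intercepts and
  fish are allocated to panels by a unimodal, lognormal-in-length
  selectivity curve peaking at a mesh-proportional optimal length;
* derelict-gear items scattered along shoreline transects as a Poisson
  process per kilometre, with a category mix and a mesh-size mixture for
  net material.

All randomness flows through explicit seeds; fixing the seed fixes every
emitted table byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifeHistory",
    "PopulationSimConfig",
    "SurveyDesign",
    "SpeciesTrend",
    "CommunityTrendConfig",
    "DEFAULT_GRAYLING",
    "simulate_population",
    "simulate_catch_survey",
    "simulate_debris",
]


class ValidationError(ValueError):
    """Raised when a config field violates its invariant; names the field."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class LifeHistory:
    """Life-history traits of one species.

    Parameters
    ----------
    linf : float
        VB asymptotic length L∞ (cm).
    k : float
        VB growth coefficient K (1/yr).
    t0 : float
        VB theoretical age at zero length (yr); typically <= 0.
    t_max : float
        Maximum observed age (yr); drives the longevity-based natural
        mortality estimator.
    gsi : float
        Gonadosomatic index (gonad mass / somatic mass, dimensionless);
        drives the reproductive-investment estimator.
    """

    linf: float
    k: float
    t0: float
    t_max: float
    gsi: float

    def __post_init__(self) -> None:
        _require(self.linf > 0, "linf", "asymptotic length must be positive")
        _require(self.k > 0, "k", "growth coefficient must be positive")
        _require(self.t_max > 0, "t_max", "maximum age must be positive")
        _require(0 <= self.gsi < 1, "gsi", "must lie in [0, 1)")


#: Default life history for the endemic lake grayling that dominates the
#: fishery: a small, slow-growing, long-lived salmonid.  Values are chosen
#: to be internally consistent with the natural-mortality estimates used in
#: the worked assessment example (M of roughly 0.27-0.37 / yr).
DEFAULT_GRAYLING = LifeHistory(linf=40.0, k=0.13, t0=0.0, t_max=17.0, gsi=0.168)


@dataclass(frozen=True)
class PopulationSimConfig:
    """Configuration for the age/length population sampler."""

    life_history: LifeHistory
    z: float
    n_fish: int
    recruit_age: float = 0.0
    length_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.z >= 0, "z", "total mortality must be non-negative")
        _require(self.n_fish >= 1, "n_fish", "need at least one fish")
        _require(0 <= self.length_cv < 0.5, "length_cv", "must lie in [0, 0.5)")
        _require(
            self.recruit_age < self.life_history.t_max,
            "recruit_age",
            "must be below t_max",
        )


def simulate_population(cfg: PopulationSimConfig) -> pd.DataFrame:
    """Draw an age-and-length sample from an exponentially declining cohort.

    Ages are drawn with density proportional to exp(-Z a), truncated to
    [recruit_age, t_max].  Length at age is the VB mean length times
    multiplicative lognormal noise with coefficient of variation
    ``length_cv`` (mean 1, so the expected length stays on the growth
    curve).

    Returns a DataFrame with columns ``age`` (yr), ``length_cm`` and
    ``length_mm``.
    """
    lh = cfg.life_history
    rng = np.random.default_rng(cfg.seed)
    u = rng.random(cfg.n_fish)
    a0, a1 = cfg.recruit_age, lh.t_max
    if cfg.z == 0:
        ages = a0 + u * (a1 - a0)
    else:
        # inverse CDF of the truncated exponential
        span = -math.expm1(-cfg.z * (a1 - a0))
        ages = a0 - np.log1p(-u * span) / cfg.z
    mean_len = vb_mean_length(ages, lh.linf, lh.k, lh.t0)
    if cfg.length_cv > 0:
        sigma = math.sqrt(math.log1p(cfg.length_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=cfg.n_fish)
        lengths = mean_len * noise
    else:
        lengths = mean_len
    return pd.DataFrame(
        {"age": ages, "length_cm": lengths, "length_mm": lengths * 10.0}
    )


def vb_mean_length(age, linf: float, k: float, t0: float):
    """Von Bertalanffy mean length at age: L(t) = L∞ (1 - exp(-K (t - t0)))."""
    return linf * (1.0 - np.exp(-k * (np.asarray(age, dtype=float) - t0)))


@dataclass(frozen=True)
class SurveyDesign:
    """Layout of the gillnet monitoring survey.

    Defaults mirror a design of two sequential-mesh nets per site at seven
    sites over four survey years, each net carrying five 4-m panels of
    2.54, 3.81, 5.08, 6.35 and 7.62 cm bar mesh, fished for one night.
    """

    sites: Sequence[str] = tuple(f"S{i}" for i in range(1, 8))
    years: Sequence[int] = (2009, 2011, 2012, 2013)
    nets_per_site: int = 2
    panel_meshes: Sequence[float] = (2.54, 3.81, 5.08, 6.35, 7.62)
    panel_length: float = 4.0
    panel_depth: float = 2.0
    soak_nights: int = 1

    def __post_init__(self) -> None:
        _require(len(self.sites) > 0, "sites", "must be non-empty")
        _require(len(self.years) > 0, "years", "must be non-empty")
        _require(self.nets_per_site >= 1, "nets_per_site", "must be >= 1")
        _require(self.panel_length > 0, "panel_length", "must be positive")
        meshes = list(self.panel_meshes)
        _require(
            len(set(meshes)) == len(meshes) and all(m > 0 for m in meshes),
            "panel_meshes",
            "meshes must be distinct and positive",
        )
        _require(self.soak_nights >= 1, "soak_nights", "must be >= 1")


@dataclass(frozen=True)
class SpeciesTrend:
    """Generative parameters for one species in the simulated community.

    ``log_cpue_intercept`` and ``year_slope`` act on the log of the
    expected per-set catch count (slope per year, on the scale named by
    ``slope_scale``).  ``site_sd`` is the SD of lognormal site random
    intercepts.  Mean length declines (or grows) at ``length_year_slope``
    per year on the log scale.  Selectivity is lognormal in length with
    peak at ``sel_optimal_mm_per_cm`` x mesh (cm) and relative spread
    ``sel_spread`` (SD on the log-length scale).
    """

    name: str
    log_cpue_intercept: float = math.log(15.0)
    year_slope: float = 0.0
    slope_scale: Literal["log", "identity"] = "log"
    site_sd: float = 0.2
    noise: Literal["poisson", "negbin"] = "poisson"
    dispersion: float = 1.0
    lw_a: float = 1e-5
    lw_b: float = 3.0
    weight_cv: float = 0.0
    mean_length_mm: float = 250.0
    length_spread: float = 0.15
    length_year_slope: float = 0.0
    sel_optimal_mm_per_cm: float = 100.0
    sel_spread: float = 0.25

    def __post_init__(self) -> None:
        _require(self.dispersion > 0, "dispersion", "must be positive")
        _require(2.5 <= self.lw_b <= 3.5, "lw_b", "allometric exponent outside [2.5, 3.5]")
        _require(self.sel_spread > 0, "sel_spread", "must be positive")
        _require(self.length_spread > 0, "length_spread", "must be positive")
        _require(self.mean_length_mm > 0, "mean_length_mm", "must be positive")


@dataclass(frozen=True)
class CommunityTrendConfig:
    """The set of species simulated together in one survey."""

    species: Sequence[SpeciesTrend] = field(
        default_factory=lambda: (SpeciesTrend(name="grayling"),)
    )

    def __post_init__(self) -> None:
        _require(len(self.species) > 0, "species", "must be non-empty")


def simulate_catch_survey(
    design: SurveyDesign,
    community: CommunityTrendConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-mesh gillnet survey.

    For each species and each net set, the number of fish encountering the
    net is Poisson (or gamma-Poisson for negative-binomial overdispersion)
    with log-mean ``intercept + slope * (year - first_year) + site_effect``.
    Each fish draws a length from the species' (possibly year-trending)
    length distribution and is allocated to one mesh panel with probability
    proportional to the lognormal selectivity of that mesh at the fish's
    length.  Weight is the allometric ``a * L^b`` with optional
    multiplicative noise; with ``weight_cv = 0`` weights sit exactly on
    the length-weight curve.

    Returns ``(catch, sets, panels)`` tables matching the schemas the
    analysis modules read.
    """
    rng = np.random.default_rng(seed)
    year0 = min(design.years)
    meshes = np.asarray(design.panel_meshes, dtype=float)

    # site random intercepts, one per species x site, fixed for the survey
    site_effects = {
        (sp.name, site): rng.normal(0.0, sp.site_sd) if sp.site_sd > 0 else 0.0
        for sp in community.species
        for site in design.sites
    }

    set_rows = []
    panel_rows = []
    catch_rows = []
    for year in design.years:
        for site in design.sites:
            for net in range(1, design.nets_per_site + 1):
                set_id = f"{site}-{year}-n{net}"
                soak_hr = rng.uniform(8.5, 10.5)
                set_rows.append(
                    {
                        "set_id": set_id,
                        "site": site,
                        "year": year,
                        "net": net,
                        "soak_hr": round(soak_hr, 2),
                        "nights": design.soak_nights,
                    }
                )
                for mesh in meshes:
                    panel_rows.append(
                        {
                            "set_id": set_id,
                            "mesh_cm": mesh,
                            "length_m": design.panel_length,
                        }
                    )
                yc = year - year0
                for sp in community.species:
                    mu = sp.log_cpue_intercept + site_effects[(sp.name, site)]
                    if sp.slope_scale == "log":
                        lam = math.exp(mu + sp.year_slope * yc)
                    else:
                        lam = max(math.exp(mu) + sp.year_slope * yc, 0.0)
                    lam *= design.soak_nights
                    if sp.noise == "negbin":
                        # gamma-Poisson mixture; dispersion = NB size parameter
                        lam = rng.gamma(sp.dispersion, lam / sp.dispersion)
                    n = rng.poisson(lam)
                    if n == 0:
                        continue
                    mean_l = sp.mean_length_mm * math.exp(sp.length_year_slope * yc)
                    lengths = rng.lognormal(
                        mean=math.log(mean_l) - 0.5 * sp.length_spread**2,
                        sigma=sp.length_spread,
                        size=n,
                    )
                    # measured to the nearest mm; weight derives from the
                    # recorded length so the allometry holds exactly
                    lengths = np.round(lengths, 0)
                    # panel allocation by relative selectivity at each length
                    opt = sp.sel_optimal_mm_per_cm * meshes  # optimal length per mesh
                    logdev = np.log(lengths)[:, None] - np.log(opt)[None, :]
                    w = np.exp(-0.5 * (logdev / sp.sel_spread) ** 2)
                    w /= w.sum(axis=1, keepdims=True)
                    panel_idx = np.array(
                        [rng.choice(len(meshes), p=wi) for wi in w]
                    )
                    weights = sp.lw_a * lengths**sp.lw_b
                    if sp.weight_cv > 0:
                        sig = math.sqrt(math.log1p(sp.weight_cv**2))
                        weights = weights * rng.lognormal(-0.5 * sig**2, sig, n)
                    for li, wi, pi in zip(lengths, weights, panel_idx):
                        catch_rows.append(
                            {
                                "set_id": set_id,
                                "mesh_cm": meshes[pi],
                                "species": sp.name,
                                "length_mm": float(li),
                                "weight_g": float(wi),
                            }
                        )

    sets = pd.DataFrame(
        set_rows, columns=["set_id", "site", "year", "net", "soak_hr", "nights"]
    )
    panels = pd.DataFrame(panel_rows, columns=["set_id", "mesh_cm", "length_m"])
    catch = pd.DataFrame(
        catch_rows, columns=["set_id", "mesh_cm", "species", "length_mm", "weight_g"]
    )
    return catch, sets, panels


# categories that carry a mesh size measurement
MESH_CATEGORIES = ("whole_net", "net_fragment")

#: Default category mix for simulated derelict gear (probabilities).  Foam
#: floats dominate by count and net fragments by weight, the pattern a
#: beach survey of gillnet debris typically shows.
DEFAULT_CATEGORY_MIX: Mapping[str, float] = {
    "foam_float": 0.40,
    "net_fragment": 0.25,
    "float_line": 0.10,
    "lead_line": 0.08,
    "bottle_float": 0.07,
    "whole_net": 0.02,
    "monofilament": 0.05,
    "bobber": 0.02,
    "lure": 0.01,
}

#: Typical item weight (g) by category, used as the lognormal median.
DEFAULT_CATEGORY_WEIGHT_G: Mapping[str, float] = {
    "whole_net": 400.0,
    "net_fragment": 60.0,
    "float_line": 30.0,
    "lead_line": 80.0,
    "foam_float": 5.0,
    "bottle_float": 15.0,
    "rod": 150.0,
    "monofilament": 10.0,
    "lure": 8.0,
    "bobber": 4.0,
}

#: Default mesh mixture for simulated net material: mass concentrated at
#: 3-4 cm bar mesh, the range small-bodied grayling fisheries use.
DEFAULT_MESH_MIX: Mapping[float, float] = {2.5: 0.1, 3.0: 0.4, 3.5: 0.25, 4.5: 0.1, 5.0: 0.1, 6.0: 0.05}


def simulate_debris(
    transects: pd.DataFrame,
    density_per_km: float = 4.0,
    category_mix: Mapping[str, float] | None = None,
    mesh_mix: Mapping[float, float] | None = None,
    weight_medians: Mapping[str, float] | None = None,
    weight_spread: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Scatter derelict-gear items along shoreline transects.

    Item counts per transect are Poisson(``density_per_km`` x transect
    length).  Each item draws a category from ``category_mix``, a weight
    from a lognormal with category-specific median, and — for whole nets
    and net fragments — a bar mesh size from ``mesh_mix``.

    ``transects`` needs columns ``transect_id`` and ``length_km``.
    Returns an items table (``transect_id, category, weight_g, mesh_cm``)
    with NaN mesh for non-net categories.
    """
    if density_per_km < 0:
        raise ValidationError("density_per_km: must be non-negative")
    category_mix = dict(category_mix or DEFAULT_CATEGORY_MIX)
    mesh_mix = dict(mesh_mix or DEFAULT_MESH_MIX)
    weight_medians = dict(weight_medians or DEFAULT_CATEGORY_WEIGHT_G)
    for name, mix in (("category_mix", category_mix), ("mesh_mix", mesh_mix)):
        total = sum(mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValidationError(f"{name}: mixture weights sum to {total}, not 1")

    rng = np.random.default_rng(seed)
    cats = list(category_mix)
    cat_p = np.array([category_mix[c] for c in cats])
    mesh_vals = np.array(list(mesh_mix), dtype=float)
    mesh_p = np.array([mesh_mix[m] for m in mesh_mix])

    rows = []
    for t in transects.itertuples(index=False):
        n = rng.poisson(density_per_km * float(t.length_km))
        for _ in range(n):
            cat = cats[rng.choice(len(cats), p=cat_p)]
            med = weight_medians.get(cat, 20.0)
            weight = float(rng.lognormal(math.log(med), weight_spread))
            mesh = (
                float(mesh_vals[rng.choice(len(mesh_vals), p=mesh_p)])
                if cat in MESH_CATEGORIES
                else math.nan
            )
            rows.append(
                {
                    "transect_id": t.transect_id,
                    "category": cat,
                    "weight_g": round(weight, 2),
                    "mesh_cm": mesh,
                }
            )
    return pd.DataFrame(rows, columns=["transect_id", "category", "weight_g", "mesh_cm"])
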