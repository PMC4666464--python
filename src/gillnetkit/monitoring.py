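"""Gillnet monitoring analyses: allometry, CPUE and year trends.

The monitoring survey fishes multi-panel sequential-mesh gillnets
overnight at fixed sites across years.  Effort is counted in net-nights
(a set soaked 8.5 or 10.5 hours overnight is one night either way), so
CPUE is fish count or biomass per 10 m of panel per night at the panel
level and per net-night at the set level.

Year trends in abundance (set CPUE) and in body size (individual lengths
or weights) are tested with linear mixed-effects models carrying a site
random intercept, fitted by full maximum likelihood; significance comes
from a likelihood-ratio test against the intercept-only model with the
same random effect (1 df chi-square).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

__all__ = [
    "LWParams",
    "TrendResult",
    "fit_length_weight",
    "impute_weights",
    "panel_cpue",
    "panel_cpue_table",
    "set_cpue",
    "optimal_mesh",
    "trend_test",
]


@dataclass(frozen=True)
class LWParams:
    """Allometric length-weight parameters W = a L^b (W in g, L in mm)."""

    a: float
    b: float
    n: int
    log_resid_sd: float

    def predict(self, length_mm):
        return self.a * np.asarray(length_mm, dtype=float) ** self.b


@dataclass(frozen=True)
class TrendResult:
    """Year-trend fit for one response with site random intercepts."""

    response: str
    slope: float
    slope_se: float
    site_sd: float
    resid_sd: float
    lr_stat: float
    p_value: float
    n_obs: int


def fit_length_weight(records: pd.DataFrame) -> LWParams:
    """Fit W = a L^b by least squares on the log-log scale.

    ``records`` needs ``length_mm`` and ``weight_g`` columns; rows without
    a measured weight are dropped.  At least three weighted records are
    required.  ``a`` is back-transformed from the log intercept.
    """
    d = records.dropna(subset=["weight_g"])
    d = d[(d["length_mm"] > 0) & (d["weight_g"] > 0)]
    if len(d) < 3:
        raise ValueError(
            f"length-weight fit needs >= 3 records with measured weight, got {len(d)}"
        )
    x = np.log(d["length_mm"].to_numpy(dtype=float))
    y = np.log(d["weight_g"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    dof = max(len(d) - 2, 1)
    return LWParams(
        a=float(np.exp(intercept)),
        b=float(slope),
        n=len(d),
        log_resid_sd=float(np.sqrt(resid @ resid / dof)),
    )


def impute_weights(records: pd.DataFrame, params: dict[str, LWParams]) -> pd.DataFrame:
    """Fill missing weights from each species' allometric fit.

    Measured weights are never altered.  A boolean ``weight_imputed``
    column records which rows were filled, so downstream body-size tests
    can exclude them (imputed weights are deterministic functions of
    length and would double-count the length signal).
    """
    out = records.copy()
    missing = out["weight_g"].isna()
    out["weight_imputed"] = missing
    if not missing.any():
        return out
    for species, grp in out[missing].groupby("species"):
        if species not in params:
            raise KeyError(f"no length-weight parameters for species {species!r}")
        out.loc[grp.index, "weight_g"] = params[species].predict(grp["length_mm"])
    return out


def panel_cpue(
    records: pd.DataFrame, panel_length_m: float, nights: int = 1
) -> tuple[float, float]:
    """CPUE of one panel: (fish per 10 m per night, kg per 10 m per night).

    ``records`` are the catch rows of this panel; effort is nights, not
    soak hours.
    """
    if panel_length_m <= 0:
        raise ValueError("panel length must be positive")
    if nights < 1:
        raise ValueError("nights must be >= 1")
    scale = (10.0 / panel_length_m) / nights
    n = len(records)
    kg = float(records["weight_g"].fillna(0.0).sum()) / 1000.0 if n else 0.0
    return n * scale, kg * scale


def set_cpue(records: pd.DataFrame, nights: int = 1) -> tuple[float, float]:
    """CPUE of a whole net set: (fish per net-night, kg per net-night)."""
    if nights < 1:
        raise ValueError("nights must be >= 1")
    n = len(records)
    kg = float(records["weight_g"].fillna(0.0).sum()) / 1000.0 if n else 0.0
    return n / nights, kg / nights


def panel_cpue_table(
    catch: pd.DataFrame, sets: pd.DataFrame, panels: pd.DataFrame,
    species: str | None = None,
) -> pd.DataFrame:
    """Per (set, mesh) CPUE table including zero-catch panels.

    Zero-catch panels are retained as CPUE-0 rows; omitting them would
    bias mesh comparisons and trends upward.
    """
    sel = catch if species is None else catch[catch["species"] == species]
    frame = panels.merge(sets[["set_id", "nights"]], on="set_id")
    grp = sel.groupby(["set_id", "mesh_cm"])
    counts = grp.size().rename("n")
    kg = (grp["weight_g"].sum() / 1000.0).rename("kg")
    frame = frame.merge(counts, on=["set_id", "mesh_cm"], how="left").merge(
        kg, on=["set_id", "mesh_cm"], how="left"
    )
    frame[["n", "kg"]] = frame[["n", "kg"]].fillna(0.0)
    frame["cpue_count"] = frame["n"] * (10.0 / frame["length_m"]) / frame["nights"]
    frame["cpue_kg"] = frame["kg"] * (10.0 / frame["length_m"]) / frame["nights"]
    return frame


def optimal_mesh(cpue_table: pd.DataFrame, criterion: str = "count") -> float:
    """Mesh size with the highest mean CPUE across sets.

    ``cpue_table`` is the output of :func:`panel_cpue_table`.  ``criterion``
    is ``"count"`` or ``"biomass"``.  Exact ties break toward the smaller
    mesh (cheaper net, and the smaller mesh retains more of the small
    abundant species).
    """
    col = {"count": "cpue_count", "biomass": "cpue_kg"}.get(criterion)
    if col is None:
        raise ValueError("criterion must be 'count' or 'biomass'")
    means = cpue_table.groupby("mesh_cm")[col].mean()
    if len(means) < 2:
        raise ValueError("optimal mesh needs >= 2 mesh sizes")
    best = means[means == means.max()]
    return float(min(best.index))


def trend_test(
    data: pd.DataFrame,
    response: str,
    year_col: str = "year",
    site_col: str = "site",
    log1p_response: bool = False,
) -> TrendResult:
    """Test a linear year trend with site random intercepts.

    Fits ``response ~ year`` with a random intercept per site by full
    maximum likelihood (ML, not REML, because the fixed effects differ
    between the nested models) and compares against the intercept-only
    model with the same random effect via a likelihood-ratio test with one
    degree of freedom.  Year is centred at the first survey year for
    conditioning; the slope and p-value are invariant to that shift.

    Works identically for abundance (one CPUE value per net set) and body
    size (one length or weight per fish).  With a single site the random
    effect is dropped and plain OLS is used, with a logged warning.
    """
    d = data[[response, year_col, site_col]].dropna().copy()
    years = d[year_col].to_numpy(dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("trend test needs >= 2 distinct years")
    y = d[response].to_numpy(dtype=float)
    if log1p_response:
        y = np.log1p(y)
    d["_y"] = y
    d["_yc"] = years - years.min()
    n = len(d)

    if np.ptp(y) == 0.0:
        # constant response: zero slope, zero evidence against the null
        return TrendResult(response, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, n)

    n_sites = d[site_col].nunique()
    if n_sites < 2:
        log.warning(
            "trend_test: single site; falling back to fixed-intercept OLS"
        )
        X = sm.add_constant(d["_yc"])
        full = sm.OLS(d["_y"], X).fit()
        null = sm.OLS(d["_y"], np.ones((n, 1))).fit()
        lr = max(2.0 * (full.llf - null.llf), 0.0)
        return TrendResult(
            response=response,
            slope=float(full.params.iloc[1]),
            slope_se=float(full.bse.iloc[1]),
            site_sd=0.0,
            resid_sd=float(np.sqrt(full.scale)),
            lr_stat=lr,
            p_value=float(stats.chi2.sf(lr, df=1)),
            n_obs=n,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = _fit_mixed("_y ~ _yc", d, site_col)
        null = _fit_mixed("_y ~ 1", d, site_col)
    lr = max(2.0 * (full.llf - null.llf), 0.0)
    return TrendResult(
        response=response,
        slope=float(full.params["_yc"]),
        slope_se=float(full.bse["_yc"]),
        site_sd=float(np.sqrt(max(full.cov_re.iloc[0, 0], 0.0))),
        resid_sd=float(np.sqrt(full.scale)),
        lr_stat=lr,
        p_value=float(stats.chi2.sf(lr, df=1)),
        n_obs=n,
    )


def _fit_mixed(formula: str, data: pd.DataFrame, group_col: str):
    """ML fit of a random-intercept model, retrying optimizers on failure."""
    model = smf.mixedlm(formula, data, groups=data[group_col])
    last_err: Exception | None = None
    for method in ("lbfgs", "cg", "powell"):
        try:
            res = model.fit(reml=False, method=method, maxiter=500)
            if np.isfinite(res.llf):
                return res
        except (np.linalg.LinAlgError, ValueError) as err:  # singular fits
            last_err = err
    raise RuntimeError(f"mixed-model fit failed for {formula!r}: {last_err}")
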