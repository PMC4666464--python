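"""Growth and mortality estimation for data-poor stocks.

The chain is the classic one for a fishery with no catch statistics:

* fit von Bertalanffy (VB) growth, L(t) = L∞ (1 - exp(-K (t - t0))), to
  age-length pairs, optionally anchoring the curve through the origin
  (t0 = 0);
* estimate total mortality Z from a length-frequency sample with a
  length-converted catch curve: lengths are binned, each bin mapped to a
  relative age by inverting the growth curve, and ln(count / Δt) is
  regressed on relative age over the trailing (descending) arm of the
  distribution; Z is the negative slope;
* estimate natural mortality M from life-history invariants (longevity,
  growth, or reproductive investment);
* fishing mortality follows by subtraction, F = Z - M.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from gillnetkit.synthio import LifeHistory

log = logging.getLogger(__name__)

__all__ = [
    "GrowthParams",
    "CatchCurveResult",
    "MortalityEstimate",
    "FishingMortality",
    "fit_vb",
    "vb_length",
    "length_to_relative_age",
    "catch_curve",
    "natural_mortality",
    "fishing_mortality",
    "M_METHODS",
]


@dataclass(frozen=True)
class GrowthParams:
    """Fitted VB growth parameters (lengths in cm, ages in yr)."""

    linf: float
    k: float
    t0: float
    n: int = 0
    resid_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.linf <= 0:
            raise ValueError("linf must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class CatchCurveResult:
    """Total mortality Z from a length-converted catch curve."""

    z: float
    slope: float
    slope_se: float
    r_squared: float
    bins: pd.DataFrame  # bin_lo, bin_hi, count, age, dt, used
    n_bins_used: int

    @property
    def negative_z_flag(self) -> bool:
        """True when the regression slope is positive (Z < 0): the sample
        shows no decline over the trailing arm and the estimate is not
        interpretable as a mortality rate."""
        return self.z < 0


@dataclass(frozen=True)
class MortalityEstimate:
    """Natural mortality M from one life-history invariant method."""

    method: str
    m: float
    inputs: dict


class FishingMortality(float):
    """F = Z - M; carries a flag when M exceeds Z (negative F)."""

    m_exceeds_z: bool

    def __new__(cls, f: float, m_exceeds_z: bool):
        obj = super().__new__(cls, f)
        obj.m_exceeds_z = m_exceeds_z
        return obj


def vb_length(age, linf: float, k: float, t0: float = 0.0):
    """Forward VB map L(t) = L∞ (1 - exp(-K (t - t0)))."""
    return linf * (1.0 - np.exp(-k * (np.asarray(age, dtype=float) - t0)))


def fit_vb(
    ages: Sequence[float],
    lengths: Sequence[float],
    anchor_origin: bool = False,
    p0: tuple[float, float, float] | None = None,
) -> GrowthParams:
    """Fit the VB growth curve by nonlinear least squares.

    With ``anchor_origin`` the age-at-zero-length parameter t0 is fixed at
    0 so the fitted curve passes exactly through the origin — appropriate
    when the youngest ages in the sample poorly constrain t0.

    Lengths are taken in the unit of the data (conventionally cm); ages in
    years.  Raises a ``RuntimeError`` carrying the final parameter state
    if the optimiser fails to converge.
    """
    t = np.asarray(ages, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if len(t) < 3:
        raise ValueError(f"VB fit needs >= 3 (age, length) pairs, got {len(t)}")
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")
    lmax = float(L.max())
    if p0 is None:
        p0 = (1.1 * lmax, 0.3, 0.0)
    try:
        if anchor_origin:
            popt, _ = optimize.curve_fit(
                lambda a, linf, k: vb_length(a, linf, k, 0.0),
                t, L, p0=p0[:2], maxfev=20000,
            )
            linf, k, t0 = float(popt[0]), float(popt[1]), 0.0
        else:
            popt, _ = optimize.curve_fit(
                vb_length, t, L, p0=p0, maxfev=20000
            )
            linf, k, t0 = map(float, popt)
    except RuntimeError as err:
        raise RuntimeError(f"VB fit did not converge (start {p0}): {err}") from err
    resid = L - vb_length(t, linf, k, t0)
    dof = max(len(t) - (2 if anchor_origin else 3), 1)
    return GrowthParams(
        linf=linf, k=k, t0=t0, n=len(t),
        resid_sd=float(np.sqrt(resid @ resid / dof)),
    )


def length_to_relative_age(length, growth: GrowthParams):
    """Invert the VB curve: t = t0 - (1/K) ln(1 - L/L∞).

    Exact inverse of :func:`vb_length` for lengths in (0, L∞); lengths at
    or beyond L∞ have no defined age and raise.
    """
    L = np.asarray(length, dtype=float)
    if np.any(L <= 0) or np.any(L >= growth.linf):
        raise ValueError("length must lie strictly between 0 and linf")
    return growth.t0 - np.log1p(-L / growth.linf) / growth.k


def catch_curve(
    growth: GrowthParams,
    lengths_cm: Sequence[float] | None = None,
    binned: pd.DataFrame | None = None,
    bin_width_cm: float = 1.0,
    max_age: float | None = None,
    max_age_fraction: float = 0.95,
) -> CatchCurveResult:
    """Length-converted catch curve estimate of total mortality Z.

    Provide either raw ``lengths_cm`` (binned at ``bin_width_cm``, default
    1 cm = 10 mm) or a pre-binned frame with columns ``bin_lo, bin_hi,
    count`` (same unit as ``growth.linf``).  Each bin is assigned the
    relative age of its midpoint length and a duration
    Δt = t(hi) - t(lo); ln(count / Δt) is regressed on relative age over
    the trailing arm, and Z is the negative slope with its regression SE.

    The trailing arm is the bins strictly after the modal bin, excluding
    zero counts, bins whose upper edge reaches L∞ (undefined age) and —
    when ``max_age`` is given — bins whose midpoint age exceeds
    ``max_age_fraction`` x max_age, where ages pile up against the
    asymptote and the age conversion is unstable.
    """
    if (lengths_cm is None) == (binned is None):
        raise ValueError("provide exactly one of lengths_cm or binned")
    if lengths_cm is not None:
        L = np.asarray(lengths_cm, dtype=float)
        if len(L) == 0:
            raise ValueError("empty length sample")
        lo0 = math.floor(L.min() / bin_width_cm) * bin_width_cm
        edges = np.arange(lo0, L.max() + bin_width_cm, bin_width_cm)
        counts, _ = np.histogram(L, bins=edges)
        binned = pd.DataFrame(
            {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
        )
    bins = binned.reset_index(drop=True).copy()
    if not (bins["bin_hi"] > bins["bin_lo"]).all():
        raise ValueError("bins must have bin_hi > bin_lo")

    valid = (bins["bin_lo"] > 0) & (bins["bin_hi"] < growth.linf)
    age = np.full(len(bins), np.nan)
    dt = np.full(len(bins), np.nan)
    mid = 0.5 * (bins["bin_lo"] + bins["bin_hi"]).to_numpy()
    v = valid.to_numpy()
    if v.any():
        age[v] = length_to_relative_age(mid[v], growth)
        dt[v] = length_to_relative_age(
            bins.loc[valid, "bin_hi"].to_numpy(), growth
        ) - length_to_relative_age(bins.loc[valid, "bin_lo"].to_numpy(), growth)
    bins["age"] = age
    bins["dt"] = dt

    modal = int(bins["count"].idxmax())  # first maximal bin
    used = (
        (bins.index > modal)
        & v
        & (bins["count"] > 0)
    )
    if max_age is not None:
        used &= bins["age"] <= max_age_fraction * max_age
    bins["used"] = used
    arm = bins[used]
    if len(arm) < 3:
        raise ValueError(
            f"trailing arm has {len(arm)} usable bins; need >= 3"
        )
    yv = np.log(arm["count"].to_numpy(dtype=float) / arm["dt"].to_numpy())
    res = stats.linregress(arm["age"].to_numpy(), yv)
    z = -float(res.slope)
    if z < 0:
        log.warning("catch curve slope is positive: estimated Z = %.3f < 0", z)
    return CatchCurveResult(
        z=z,
        slope=float(res.slope),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        bins=bins,
        n_bins_used=len(arm),
    )


M_METHODS = ("hoenig_nls", "pauly_nls_t", "gunderson")


def natural_mortality(
    life: LifeHistory, method: Literal["hoenig_nls", "pauly_nls_t", "gunderson"]
) -> MortalityEstimate:
    """Natural mortality M (1/yr) from a life-history invariant.

    Three empirical estimators, each trading on a different invariant:

    * ``hoenig_nls`` — longevity:            M = 4.899 t_max^-0.916
    * ``pauly_nls_t`` — growth:              M = 4.118 K^0.73 L∞^-0.33
      (L∞ in cm; a value above 200 is assumed to be mm and is converted
      with a logged note)
    * ``gunderson`` — reproductive effort:   M = 1.79 GSI
    """
    if method == "hoenig_nls":
        if life.t_max <= 0:
            raise ValueError("hoenig_nls requires positive t_max")
        m = 4.899 * life.t_max**-0.916
        used = {"t_max": life.t_max}
    elif method == "pauly_nls_t":
        if life.k <= 0 or life.linf <= 0:
            raise ValueError("pauly_nls_t requires positive k and linf")
        linf_cm = life.linf
        if linf_cm > 200:  # no freshwater gillnet catch is 2 m+; treat as mm
            log.info("pauly_nls_t: linf=%.1f looks like mm; converting to cm", linf_cm)
            linf_cm /= 10.0
        m = 4.118 * life.k**0.73 * linf_cm**-0.33
        used = {"k": life.k, "linf_cm": linf_cm}
    elif method == "gunderson":
        if life.gsi < 0:
            raise ValueError("gunderson requires non-negative gsi")
        m = 1.79 * life.gsi
        used = {"gsi": life.gsi}
    else:
        raise ValueError(f"unknown method {method!r}; choose from {M_METHODS}")
    return MortalityEstimate(method=method, m=float(m), inputs=used)


def fishing_mortality(z: float, m: float) -> FishingMortality:
    """F = Z - M.  A negative F (M exceeding Z) is returned flagged, not
    clipped: it usually signals an inconsistency between the Z source and
    the M estimator rather than a true zero fishery."""
    if z < 0 or m < 0:
        raise ValueError("z and m must be non-negative")
    f = z - m
    if f < 0:
        log.warning("F = %.3f < 0: natural mortality estimate exceeds Z", f)
    return FishingMortality(f, m_exceeds_z=f < 0)
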