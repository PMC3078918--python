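"""Rate normalisation and kinetic parameter estimation.

Three operations, mirroring the published analysis:

* :func:`normalize_activity` expresses raw initial velocities as a
  percentage of the same construct's activity on the reference spot
  (1000 uM STA5A_687_699 by default) and per pmol of enzyme.  The transform
  is scale-invariant in the raw signal units; ``reference_value`` (default
  100, the percent convention) sets the absolute scale and may be given per
  construct when an external calibration is available.
* :func:`fit_mm_atp` fits v = Vmax_app [ATP] / (Km + [ATP]) to an ATP
  titration by nonlinear least squares, with standard errors from the fit
  covariance.
* :func:`efficiency_from_linear` estimates the catalytic efficiency
  Vmax/Km as the slope of an ordinary least-squares line (free intercept)
  through v versus [peptide] in the low-concentration linear regime, at a
  fixed, near-saturating ATP concentration (400 uM in the published design).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .fixtures import REFERENCE_CONC_UM, REFERENCE_PEPTIDE

__all__ = [
    "MMFit",
    "Efficiency",
    "normalize_activity",
    "fit_mm_atp",
    "efficiency_from_linear",
    "efficiency_table",
]


@dataclass
class MMFit:
    """Michaelis-Menten fit of an ATP titration."""

    construct_id: str
    km_uM: float
    km_se: float
    vmax_app: float
    vmax_se: float
    r_squared: float
    n_points: int
    extrapolated: bool = False  # fitted Km far beyond the titration range
    peptide_id: str | None = None
    peptide_conc_uM: float | None = None


@dataclass
class Efficiency:
    """Catalytic efficiency (Vmax/Km) from the linear regime of v vs [S]."""

    construct_id: str
    peptide_id: str
    vmax_km: float
    slope_se: float
    r_squared: float
    intercept: float
    conc_used: tuple[float, ...]
    non_substrate: bool = False  # negative fitted slope


def normalize_activity(
    rate_table: pd.DataFrame,
    *,
    reference: tuple[str, float] = (REFERENCE_PEPTIDE, REFERENCE_CONC_UM),
    pmol_per_reaction: dict[str, float] | None = None,
    per_pmol: bool = True,
    reference_value: float | dict[str, float] = 100.0,
    value_col: str = "v",
) -> pd.DataFrame:
    """Normalise rates to the reference spot, per construct.

    For each construct the replicate-mean rate of the reference (peptide,
    concentration) cell under assay conditions (control == "none", at that
    construct's maximal enzyme amount) defines the scale: every rate is
    multiplied by ``reference_value / v_ref`` and, if ``per_pmol``, divided
    by the pmol of enzyme in its own run (falling back to
    ``pmol_per_reaction`` when the table lacks an ``enzyme_pmol`` column).

    Returns a copy of the table with a ``v_norm`` column.  Raises if a
    construct lacks a usable (positive) reference cell.
    """
    ref_pep, ref_conc = reference
    out = []
    for construct, grp in rate_table.groupby("construct", sort=True):
        assay = grp[grp.get("control", "none") == "none"] if "control" in grp else grp
        ref_rows = assay[
            (assay["peptide_id"] == ref_pep) & (assay["conc_uM"] == ref_conc)
        ]
        if "enzyme_pmol" in ref_rows and len(ref_rows):
            ref_rows = ref_rows[ref_rows["enzyme_pmol"] == ref_rows["enzyme_pmol"].max()]
        if len(ref_rows) == 0 or not ref_rows[value_col].mean() > 0:
            raise ValueError(
                f"construct {construct}: reference cell {ref_pep} @ {ref_conc} uM "
                "missing or has zero rate"
            )
        v_ref = ref_rows[value_col].mean()
        ref_val = (
            reference_value.get(construct, 100.0)
            if isinstance(reference_value, dict)
            else reference_value
        )
        g = grp.copy()
        g["v_norm"] = g[value_col] * (ref_val / v_ref)
        if per_pmol:
            if "enzyme_pmol" in g.columns:
                pmol = g["enzyme_pmol"].replace(0, np.nan)
            elif pmol_per_reaction:
                pmol = pmol_per_reaction[construct]
            else:
                raise ValueError("per_pmol=True requires enzyme_pmol column or pmol_per_reaction map")
            g["v_norm"] = g["v_norm"] / pmol
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_mm_atp(
    atp_uM,
    v,
    *,
    construct_id: str = "",
    peptide_id: str | None = None,
    peptide_conc_uM: float | None = None,
) -> MMFit:
    """Least-squares Michaelis-Menten fit of v versus [ATP].

    Requires >= 4 distinct ATP levels with at least one nonzero.  A fitted
    Km more than 4x the largest measured [ATP] flags the result as
    extrapolated (the titration did not approach saturation).
    """
    atp = np.asarray(atp_uM, dtype=float)
    vv = np.asarray(v, dtype=float)
    if len(np.unique(atp)) < 4 or not np.any(atp > 0):
        raise ValueError("need >= 4 distinct ATP levels with at least one nonzero")
    vmax0 = max(float(vv.max()), 1e-12)
    km0 = float(np.median(atp[atp > 0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            _mm, atp, vv, p0=(vmax0, km0), bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=5000
        )
    vmax, km = (float(p) for p in popt)
    se = np.sqrt(np.diag(pcov))
    resid = vv - _mm(atp, *popt)
    ss_tot = float(np.sum((vv - vv.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else math.nan
    return MMFit(
        construct_id=construct_id,
        km_uM=km,
        km_se=float(se[1]),
        vmax_app=vmax,
        vmax_se=float(se[0]),
        r_squared=r2,
        n_points=len(vv),
        extrapolated=km > 4.0 * float(atp.max()),
        peptide_id=peptide_id,
        peptide_conc_uM=peptide_conc_uM,
    )


def efficiency_from_linear(
    conc_uM,
    v,
    *,
    construct_id: str = "",
    peptide_id: str = "",
    force_origin: bool = False,
    truncate: bool = False,
    min_points: int = 3,
) -> Efficiency:
    """Catalytic efficiency from the linear part of v versus [peptide].

    Ordinary least squares with a free intercept over the replicate-mean
    rates at each spotted concentration (all six levels by default).  With
    ``truncate=True`` the highest concentration is dropped, repeatedly,
    while doing so raises R^2 by more than 0.05 and at least ``min_points``
    levels remain — a guard against curvature entering at high [S].
    A negative slope flags the peptide as a non-substrate.
    """
    s = np.asarray(conc_uM, dtype=float)
    vv = np.asarray(v, dtype=float)
    order = np.argsort(s)
    s, vv = s[order], vv[order]
    if len(np.unique(s)) < min_points:
        raise ValueError(f"need >= {min_points} concentration levels")

    def _fit(sx, vx):
        if force_origin:
            slope = float(np.sum(sx * vx) / np.sum(sx * sx))
            resid = vx - slope * sx
            dof = len(sx) - 1
            se = math.sqrt(float(resid @ resid) / dof / float(np.sum(sx * sx))) if dof > 0 else math.nan
            ss_tot = float(np.sum((vx - vx.mean()) ** 2))
            r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else math.nan
            return slope, se, r2, 0.0
        res = stats.linregress(sx, vx)
        return float(res.slope), float(res.stderr), float(res.rvalue**2), float(res.intercept)

    slope, se, r2, intercept = _fit(s, vv)
    while truncate and len(np.unique(s)) > min_points:
        s_t, v_t = s[s < s.max()], vv[s < s.max()]
        slope_t, se_t, r2_t, int_t = _fit(s_t, v_t)
        if not (r2_t > r2 + 0.05):
            break
        s, vv = s_t, v_t
        slope, se, r2, intercept = slope_t, se_t, r2_t, int_t

    return Efficiency(
        construct_id=construct_id,
        peptide_id=peptide_id,
        vmax_km=slope,
        slope_se=se,
        r_squared=r2,
        intercept=intercept,
        conc_used=tuple(sorted(np.unique(s))),
        non_substrate=slope < 0,
    )


def efficiency_table(
    normalized_rates: pd.DataFrame,
    *,
    atp_uM: float = 400.0,
    value_col: str = "v_norm",
    force_origin: bool = False,
    truncate: bool = False,
) -> pd.DataFrame:
    """Per-(construct, peptide) efficiencies from a normalised rate table.

    Replicates are averaged per concentration before the regression.
    Rows from control runs or other ATP levels are ignored.
    """
    sub = normalized_rates
    if "control" in sub.columns:
        sub = sub[sub["control"] == "none"]
    sub = sub[sub["atp_uM"] == atp_uM]
    rows = []
    for (construct, pep), grp in sub.groupby(["construct", "peptide_id"], sort=True):
        means = grp.groupby("conc_uM")[value_col].mean()
        if len(means) < 3:
            continue
        eff = efficiency_from_linear(
            means.index.to_numpy(),
            means.to_numpy(),
            construct_id=construct,
            peptide_id=pep,
            force_origin=force_origin,
            truncate=truncate,
        )
        rows.append(
            {
                "construct": construct,
                "peptide_id": pep,
                "vmax_km": eff.vmax_km,
                "slope_se": eff.slope_se,
                "r_squared": eff.r_squared,
                "intercept": eff.intercept,
                "n_conc": len(eff.conc_used),
                "non_substrate": eff.non_substrate,
            }
        )
    return pd.DataFrame(rows)
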