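"""Substrate calling from the screening array.

A peptide is called a substrate of a construct when, at the 20-minute image:

* its background-subtracted signal exceeds ``sd_mult`` (default 2) times the
  standard deviation of the array background,
* its signal increases with enzyme amount across the enzyme titration
  (strictly increasing replicate means, with the top level exceeding the
  bottom by more than the same threshold),
* its signal likewise increases with ATP across the ATP titration, and
* it shows no above-threshold signal in any negative control (no enzyme,
  no ATP, staurosporine, AMP-PNP, kinase-dead enzyme, or pre-activated
  enzyme — the last excludes phospho-protein binding artifacts).

The background SD is pooled, at the 20-minute image, from the local
background channel and the tyrosine-free control spots.  The dose-dependence
rule operationalises the published qualitative criterion ("signals must
increase with enzyme and ATP concentration") as strict monotonicity of
replicate means plus a top-vs-bottom margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (
    CYCLES_PER_MIN,
    NO_TYR_CONTROL_ID,
    PRE_PHOSPHO_CONTROL_ID,
)

__all__ = ["SubstrateCall", "estimate_background_sd", "call_substrates", "calls_to_table"]

CONTROL_SPOT_IDS = frozenset({NO_TYR_CONTROL_ID, PRE_PHOSPHO_CONTROL_ID})


@dataclass
class SubstrateCall:
    """Screening verdict for one (peptide, construct)."""

    peptide_id: str
    construct_id: str
    called: bool
    above_threshold: bool
    increases_with_enzyme: bool
    increases_with_atp: bool
    nonspecific: bool
    s20_mean: float
    bg_sd_used: float


def _s20(dataset: pd.DataFrame, at_min: float = 20.0) -> pd.DataFrame:
    """Background-subtracted signal at the imaged cycle nearest ``at_min``."""
    target = at_min * CYCLES_PER_MIN
    cycle = dataset["cycle"].iloc[(dataset["cycle"] - target).abs().argmin()]
    sub = dataset[dataset["cycle"] == cycle].copy()
    sub["s20"] = sub["signal"] - sub["background"]
    return sub


def estimate_background_sd(dataset: pd.DataFrame, at_min: float = 20.0) -> tuple[float, float]:
    """Pooled (mean, SD) of the array background at the 20-minute image.

    Pools the local background channel with the tyrosine-free control spots'
    raw signals, each group centred on its own mean so only dispersion is
    pooled.  Raises if the dataset carries no background information.
    """
    sub = _s20(dataset, at_min)
    groups = []
    bg = sub["background"].to_numpy(dtype=float)
    if len(bg):
        groups.append(bg - bg.mean())
    notyr = sub.loc[sub["peptide_id"] == NO_TYR_CONTROL_ID, "signal"].to_numpy(dtype=float)
    if len(notyr) > 1:
        groups.append(notyr - notyr.mean())
    if not groups:
        raise ValueError(
            "no background channel or no-Tyr control spots; pass an explicit bg_sd"
        )
    pooled = np.concatenate(groups)
    return float(bg.mean()) if len(bg) else float("nan"), float(pooled.std(ddof=1))


def _dose_response(s20: pd.DataFrame, level_col: str, threshold: float) -> pd.Series:
    """Strictly-increasing-replicate-means test per peptide along a titration.

    Requires at least two levels; the top level must exceed the bottom by
    more than ``threshold``.  Returns a boolean Series indexed by peptide,
    or an all-False Series when the titration is absent.
    """
    means = (
        s20.groupby(["peptide_id", level_col])["s20"].mean().unstack(level_col).sort_index(axis=1)
    )
    if means.shape[1] < 2:
        return pd.Series(False, index=means.index)
    values = means.to_numpy()
    strictly_up = np.all(np.diff(values, axis=1) > 0, axis=1)
    margin = (values[:, -1] - values[:, 0]) > threshold
    return pd.Series(strictly_up & margin, index=means.index)


def call_substrates(
    dataset: pd.DataFrame,
    *,
    sd_mult: float = 2.0,
    bg_sd: float | None = None,
    at_min: float = 20.0,
) -> pd.DataFrame:
    """Screen a simulated or measured dataset; one row per (construct, peptide).

    ``dataset`` must contain, per construct, an enzyme titration at fixed
    ATP, an ATP titration at fixed enzyme, and (optionally) negative-control
    runs.  Peptides whose titrations are absent are reported uncalled with
    their evidence flags False.
    """
    if bg_sd is None:
        _, bg_sd = estimate_background_sd(dataset, at_min)
        if bg_sd == 0:
            raise ValueError(
                "estimated background SD is 0 (degenerate input); pass bg_sd explicitly"
            )
    threshold = sd_mult * bg_sd

    results = []
    for construct, cgrp in dataset.groupby("construct", sort=True):
        s20 = _s20(cgrp, at_min)
        s20 = s20[~s20["peptide_id"].isin(CONTROL_SPOT_IDS)]
        # keep the highest spotted concentration per peptide
        top_conc = s20.groupby("peptide_id")["conc_uM"].transform("max")
        s20 = s20[s20["conc_uM"] == top_conc]

        assay = s20[s20["control"] == "none"]
        controls = s20[s20["control"] != "none"]

        # enzyme titration: fixed ATP level with the most enzyme levels
        n_enzyme_levels = assay.groupby("atp_uM")["enzyme_pmol"].nunique()
        atp_fixed = n_enzyme_levels.idxmax() if len(n_enzyme_levels) else None
        enz = assay[assay["atp_uM"] == atp_fixed] if atp_fixed is not None else assay.iloc[0:0]
        inc_enzyme = _dose_response(enz, "enzyme_pmol", threshold)

        # ATP titration: fixed (maximal) enzyme amount
        n_atp_levels = assay.groupby("enzyme_pmol")["atp_uM"].nunique()
        enz_fixed = n_atp_levels.idxmax() if len(n_atp_levels) else None
        atp = assay[assay["enzyme_pmol"] == enz_fixed] if enz_fixed is not None else assay.iloc[0:0]
        inc_atp = _dose_response(atp, "atp_uM", threshold)

        # intensity at the top assay condition
        if atp_fixed is not None and len(enz):
            top = enz[enz["enzyme_pmol"] == enz["enzyme_pmol"].max()]
            s20_mean = top.groupby("peptide_id")["s20"].mean()
        else:
            s20_mean = assay.groupby("peptide_id")["s20"].mean()
        above = s20_mean > threshold

        nonspec = (
            controls.groupby("peptide_id")["s20"].mean() > threshold
            if len(controls)
            else pd.Series(dtype=float)
        )

        for pep in sorted(s20["peptide_id"].unique()):
            a = bool(above.get(pep, False))
            e = bool(inc_enzyme.get(pep, False))
            t = bool(inc_atp.get(pep, False))
            ns = bool(nonspec.get(pep, False))
            results.append(
                SubstrateCall(
                    peptide_id=pep,
                    construct_id=construct,
                    called=a and e and t and not ns,
                    above_threshold=a,
                    increases_with_enzyme=e,
                    increases_with_atp=t,
                    nonspecific=ns,
                    s20_mean=float(s20_mean.get(pep, np.nan)),
                    bg_sd_used=float(bg_sd),
                )
            )
    return pd.DataFrame([vars(c) for c in results])


def calls_to_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot calls into the published X-mark layout (peptides x constructs)."""
    wide = calls.pivot(index="peptide_id", columns="construct_id", values="called")
    return wide.map(lambda b: "X" if b else "")
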