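"""Cross-construct comparison transforms of catalytic efficiencies.

Two transforms make Vmax/Km tables comparable across kinase constructs:

* **fold change** — the reference construct (the JH1-JH2 wild type in the
  published analysis) is set to 1 for every peptide and each other
  construct's efficiency is expressed as a ratio to it.  This levels off
  the peptide-specific efficiency while preserving differences in both
  activity and specificity between constructs.
* **percent of total** — each efficiency is expressed as a percentage of
  the sum of all efficiencies of its own construct.  This averages out
  overall activity differences while preserving peptide specificity, and
  is the weighting used for the substrate motif logos.

Reporting columns are rounded half-up to integers, matching the published
table; unrounded values are always retained alongside.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = ["round_half_up", "fold_change", "pct_total", "comparison_table"]


def round_half_up(x) -> int | np.ndarray:
    """Round to nearest integer with .5 going up (publication convention)."""
    if np.isscalar(x):
        return int(math.floor(x + 0.5))
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def fold_change(
    eff_table: pd.DataFrame,
    reference_construct: str,
    *,
    value_col: str = "vmax_km",
) -> pd.DataFrame:
    """Per-peptide efficiency ratios to the reference construct.

    ``eff_table`` is long format (construct, peptide_id, vmax_km).  Peptides
    whose reference efficiency is zero or missing are omitted with a
    warning.  Adds ``fold_change`` and ``fold_change_int`` columns.
    """
    ref = (
        eff_table[eff_table["construct"] == reference_construct]
        .set_index("peptide_id")[value_col]
    )
    if len(ref) == 0:
        raise ValueError(f"reference construct {reference_construct!r} absent")
    usable = ref[ref > 0]
    dropped = set(eff_table["peptide_id"]) - set(usable.index)
    if dropped:
        warnings.warn(
            f"omitting peptides with zero/missing reference efficiency: {sorted(dropped)}"
        )
    out = eff_table[eff_table["peptide_id"].isin(usable.index)].copy()
    out["fold_change"] = out[value_col] / out["peptide_id"].map(usable)
    out["fold_change_int"] = round_half_up(out["fold_change"].to_numpy())
    return out


def pct_total(eff_table: pd.DataFrame, *, value_col: str = "vmax_km") -> pd.DataFrame:
    """Efficiencies as percent of each construct's total.

    Adds ``pct_total`` (sums to exactly 100 per construct) and
    ``pct_total_int`` columns.  Raises on an all-zero construct.
    """
    out = eff_table.copy()
    totals = out.groupby("construct")[value_col].transform("sum")
    if (out.groupby("construct")[value_col].sum() <= 0).any():
        bad = out.groupby("construct")[value_col].sum()
        raise ValueError(f"construct(s) with non-positive total efficiency: "
                         f"{list(bad[bad <= 0].index)}")
    out["pct_total"] = 100.0 * out[value_col] / totals
    out["pct_total_int"] = round_half_up(out["pct_total"].to_numpy())
    return out


def comparison_table(
    eff_table: pd.DataFrame,
    reference_construct: str,
    *,
    value_col: str = "vmax_km",
) -> pd.DataFrame:
    """Both transforms on one long-format efficiency table."""
    out = fold_change(eff_table, reference_construct, value_col=value_col)
    out = pct_total(out, value_col=value_col)
    out["reference_construct"] = reference_construct
    return out
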