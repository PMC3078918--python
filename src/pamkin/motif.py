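"""Catalytic-efficiency-weighted substrate recognition motifs.

Substrate peptides are aligned on their central tyrosine (the phosphoacceptor)
and each peptide contributes to the per-position residue frequencies with a
weight — in the published analysis, its percent of the construct's total
Vmax/Km.  Stack heights are the relative entropy (Kullback-Leibler
divergence, in bits) of each position's weighted residue distribution from a
uniform background over the 20 canonical amino acids:

    height(p) = log2(20) + sum_r f_p(r) log2 f_p(r)

so a position occupied by a single residue in every weighted peptide reaches
the maximum log2(20) ~ 4.32 bits and a uniformly spread position scores 0.
Positions outside a peptide's span are gaps; frequencies at each position are
renormalised over the non-gap weight.  Only positions -5..+5 around the
anchor tyrosine are considered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import AMINO_ACIDS, PeptideSpec, central_tyrosine

__all__ = [
    "MotifMatrix",
    "align_on_central_tyr",
    "weighted_motif",
    "compare_motifs",
    "motif_to_meme",
    "plot_logo",
]

POSITIONS = tuple(range(-5, 6))
LOG2_20 = math.log2(20.0)
GAP = "-"


@dataclass
class MotifMatrix:
    """Weighted residue frequencies and relative-entropy heights, -5..+5.

    ``freq`` is positions x 20 residues (rows sum to 1 where any weight is
    present); ``height`` is the per-position relative entropy in bits;
    ``letter_height`` = freq x height gives the stacked-letter sizes of a
    logo; ``effective_weight`` is the total weight with a residue (non-gap)
    at each position.
    """

    freq: pd.DataFrame
    height: pd.Series
    letter_height: pd.DataFrame
    effective_weight: pd.Series


def align_on_central_tyr(
    peptides: Sequence[PeptideSpec | tuple[str, str]],
) -> pd.DataFrame:
    """Align peptides on the anchor tyrosine; columns are positions -5..+5.

    The anchor is the Tyr closest to the sequence midpoint (N-terminal-most
    on ties).  Positions outside a peptide are gaps.  Peptides without any
    tyrosine are skipped with a warning.
    """
    rows = {}
    for pep in peptides:
        pid, seq = (pep.peptide_id, pep.sequence) if isinstance(pep, PeptideSpec) else pep
        try:
            anchor = (
                pep.central_tyr_index
                if isinstance(pep, PeptideSpec) and pep.central_tyr_index
                else central_tyrosine(seq)
            )
        except ValueError:
            import warnings

            warnings.warn(f"skipping {pid}: no tyrosine in sequence")
            continue
        row = []
        for offset in POSITIONS:
            i = anchor - 1 + offset
            row.append(seq[i] if 0 <= i < len(seq) else GAP)
        rows[pid] = row
    aln = pd.DataFrame.from_dict(rows, orient="index", columns=list(POSITIONS))
    if len(aln) and not (aln[0] == "Y").all():
        raise AssertionError("anchor column must be tyrosine")
    return aln


def weighted_motif(
    alignment: pd.DataFrame,
    weights: Mapping[str, float],
    *,
    background: Mapping[str, float] | None = None,
) -> MotifMatrix:
    """Weighted frequencies and relative-entropy heights from an alignment.

    ``weights`` maps peptide_id -> non-negative weight (at least one must be
    positive); keys must be rows of the alignment.  ``background`` replaces
    the uniform 1/20 reference distribution when given.
    """
    missing = set(weights) - set(alignment.index)
    if missing:
        raise ValueError(f"weights for peptides absent from alignment: {sorted(missing)}")
    w = pd.Series({pid: float(weights.get(pid, 0.0)) for pid in alignment.index})
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    if not (w > 0).any():
        raise ValueError("all weights are zero")

    aas = list(AMINO_ACIDS)
    if background is None:
        bg = pd.Series(1.0 / 20.0, index=aas)
    else:
        bg = pd.Series({a: background[a] for a in aas})
        bg = bg / bg.sum()

    freq = pd.DataFrame(0.0, index=list(POSITIONS), columns=aas)
    eff_weight = pd.Series(0.0, index=list(POSITIONS))
    for pos in POSITIONS:
        col = alignment[pos]
        present = col != GAP
        total = w[present].sum()
        eff_weight[pos] = total
        if total <= 0:
            continue
        for aa, grp in w[present].groupby(col[present]):
            freq.loc[pos, aa] = grp.sum() / total

    height = pd.Series(0.0, index=list(POSITIONS))
    for pos in POSITIONS:
        f = freq.loc[pos]
        nz = f[f > 0]
        if eff_weight[pos] > 0:
            height[pos] = float((nz * np.log2(nz / bg[nz.index])).sum())
    letter_height = freq.mul(height, axis=0)
    return MotifMatrix(
        freq=freq, height=height, letter_height=letter_height, effective_weight=eff_weight
    )


def _js_divergence_bits(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)

    def _kl(a, b):
        nz = a > 0
        return float(np.sum(a[nz] * np.log2(a[nz] / b[nz])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def compare_motifs(m1: MotifMatrix, m2: MotifMatrix) -> pd.Series:
    """Per-position Jensen-Shannon divergence (bits, in [0, 1]) between motifs.

    Positions where either motif has no residue weight are NaN.
    """
    if list(m1.freq.index) != list(m2.freq.index):
        raise ValueError("motifs cover different position ranges")
    out = pd.Series(np.nan, index=m1.freq.index, name="js_bits")
    for pos in m1.freq.index:
        if m1.effective_weight[pos] > 0 and m2.effective_weight[pos] > 0:
            out[pos] = _js_divergence_bits(
                m1.freq.loc[pos].to_numpy(), m2.freq.loc[pos].to_numpy()
            )
    return out


def motif_to_meme(motif: MotifMatrix, name: str = "motif") -> str:
    """MEME-format (minimal motif format) probability matrix."""
    lines = [
        "MEME version 4",
        "",
        f"ALPHABET= {AMINO_ACIDS}",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 20 w= {len(POSITIONS)}",
    ]
    for pos in POSITIONS:
        row = motif.freq.loc[pos]
        lines.append(" " + " ".join(f"{row[a]:.6f}" for a in AMINO_ACIDS))
    return "\n".join(lines) + "\n"


def plot_logo(motif: MotifMatrix, ax=None, title: str | None = None):
    """Minimal letter-stack rendering of a motif (matplotlib).

    The numeric :class:`MotifMatrix` is the tested surface; this is a thin
    convenience layer for visual inspection.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for x, pos in enumerate(POSITIONS):
        stack = motif.letter_height.loc[pos]
        y = 0.0
        for aa in stack[stack > 0].sort_values().index:
            h = stack[aa]
            ax.text(
                x,
                y + h / 2,
                aa,
                ha="center",
                va="center",
                fontsize=6 + 40 * h / LOG2_20,
                family="monospace",
            )
            y += h
    ax.set_xticks(range(len(POSITIONS)))
    ax.set_xticklabels([str(p) for p in POSITIONS])
    ax.set_xlim(-0.5, len(POSITIONS) - 0.5)
    ax.set_ylim(0, LOG2_20)
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    return ax
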