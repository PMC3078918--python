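"""Packaged reference data for the JAK2 PamChip kinetics pipeline.

The package ships three small tab-separated fixtures transcribed from the
published study of JAK2 kinase-domain constructs on real-time peptide
microarrays:

* the 63-peptide substrate screen (which of the 144 arrayed peptides each
  construct phosphorylated),
* the 24-peptide catalytic-efficiency table (Vmax/Km +/- SE, R-squared,
  fold change vs. the JH1-JH2 wild type, and percent of the construct's
  total Vmax/Km, all at 400 uM ATP), and
* per-construct kinetic constants (Km for ATP, apparent Vmax per pmol
  enzyme, and the amount of enzyme used per reaction).

These serve both as ground truth for the synthetic assay generator and as
oracles for the analysis stages.  Values are stored exactly as printed;
the only normalisation applied at load time is decimal-comma -> decimal-point
conversion in the R-squared column (a European-format artifact of the
publication).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CONSTRUCTS",
    "PeptideSpec",
    "ConstructProfile",
    "ScreenTruth",
    "EfficiencyRecord",
    "load_table1",
    "load_table2",
    "load_constructs",
    "load_peptides",
    "peptides_to_fasta",
]

#: Canonical construct identifiers, in the column order of the publication.
CONSTRUCTS = (
    "JAK2_JH1JH2_WT",
    "JAK2_JH1JH2_V617F",
    "JAK2_JH1",
    "JAK3_JH1",
)

#: Catalytically dead JAK2 used as a negative control.
KINASE_DEAD = "JAK2_K882D"

#: Reference substrate for activity normalisation (1000 uM spot).
REFERENCE_PEPTIDE = "STA5A_687_699"
REFERENCE_CONC_UM = 1000.0

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _data_path(name: str) -> Path:
    path = resources.files("pamkin").joinpath("data", name)
    return Path(str(path))


@dataclass(frozen=True)
class PeptideSpec:
    """One arrayed peptide: identity, sequence and spotting concentrations.

    ``peptide_id`` follows the UniProt-derived ``NAME_start_end`` convention;
    ``central_tyr_index`` is the 1-based position of the tyrosine used as
    the alignment anchor.  ``no_tyr_control`` marks the tyrosine-free
    antibody control, which is exempt from the Tyr invariants.
    """

    peptide_id: str
    sequence: str
    central_tyr_index: int = 0
    spotted_concs_uM: tuple[float, ...] = (1000.0,)
    no_tyr_control: bool = False

    def __post_init__(self):
        if not self.no_tyr_control:
            if "Y" not in self.sequence:
                raise ValueError(f"{self.peptide_id}: no Tyr in {self.sequence!r}")
            idx = self.central_tyr_index or central_tyrosine(self.sequence)
            if self.sequence[idx - 1] != "Y":
                raise ValueError(
                    f"{self.peptide_id}: central_tyr_index {idx} is not a Tyr"
                )
            object.__setattr__(self, "central_tyr_index", idx)
        concs = tuple(float(c) for c in self.spotted_concs_uM)
        if any(c <= 0 for c in concs) or list(concs) != sorted(concs):
            raise ValueError(f"{self.peptide_id}: concentrations must be >0 ascending")
        object.__setattr__(self, "spotted_concs_uM", concs)


def central_tyrosine(sequence: str) -> int:
    """1-based position of the alignment-anchor tyrosine.

    The anchor is the Tyr closest to the sequence midpoint; ties are broken
    toward the N-terminus.  For the 13-mers and 15-mers used on the arrays
    this reproduces the 'central Tyr' of the published alignment.
    """
    positions = [i + 1 for i, aa in enumerate(sequence) if aa == "Y"]
    if not positions:
        raise ValueError(f"no tyrosine in {sequence!r}")
    mid = (len(sequence) + 1) / 2.0
    return min(positions, key=lambda p: (abs(p - mid), p))


@dataclass(frozen=True)
class ConstructProfile:
    """Ground-truth kinetic profile of one kinase construct.

    ``efficiency_by_peptide`` maps peptide_id -> Vmax/Km in relative-activity
    units per uM; ``km_atp_uM`` is the Michaelis constant for ATP and
    ``vmax_app_per_pmol`` the apparent maximal velocity per pmol enzyme.
    """

    construct_id: str
    km_atp_uM: float
    vmax_app_per_pmol: float
    pmol_per_reaction: float
    efficiency_by_peptide: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not math.isnan(self.km_atp_uM) and self.km_atp_uM <= 0:
            raise ValueError("km_atp_uM must be > 0")
        if not math.isnan(self.vmax_app_per_pmol) and self.vmax_app_per_pmol < 0:
            raise ValueError("vmax_app_per_pmol must be >= 0")
        if any(v < 0 for v in self.efficiency_by_peptide.values()):
            raise ValueError("efficiencies must be >= 0")

    @property
    def kinase_dead(self) -> bool:
        return self.vmax_app_per_pmol == 0


@dataclass(frozen=True)
class ScreenTruth:
    """Phosphorylation calls of the 144-peptide screening array (per construct)."""

    calls: Mapping[str, frozenset[str]]
    sequences: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        jh1 = self.calls.get("JAK2_JH1", frozenset())
        for construct, peptides in self.calls.items():
            if construct != "JAK2_JH1" and not peptides <= jh1:
                raise ValueError(
                    f"screen calls for {construct} are not nested within JAK2_JH1"
                )


@dataclass(frozen=True)
class EfficiencyRecord:
    """One printed catalytic-efficiency cell: Vmax/Km +/- SE and fit R^2."""

    vmax_km: float
    vmax_km_se: float
    r_squared: float
    fold_change: int
    pct_total: int


def load_table1(path: str | Path | None = None) -> ScreenTruth:
    """Load the screening-array substrate calls.

    Returns a :class:`ScreenTruth` whose ``calls`` map constructs to the set
    of peptides marked phosphorylated.  The JH1 kinase domain alone
    phosphorylates 63 of the 144 arrayed peptides; both JH1-JH2 constructs
    phosphorylate strict subsets of those.
    """
    path = Path(path) if path is not None else _data_path("table1_screen_calls.tsv")
    if not path.exists():
        raise FileNotFoundError(f"screen-call fixture missing: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"peptide_id", "sequence", "JAK2_JH1", "JAK2_JH1JH2_WT", "JAK2_JH1JH2_V617F"}
    if not required <= set(df.columns):
        raise ValueError(f"corrupt screen-call fixture {path}: columns {list(df.columns)}")
    calls = {
        c: frozenset(df.loc[df[c].str.strip() == "X", "peptide_id"])
        for c in ("JAK2_JH1", "JAK2_JH1JH2_WT", "JAK2_JH1JH2_V617F")
    }
    sequences = dict(zip(df["peptide_id"], df["sequence"]))
    return ScreenTruth(calls=calls, sequences=sequences)


def load_table2(
    path: str | Path | None = None,
) -> dict[str, dict[str, EfficiencyRecord]]:
    """Load the 24-peptide catalytic-efficiency table.

    Returns ``{construct_id: {peptide_id: EfficiencyRecord}}`` covering the
    four profiled constructs.  Decimal commas in the R^2 column are
    normalised to decimal points.
    """
    path = Path(path) if path is not None else _data_path("table2_catalytic_efficiency.tsv")
    if not path.exists():
        raise FileNotFoundError(f"efficiency fixture missing: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["r_squared"] = df["r_squared"].str.replace(",", ".", regex=False).astype(float)
    for col in ("vmax_km", "vmax_km_se"):
        df[col] = df[col].astype(float)
    for col in ("fold_change", "pct_total"):
        df[col] = df[col].astype(int)
    out: dict[str, dict[str, EfficiencyRecord]] = {}
    for construct, grp in df.groupby("construct"):
        if len(grp) != 24:
            raise ValueError(
                f"efficiency fixture {path}: {construct} has {len(grp)} rows, expected 24"
            )
        out[construct] = {
            row.peptide_id: EfficiencyRecord(
                vmax_km=row.vmax_km,
                vmax_km_se=row.vmax_km_se,
                r_squared=row.r_squared,
                fold_change=row.fold_change,
                pct_total=row.pct_total,
            )
            for row in grp.itertuples()
        }
    return out


def load_table2_frame(path: str | Path | None = None) -> pd.DataFrame:
    """Long-format view of the efficiency table (one row per construct x peptide)."""
    table = load_table2(path)
    rows = [
        {
            "construct": construct,
            "peptide_id": pep,
            "vmax_km": rec.vmax_km,
            "vmax_km_se": rec.vmax_km_se,
            "r_squared": rec.r_squared,
            "fold_change_printed": rec.fold_change,
            "pct_total_printed": rec.pct_total,
        }
        for construct, recs in table.items()
        for pep, rec in recs.items()
    ]
    return pd.DataFrame(rows)


def load_constructs(path: str | Path | None = None) -> dict[str, ConstructProfile]:
    """Load per-construct kinetic constants and attach efficiency maps."""
    path = Path(path) if path is not None else _data_path("constructs.tsv")
    if not path.exists():
        raise FileNotFoundError(f"construct fixture missing: {path}")
    df = pd.read_csv(path, sep="\t")
    table2 = load_table2()
    profiles = {}
    for row in df.itertuples():
        eff = {
            pep: rec.vmax_km for pep, rec in table2.get(row.construct_id, {}).items()
        }
        profiles[row.construct_id] = ConstructProfile(
            construct_id=row.construct_id,
            km_atp_uM=float(row.km_atp_uM) if pd.notna(row.km_atp_uM) else float("nan"),
            vmax_app_per_pmol=(
                float(row.vmax_app_per_pmol)
                if pd.notna(row.vmax_app_per_pmol)
                else float("nan")
            ),
            pmol_per_reaction=float(row.pmol_per_reaction),
            efficiency_by_peptide=eff,
        )
    return profiles


def load_peptides(
    concs_uM: tuple[float, ...] = (1000.0,), path: str | Path | None = None
) -> list[PeptideSpec]:
    """PeptideSpecs for the 63 screen peptides, spotted at ``concs_uM``."""
    truth = load_table1(path)
    return [
        PeptideSpec(peptide_id=pid, sequence=seq, spotted_concs_uM=concs_uM)
        for pid, seq in truth.sequences.items()
    ]


def peptides_to_fasta(peptides: list[PeptideSpec], path: str | Path) -> None:
    """Export a peptide library as FASTA (record id = peptide_id)."""
    with open(path, "w") as fh:
        for pep in peptides:
            fh.write(f">{pep.peptide_id}\n{pep.sequence}\n")


def read_fasta(path: str | Path) -> list[PeptideSpec]:
    """Read a peptide library from FASTA."""
    peptides = []
    pid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if pid is not None:
                    peptides.append(PeptideSpec(pid, "".join(chunks)))
                pid, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if pid is not None:
        peptides.append(PeptideSpec(pid, "".join(chunks)))
    return peptides
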