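"""Synthetic real-time peptide-microarray (PamChip-style) kinase assays.

The generator produces complete experiments — a fluorescence time series for
every spot under every run condition, including all negative controls — from
a known kinetic ground truth, so that every downstream stage of the pipeline
(rate extraction, substrate calling, Km/Vmax and Vmax/Km estimation) can be
tested against known answers.

Forward model
-------------
The true initial phosphorylation velocity of a spot is first order in enzyme
and (by default) in immobilised peptide, and Michaelis-saturating in ATP::

    v = E_pmol * (Vmax/Km)_pep * f([S]) * [ATP] / (Km_ATP + [ATP]) * u

where ``f([S]) = [S]`` in the default linear (Vmax/Km) regime, or
``[S] / (1 + [S]/Km_pep)`` when a peptide-level Michaelis constant is
configured, and ``u`` converts relative-activity units to signal units.
Inhibitor, no-enzyme, no-ATP, kinase-dead and pre-activated-enzyme controls
force ``v = 0``.

Each spot's progress curve follows the exponential-association form used by
the measurement software, ``y(c) = y0 + ymax * (1 - exp(-k c))`` with ``c``
the pump-cycle index, plus additive and proportional Gaussian noise and a
Gaussian local background.  The rate constant ``k`` is chosen so that the
pipeline's definition of the initial velocity — the curve tangent at the
second imaged cycle, in signal units per minute — equals ``v`` exactly
(``second_point`` convention, solved with the Lambert W function).  The
simpler closed form ``k = v / (2 ymax)``, which matches the tangent at cycle
zero instead, is available as the ``initial_tangent`` convention.

Assay geometry defaults follow the published protocol: 60 pump cycles at
2 cycles per minute, imaged every second cycle (30 images over 30 minutes);
screening arrays carry 144 peptides spotted at 1000 uM, and the custom chip
carries 24 peptides in a {100, 300, 400, 600, 750, 1000} uM series.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import lambertw

from .fixtures import (
    AMINO_ACIDS,
    CONSTRUCTS,
    REFERENCE_CONC_UM,
    REFERENCE_PEPTIDE,
    ConstructProfile,
    PeptideSpec,
    ScreenTruth,
    central_tyrosine,
    load_constructs,
    load_table1,
    load_table2,
)

__all__ = [
    "RunCondition",
    "NoiseModel",
    "SpotSeries",
    "true_initial_rate",
    "rate_constant",
    "simulate_spot",
    "simulate_experiment",
    "screening_layout",
    "custom_chip_layout",
    "screening_design",
    "custom_chip_design",
    "atp_titration_design",
    "screen_efficiencies",
]

#: Control types that force a null reaction on substrate spots.
NULL_CONTROLS = frozenset(
    {"no_enzyme", "no_atp", "staurosporine", "amp_pnp", "kinase_dead", "pre_activated"}
)
CONTROL_TYPES = frozenset({"none"}) | NULL_CONTROLS

#: Peptide IDs of the on-array antibody controls.
NO_TYR_CONTROL_ID = "CTRL_NOTYR"
PRE_PHOSPHO_CONTROL_ID = "CTRL_PPHOS"

#: Default imaged cycles: every second cycle of a 60-cycle run.
DEFAULT_CYCLES = tuple(range(2, 61, 2))

#: Cycles per minute of the pump programme (time_min = cycle / 2).
CYCLES_PER_MIN = 2.0

#: Default plateau signal per uM of spotted peptide.
DEFAULT_YMAX_PER_UM = 50.0

#: Custom-chip peptide concentration series (uM).
CUSTOM_CHIP_CONCS = (100.0, 300.0, 400.0, 600.0, 750.0, 1000.0)


@dataclass(frozen=True)
class RunCondition:
    """One incubation: construct, enzyme amount, ATP, replicate, control type."""

    construct_id: str
    enzyme_pmol: float
    atp_uM: float
    replicate: int = 1
    control_type: str = "none"

    def __post_init__(self):
        if self.control_type not in CONTROL_TYPES:
            raise ValueError(f"unknown control_type {self.control_type!r}")
        if self.enzyme_pmol < 0 or self.atp_uM < 0:
            raise ValueError("enzyme_pmol and atp_uM must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.control_type == "no_enzyme" and self.enzyme_pmol != 0:
            raise ValueError("no_enzyme control requires enzyme_pmol = 0")
        if self.control_type == "no_atp" and self.atp_uM != 0:
            raise ValueError("no_atp control requires atp_uM = 0")

    def key(self) -> str:
        return (
            f"{self.construct_id}|{self.control_type}|{self.enzyme_pmol:g}"
            f"|{self.atp_uM:g}|{self.replicate}"
        )


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise on spot signals and local backgrounds.

    The publication reports no noise model; these defaults are calibrated so
    that technical-replicate CVs land in the 5-10% range suggested by the
    standard errors of the printed efficiency table.
    """

    sigma_add: float = 5.0
    sigma_prop: float = 0.05
    bg_mean: float = 50.0
    bg_sd: float = 10.0

    def __post_init__(self):
        if min(self.sigma_add, self.sigma_prop, self.bg_sd) < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def noiseless(cls, bg_mean: float = 0.0) -> "NoiseModel":
        return cls(sigma_add=0.0, sigma_prop=0.0, bg_mean=bg_mean, bg_sd=0.0)


@dataclass
class SpotSeries:
    """One spot's intensity time series with its run metadata."""

    peptide_id: str
    spot_conc_uM: float
    cycles: np.ndarray
    signals: np.ndarray
    backgrounds: np.ndarray
    run_condition: RunCondition | None = None
    saturated: bool = False

    def __post_init__(self):
        if not (len(self.cycles) == len(self.signals) == len(self.backgrounds)):
            raise ValueError("cycles, signals and backgrounds must have equal length")

    @property
    def times_min(self) -> np.ndarray:
        return np.asarray(self.cycles) / CYCLES_PER_MIN

    @property
    def corrected(self) -> np.ndarray:
        return np.asarray(self.signals) - np.asarray(self.backgrounds)


def true_initial_rate(
    profile: ConstructProfile,
    peptide_id: str,
    spot_conc_uM: float,
    cond: RunCondition,
    *,
    signal_scale: float = 1.0,
    km_pep_uM: float | None = None,
    efficiencies: Mapping[str, float] | None = None,
) -> float:
    """True initial velocity (signal units / min) of one spot.

    Linear in enzyme amount, linear (or Michaelis with ``km_pep_uM``) in
    spotted peptide, saturating in ATP with the construct's Km.  All null
    controls, the kinase-dead construct and peptides absent from the
    efficiency map yield zero.
    """
    if spot_conc_uM < 0:
        raise ValueError("spot_conc_uM must be >= 0")
    if cond.control_type in NULL_CONTROLS:
        return 0.0
    if profile.kinase_dead:
        return 0.0
    eff_map = profile.efficiency_by_peptide if efficiencies is None else efficiencies
    eff = eff_map.get(peptide_id, 0.0)
    if eff <= 0 or cond.enzyme_pmol == 0 or cond.atp_uM == 0:
        return 0.0
    atp_factor = cond.atp_uM / (profile.km_atp_uM + cond.atp_uM)
    if km_pep_uM is None:
        s_factor = spot_conc_uM
    else:
        s_factor = spot_conc_uM / (1.0 + spot_conc_uM / km_pep_uM)
    return cond.enzyme_pmol * eff * s_factor * atp_factor * signal_scale


def rate_constant(
    v_true,
    ymax,
    *,
    convention: str = "second_point",
    v_cycle: int = 4,
):
    """Per-cycle rate constant(s) matching a target initial velocity.

    ``initial_tangent``: ``k = v / (2 ymax)`` (curve tangent at cycle 0 in
    minutes equals v).  ``second_point``: solve ``2 ymax k exp(-k c) = v``
    at the velocity-evaluation cycle ``c`` so the pipeline's tangent-at-
    second-image velocity recovers v exactly; spots too fast for a solution
    (``v c / (2 ymax) >= 1/e``) are capped at the turning point ``k = 1/c``
    and flagged saturated.

    Returns ``(k, saturated)`` as arrays broadcast over the inputs.
    """
    v = np.asarray(v_true, dtype=float)
    ym = np.asarray(ymax, dtype=float)
    if np.any(ym <= 0):
        raise ValueError("plateau ymax must be > 0")
    a = v / (2.0 * ym)
    if convention == "initial_tangent":
        k = a
        saturated = np.zeros_like(k, dtype=bool)
    elif convention == "second_point":
        x = a * v_cycle
        solvable = x < np.exp(-1.0)
        k = np.where(
            solvable,
            np.real(-lambertw(-np.clip(x, 0.0, np.exp(-1.0) * (1 - 1e-12)))) / v_cycle,
            1.0 / v_cycle,
        )
        saturated = ~solvable & (v > 0)
    else:
        raise ValueError(f"unknown rate convention {convention!r}")
    # >99.9% of plateau reached within the first 2 cycles: curve shape lost.
    saturated = saturated | (-np.expm1(-2.0 * k) > 0.999)
    return k, saturated


def _exponential(cycles, y0, ymax, k):
    return y0 + ymax * -np.expm1(-np.multiply.outer(k, np.asarray(cycles, float)))


def simulate_spot(
    v_true: float,
    plateau_ymax: float,
    noise: NoiseModel,
    *,
    cycles: Sequence[int] = DEFAULT_CYCLES,
    rng: np.random.Generator | int | None = None,
    convention: str = "second_point",
    v_cycle: int = 4,
    peptide_id: str = "SPOT",
    spot_conc_uM: float = 1000.0,
    cond: RunCondition | None = None,
) -> SpotSeries:
    """Simulate one spot's progress curve at the imaged cycles."""
    if plateau_ymax <= 0:
        raise ValueError("plateau_ymax must be > 0")
    rng = np.random.default_rng(rng)
    cyc = np.asarray(cycles, dtype=int)
    if v_true > 0:
        k, sat = rate_constant(v_true, plateau_ymax, convention=convention, v_cycle=v_cycle)
        model = _exponential(cyc, 0.0, plateau_ymax, float(k))
        saturated = bool(sat)
    else:
        model = np.zeros_like(cyc, dtype=float)
        saturated = False
    bg = rng.normal(noise.bg_mean, noise.bg_sd, size=cyc.shape) if noise.bg_sd else np.full(cyc.shape, noise.bg_mean)
    eps = rng.normal(0.0, noise.sigma_add, size=cyc.shape) if noise.sigma_add else 0.0
    prop = model * rng.normal(0.0, noise.sigma_prop, size=cyc.shape) if noise.sigma_prop else 0.0
    signals = model + bg + eps + prop
    return SpotSeries(
        peptide_id=peptide_id,
        spot_conc_uM=spot_conc_uM,
        cycles=cyc,
        signals=signals,
        backgrounds=bg,
        run_condition=cond,
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# Array layouts


def _decoy_sequences(n: int, library_seed: int = 2011) -> list[str]:
    """Deterministic tyrosine-centred 13-mers used to fill the screening array."""
    rng = np.random.default_rng(library_seed)
    aas = [a for a in AMINO_ACIDS if a != "Y"]
    seqs = []
    for _ in range(n):
        flanks = rng.choice(list(aas), size=12)
        seqs.append("".join(flanks[:6]) + "Y" + "".join(flanks[6:]))
    return seqs


def screening_layout(
    n_total: int = 144, spot_conc_uM: float = 1000.0, library_seed: int = 2011
) -> list[PeptideSpec]:
    """The 144-spot screening array: 63 published peptides, synthetic decoys
    filling the remainder, plus the tyrosine-free and pre-phosphorylated
    antibody-control spots (never callable as substrates)."""
    real = load_table1().sequences
    n_decoys = n_total - len(real)
    if n_decoys < 0:
        raise ValueError(f"n_total must be >= {len(real)}")
    peptides = [
        PeptideSpec(pid, seq, spotted_concs_uM=(spot_conc_uM,))
        for pid, seq in real.items()
    ]
    peptides += [
        PeptideSpec(f"DECOY_{i:03d}", seq, spotted_concs_uM=(spot_conc_uM,))
        for i, seq in enumerate(_decoy_sequences(n_decoys, library_seed))
    ]
    peptides.append(
        PeptideSpec(
            NO_TYR_CONTROL_ID,
            "GASPAGSTAGSPA",
            spotted_concs_uM=(spot_conc_uM,),
            no_tyr_control=True,
        )
    )
    peptides.append(
        PeptideSpec(PRE_PHOSPHO_CONTROL_ID, "GASPAGYTAGSPA", spotted_concs_uM=(spot_conc_uM,))
    )
    return peptides


def custom_chip_layout(
    concs_uM: tuple[float, ...] = CUSTOM_CHIP_CONCS,
) -> list[PeptideSpec]:
    """The 24-peptide custom chip with its 6-level concentration series."""
    table2 = load_table2()
    sequences = load_table1().sequences
    peptide_ids = sorted(next(iter(table2.values())).keys())
    return [
        PeptideSpec(pid, sequences[pid], spotted_concs_uM=concs_uM)
        for pid in peptide_ids
    ]


# ---------------------------------------------------------------------------
# Run designs


def _control_conditions(construct_id: str, enzyme_pmol: float, atp_uM: float) -> list[RunCondition]:
    return [
        RunCondition(construct_id, 0.0, atp_uM, 1, "no_enzyme"),
        RunCondition(construct_id, enzyme_pmol, 0.0, 1, "no_atp"),
        RunCondition(construct_id, enzyme_pmol, atp_uM, 1, "staurosporine"),
        RunCondition(construct_id, enzyme_pmol, atp_uM, 1, "amp_pnp"),
        RunCondition(construct_id, enzyme_pmol, atp_uM, 1, "kinase_dead"),
        RunCondition(construct_id, enzyme_pmol, atp_uM, 1, "pre_activated"),
    ]


def screening_design(
    construct_id: str,
    pmol_per_reaction: float,
    *,
    atp_screen_uM: float = 100.0,
    enzyme_factors: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0),
    atp_levels_uM: Sequence[float] = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0),
    replicates: int = 3,
    include_controls: bool = True,
) -> list[RunCondition]:
    """Substrate-identification design: an enzyme titration at fixed ATP, an
    ATP titration at the working enzyme amount, and the negative controls.

    The enzyme titration spans 0 to ``2 x`` the construct's working amount
    (the published 0-8 pmol range scaled to each construct) so that strong
    substrates stay out of plateau saturation inside the titration.
    """
    conds = []
    for rep in range(1, replicates + 1):
        for f in enzyme_factors:
            conds.append(
                RunCondition(construct_id, f * pmol_per_reaction, atp_screen_uM, rep)
            )
        for atp in atp_levels_uM:
            if atp == atp_screen_uM:
                continue  # already covered at full enzyme by the titration
            conds.append(RunCondition(construct_id, pmol_per_reaction, atp, rep))
    if include_controls:
        conds += _control_conditions(construct_id, pmol_per_reaction, atp_screen_uM)
    return conds


def atp_titration_design(
    construct_id: str,
    pmol_per_reaction: float,
    *,
    atp_levels_uM: Sequence[float] = (0.0, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0),
    replicates: int = 3,
) -> list[RunCondition]:
    """Michaelis design for ATP: fixed enzyme, increasing ATP, triplicates."""
    return [
        RunCondition(construct_id, pmol_per_reaction, atp, rep)
        for rep in range(1, replicates + 1)
        for atp in atp_levels_uM
    ]


def custom_chip_design(
    profiles: Mapping[str, ConstructProfile],
    constructs: Sequence[str] = CONSTRUCTS,
    *,
    atp_uM: float = 400.0,
    replicates: int = 3,
    include_controls: bool = False,
) -> list[RunCondition]:
    """Catalytic-efficiency design: each construct at its working amount and
    400 uM ATP, in triplicate."""
    conds = []
    for cid in constructs:
        pmol = profiles[cid].pmol_per_reaction
        for rep in range(1, replicates + 1):
            conds.append(RunCondition(cid, pmol, atp_uM, rep))
        if include_controls:
            conds += _control_conditions(cid, pmol, atp_uM)
    return conds


# ---------------------------------------------------------------------------
# Experiment-level simulation


def _run_seed(master_seed: int, cond: RunCondition) -> np.random.Generator:
    crc = zlib.crc32(cond.key().encode())
    return np.random.default_rng([int(master_seed), crc])


def screen_efficiencies(
    truth: ScreenTruth | None = None,
    *,
    default: str | float = "median",
) -> dict[str, dict[str, float]]:
    """Per-construct efficiency maps realising a screen truth.

    Peptides called for a construct receive that construct's printed Vmax/Km
    where available, otherwise ``default`` (the median of the construct's
    printed column, or an explicit value).  Uncalled peptides and decoys are
    absent, i.e. zero.
    """
    truth = truth if truth is not None else load_table1()
    table2 = load_table2()
    out: dict[str, dict[str, float]] = {}
    for construct, called in truth.calls.items():
        printed = {p: r.vmax_km for p, r in table2.get(construct, {}).items()}
        if default == "median":
            fill = float(np.median(list(printed.values()))) if printed else 0.1
        else:
            fill = float(default)
        out[construct] = {p: printed.get(p, fill) for p in called}
    return out


def simulate_experiment(
    design: Iterable[RunCondition],
    layout: Sequence[PeptideSpec],
    profiles: Mapping[str, ConstructProfile] | None = None,
    noise: NoiseModel | None = None,
    *,
    master_seed: int = 0,
    efficiencies: Mapping[str, Mapping[str, float]] | None = None,
    signal_scale: float = 1.0,
    ymax_per_uM: float = DEFAULT_YMAX_PER_UM,
    km_pep_uM: float | None = None,
    cycles: Sequence[int] = DEFAULT_CYCLES,
    convention: str = "second_point",
    v_cycle: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full experiment as a long-format table of spot time series.

    Every (run condition, spot) pair appears exactly once; per-run random
    streams are derived from the master seed by stable hashing of the run
    key, so replicates are independent and the whole dataset is reproducible
    bit for bit from ``master_seed``.

    Returns ``(data, config)``: the long table (one row per spot per imaged
    cycle) and a sidecar dict capturing all ground-truth parameters,
    including the per-construct calibration constants needed to express
    recovered efficiencies in the printed relative-activity units.
    """
    profiles = profiles if profiles is not None else load_constructs()
    noise = noise if noise is not None else NoiseModel()
    design = list(design)
    keys = [c.key() for c in design]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate run conditions in design")

    spots = [
        (pep, conc) for pep in layout for conc in pep.spotted_concs_uM
    ]
    spot_ids = [p.peptide_id for p, _ in spots]
    spot_keys = {(p.peptide_id, c) for p, c in spots}
    if len(spot_keys) != len(spots):
        raise ValueError("duplicate (peptide, concentration) spots in layout")
    concs = np.array([c for _, c in spots])
    ymax = ymax_per_uM * concs
    cyc = np.asarray(cycles, dtype=int)
    n_c = len(cyc)

    frames = []
    for cond in design:
        profile = profiles[cond.construct_id]
        eff_map = None if efficiencies is None else efficiencies.get(cond.construct_id, {})
        v = np.array(
            [
                true_initial_rate(
                    profile,
                    pep.peptide_id,
                    conc,
                    cond,
                    signal_scale=signal_scale,
                    km_pep_uM=km_pep_uM,
                    efficiencies=eff_map,
                )
                for pep, conc in spots
            ]
        )
        k, saturated = rate_constant(v, ymax, convention=convention, v_cycle=v_cycle)
        model = ymax[:, None] * -np.expm1(-k[:, None] * cyc[None, :])
        model[v <= 0] = 0.0
        # pre-phosphorylated control spot: constant near-plateau signal,
        # present under every condition (antibody-detection positive control)
        for i, (pep, conc) in enumerate(spots):
            if pep.peptide_id == PRE_PHOSPHO_CONTROL_ID:
                model[i, :] = 0.8 * ymax[i]
        rng = _run_seed(master_seed, cond)
        bg = (
            rng.normal(noise.bg_mean, noise.bg_sd, size=model.shape)
            if noise.bg_sd
            else np.full(model.shape, noise.bg_mean)
        )
        signals = model + bg
        if noise.sigma_add:
            signals = signals + rng.normal(0.0, noise.sigma_add, size=model.shape)
        if noise.sigma_prop:
            signals = signals + model * rng.normal(0.0, noise.sigma_prop, size=model.shape)
        n_s = len(spots)
        frames.append(
            pd.DataFrame(
                {
                    "construct": cond.construct_id,
                    "control": cond.control_type,
                    "enzyme_pmol": cond.enzyme_pmol,
                    "atp_uM": cond.atp_uM,
                    "replicate": cond.replicate,
                    "peptide_id": np.repeat(spot_ids, n_c),
                    "conc_uM": np.repeat(concs, n_c),
                    "cycle": np.tile(cyc, n_s),
                    "signal": signals.ravel(),
                    "background": bg.ravel(),
                    "saturated": np.repeat(saturated, n_c),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)

    eff_truth = {
        cid: dict(
            (efficiencies or {}).get(cid, profiles[cid].efficiency_by_peptide)
        )
        for cid in {c.construct_id for c in design}
    }
    reference_values = {}
    for cid, eff in eff_truth.items():
        ref_eff = eff.get(REFERENCE_PEPTIDE, 0.0)
        if ref_eff > 0:
            reference_values[cid] = (
                ref_eff * REFERENCE_CONC_UM * profiles[cid].pmol_per_reaction
            )
    config = {
        "master_seed": int(master_seed),
        "noise": asdict(noise),
        "signal_scale": signal_scale,
        "ymax_per_uM": ymax_per_uM,
        "km_pep_uM": km_pep_uM,
        "cycles": [int(c) for c in cyc],
        "convention": convention,
        "v_cycle": int(v_cycle),
        "efficiencies": eff_truth,
        "km_atp_uM": {
            cid: profiles[cid].km_atp_uM for cid in eff_truth
        },
        "pmol_per_reaction": {
            cid: profiles[cid].pmol_per_reaction for cid in eff_truth
        },
        "reference_values": reference_values,
    }
    return data, config
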