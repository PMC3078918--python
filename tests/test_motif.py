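"""Efficiency-weighted substrate motifs: alignment, entropies, divergences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pamkin as pk
from pamkin.compare import pct_total
from pamkin.fixtures import AMINO_ACIDS, central_tyrosine
from pamkin.motif import (
    LOG2_20,
    align_on_central_tyr,
    compare_motifs,
    motif_to_meme,
    weighted_motif,
)


@pytest.fixture(scope="module")
def chip_alignment():
    return align_on_central_tyr(pk.custom_chip_layout())


@pytest.fixture(scope="module")
def construct_motifs(chip_alignment):
    eff = pct_total(pk.load_table2_frame())
    return {
        construct: weighted_motif(
            chip_alignment, dict(zip(grp.peptide_id, grp.pct_total))
        )
        for construct, grp in eff.groupby("construct")
    }


class TestAlignment:
    def test_reference_peptide_window(self, chip_alignment):
        assert chip_alignment.loc["STA5A_687_699"].tolist() == list("KAVDGYVKPQI")

    def test_multi_tyrosine_anchor_is_midpoint_closest(self):
        aln = align_on_central_tyr([("NTRK2_696_708", "GMSRDVYSTDYYR")])
        # anchor at position 7 of GMSRDVYSTDYYR
        assert aln.loc["NTRK2_696_708"].tolist() == list("MSRDVYSTDYY")

    def test_centred_13mer_has_no_gaps(self):
        aln = align_on_central_tyr([("P", "ACDEFGYHIKLMN")])
        assert (aln.loc["P"] != "-").all()

    def test_off_centre_anchor_pads_with_gaps(self):
        # single Tyr near the N-terminus: positions left of it are gaps
        aln = align_on_central_tyr([("P", "YVQAAAAAAAAAA")])
        row = aln.loc["P"]
        assert row.tolist() == list("----") + ["-"] + list("YVQAAA")

    def test_two_tyr_thirteen_mer_full_window(self):
        aln = align_on_central_tyr([("RON_1353_1365", "YVQLPATYMNLGP")])
        # anchor at position 8 (closest to midpoint 7); window covers 3..13
        assert aln.loc["RON_1353_1365"].tolist() == list("QLPATYMNLGP")

    def test_anchor_column_is_always_tyrosine(self, chip_alignment):
        assert (chip_alignment[0] == "Y").all()

    def test_tyrosine_free_peptides_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="no tyrosine"):
            aln = align_on_central_tyr([("GOOD", "AAAAAAYAAAAAA"), ("BAD", "AAAA")])
        assert list(aln.index) == ["GOOD"]


class TestWeightedMotif:
    def test_single_peptide_point_distributions(self):
        aln = align_on_central_tyr([("P", "ACDEFGYHIKLMN")])
        m = weighted_motif(aln, {"P": 1.0})
        for pos in m.freq.index:
            assert m.height[pos] == pytest.approx(LOG2_20)
            assert m.freq.loc[pos].max() == pytest.approx(1.0)

    def test_uniform_spread_has_zero_height(self):
        # 20 peptides differing only at +1, covering all residues uniformly
        peptides = [(f"P{i}", f"AAAAAAY{aa}AAAAA") for i, aa in enumerate(AMINO_ACIDS)]
        aln = align_on_central_tyr(peptides)
        m = weighted_motif(aln, {f"P{i}": 1.0 for i in range(20)})
        assert m.height[1] == pytest.approx(0.0, abs=1e-12)
        assert m.height[0] == pytest.approx(LOG2_20)

    def test_anchor_invariants_on_chip_motifs(self, construct_motifs):
        for m in construct_motifs.values():
            assert m.freq.loc[0, "Y"] == pytest.approx(1.0)
            assert m.height[0] == pytest.approx(LOG2_20)
            assert ((m.height >= -1e-12) & (m.height <= LOG2_20 + 1e-12)).all()

    def test_frequencies_sum_to_one_where_weighted(self, construct_motifs):
        for m in construct_motifs.values():
            occupied = m.effective_weight > 0
            np.testing.assert_allclose(m.freq[occupied.to_numpy()].sum(axis=1), 1.0)

    def test_hand_summed_position_plus_one(self, chip_alignment):
        eff = pct_total(pk.load_table2_frame())
        grp = eff[eff.construct == "JAK2_JH1"]
        weights = dict(zip(grp.peptide_id, grp.pct_total))
        m = weighted_motif(chip_alignment, weights)
        seqs = pk.load_table1().sequences
        acc: dict[str, float] = {}
        for pid, w in weights.items():
            seq = seqs[pid]
            aa = seq[central_tyrosine(seq)]  # residue at +1
            acc[aa] = acc.get(aa, 0.0) + w
        total = sum(acc.values())
        for aa, w in acc.items():
            assert m.freq.loc[1, aa] == pytest.approx(w / total, abs=1e-9)

    @given(scale=st.floats(0.001, 1000.0))
    def test_weight_scale_invariance(self, chip_alignment, scale):
        eff = pct_total(pk.load_table2_frame())
        grp = eff[eff.construct == "JAK2_JH1JH2_WT"]
        w = dict(zip(grp.peptide_id, grp.pct_total))
        a = weighted_motif(chip_alignment, w)
        b = weighted_motif(chip_alignment, {k: v * scale for k, v in w.items()})
        pd.testing.assert_frame_equal(a.freq, b.freq)
        pd.testing.assert_series_equal(a.height, b.height)

    def test_zero_weight_peptide_changes_nothing(self, chip_alignment):
        eff = pct_total(pk.load_table2_frame())
        grp = eff[eff.construct == "JAK2_JH1JH2_WT"]
        w = dict(zip(grp.peptide_id, grp.pct_total))
        full = weighted_motif(chip_alignment, {**w, "EGFR_1103_1115": 0.0})
        dropped_w = {k: v for k, v in w.items() if k != "EGFR_1103_1115"}
        dropped = weighted_motif(chip_alignment.drop("EGFR_1103_1115"), dropped_w)
        pd.testing.assert_frame_equal(full.freq, dropped.freq)

    def test_all_zero_weights_rejected(self, chip_alignment):
        with pytest.raises(ValueError, match="zero"):
            weighted_motif(chip_alignment, {"STA5A_687_699": 0.0})

    def test_unknown_weight_keys_rejected(self, chip_alignment):
        with pytest.raises(ValueError, match="absent"):
            weighted_motif(chip_alignment, {"NOT_A_PEPTIDE": 1.0})


class TestCompareMotifs:
    def test_identical_motifs_diverge_nowhere(self, construct_motifs):
        m = construct_motifs["JAK2_JH1"]
        js = compare_motifs(m, m)
        np.testing.assert_allclose(js.dropna(), 0.0, atol=1e-12)

    def test_disjoint_point_distributions_reach_one_bit(self):
        a = weighted_motif(align_on_central_tyr([("A", "AAAAAAYAAAAAA")]), {"A": 1.0})
        b = weighted_motif(align_on_central_tyr([("B", "CCCCCCYCCCCCC")]), {"B": 1.0})
        js = compare_motifs(a, b)
        assert js[-1] == pytest.approx(1.0)
        assert js[0] == pytest.approx(0.0, abs=1e-12)  # shared anchor Tyr

    def test_v617f_motif_closer_to_wt_than_jak3(self, construct_motifs):
        js_vf = compare_motifs(
            construct_motifs["JAK2_JH1JH2_WT"], construct_motifs["JAK2_JH1JH2_V617F"]
        )
        js_j3 = compare_motifs(
            construct_motifs["JAK2_JH1JH2_WT"], construct_motifs["JAK3_JH1"]
        )
        assert js_vf.max() < js_j3.max()

    def test_mismatched_ranges_rejected(self, construct_motifs):
        m = construct_motifs["JAK2_JH1"]
        truncated = pk.MotifMatrix(
            freq=m.freq.iloc[1:],
            height=m.height.iloc[1:],
            letter_height=m.letter_height.iloc[1:],
            effective_weight=m.effective_weight.iloc[1:],
        )
        with pytest.raises(ValueError, match="range"):
            compare_motifs(m, truncated)


class TestExport:
    def test_meme_matrix_rows_are_probabilities(self, construct_motifs):
        text = motif_to_meme(construct_motifs["JAK2_JH1"], name="jh1")
        lines = text.splitlines()
        assert "MOTIF jh1" in lines
        header = next(l for l in lines if l.startswith("letter-probability"))
        assert "alength= 20 w= 11" in header
        data = [l for l in lines if l.startswith(" ")]
        assert len(data) == 11
        for row in data:
            vals = np.array([float(x) for x in row.split()])
            assert vals.sum() == pytest.approx(1.0, abs=1e-4)
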