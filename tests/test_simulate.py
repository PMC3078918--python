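"""Synthetic assay generator: forward model, spot curves, experiment layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pamkin as pk
from pamkin.rates import fit_exponential
from pamkin.simulate import (
    DEFAULT_CYCLES,
    NoiseModel,
    RunCondition,
    custom_chip_design,
    custom_chip_layout,
    rate_constant,
    simulate_experiment,
    simulate_spot,
    true_initial_rate,
)


@pytest.fixture
def wt(profiles):
    return profiles["JAK2_JH1JH2_WT"]


def cond(construct="JAK2_JH1JH2_WT", pmol=1.0, atp=400.0, control="none", rep=1):
    return RunCondition(construct, pmol, atp, rep, control)


class TestForwardModel:
    def test_reference_cell_hand_value(self, wt):
        # 0.106 * 100 uM * 400/(88+400) for 1 pmol at unit signal scale
        v = true_initial_rate(wt, "STA5A_687_699", 100.0, cond())
        assert v == pytest.approx(0.106 * 100 * 400 / 488, rel=1e-12)

    @pytest.mark.parametrize(
        "control", ["staurosporine", "amp_pnp", "kinase_dead", "pre_activated"]
    )
    def test_inhibited_reactions_are_null(self, wt, control):
        assert true_initial_rate(wt, "STA5A_687_699", 1000.0, cond(control=control)) == 0

    def test_no_enzyme_and_no_atp_are_null(self, wt):
        assert true_initial_rate(wt, "STA5A_687_699", 1000.0, cond(pmol=0, control="no_enzyme")) == 0
        assert true_initial_rate(wt, "STA5A_687_699", 1000.0, cond(atp=0, control="no_atp")) == 0

    def test_atp_half_saturation_identity(self, wt):
        at_km = true_initial_rate(wt, "STA5A_687_699", 100.0, cond(atp=wt.km_atp_uM))
        at_inf = true_initial_rate(wt, "STA5A_687_699", 100.0, cond(atp=1e12))
        assert at_km == pytest.approx(at_inf / 2, rel=1e-9)

    def test_linear_in_enzyme_and_substrate(self, wt):
        v1 = true_initial_rate(wt, "STA5A_687_699", 100.0, cond(pmol=1))
        assert true_initial_rate(wt, "STA5A_687_699", 100.0, cond(pmol=3)) == pytest.approx(3 * v1)
        assert true_initial_rate(wt, "STA5A_687_699", 700.0, cond(pmol=1)) == pytest.approx(7 * v1)

    def test_unknown_peptide_is_decoy_baseline(self, wt):
        assert true_initial_rate(wt, "DECOY_001", 1000.0, cond()) == 0

    def test_negative_concentration_rejected(self, wt):
        with pytest.raises(ValueError):
            true_initial_rate(wt, "STA5A_687_699", -1.0, cond())

    def test_peptide_michaelis_saturation(self, wt):
        lin = true_initial_rate(wt, "STA5A_687_699", 1000.0, cond())
        sat = true_initial_rate(wt, "STA5A_687_699", 1000.0, cond(), km_pep_uM=1000.0)
        assert sat == pytest.approx(lin / 2, rel=1e-12)


class TestSpotSimulation:
    def test_closed_form_initial_tangent_example(self):
        # v=50/min with plateau 1000 gives k=0.025/cycle; endpoint 1000(1-e^-1.5)
        series = simulate_spot(
            50.0, 1000.0, NoiseModel.noiseless(), convention="initial_tangent", rng=0
        )
        k, sat = rate_constant(50.0, 1000.0, convention="initial_tangent")
        assert float(k) == pytest.approx(0.025)
        assert not sat
        assert series.signals[-1] == pytest.approx(1000 * (1 - np.exp(-1.5)), rel=1e-12)

    def test_null_reaction_without_noise_is_flat_zero(self):
        series = simulate_spot(0.0, 1000.0, NoiseModel.noiseless(), rng=0)
        assert np.all(series.signals == 0)
        assert np.all(series.backgrounds == 0)

    def test_second_point_convention_refits_to_true_velocity(self):
        for v_true in (2.0, 50.0, 400.0):
            series = simulate_spot(v_true, 50000.0, NoiseModel.noiseless(), rng=0)
            fit = fit_exponential(series)
            assert fit.converged
            assert fit.v == pytest.approx(v_true, rel=1e-6)

    def test_noiseless_refit_recovers_generating_parameters(self):
        series = simulate_spot(
            50.0, 1000.0, NoiseModel.noiseless(), convention="initial_tangent", rng=0
        )
        fit = fit_exponential(series)
        assert fit.ymax == pytest.approx(1000.0, rel=1e-6)
        assert fit.k == pytest.approx(0.025, rel=1e-6)
        assert abs(fit.y0) < 1e-6 * 1000

    def test_backgrounds_average_to_bg_mean(self):
        noise = NoiseModel(sigma_add=0, sigma_prop=0, bg_mean=120.0, bg_sd=8.0)
        bgs = [
            simulate_spot(0.0, 100.0, noise, rng=i).backgrounds.mean() for i in range(40)
        ]
        assert np.mean(bgs) == pytest.approx(120.0, abs=1.0)

    def test_too_fast_spot_flagged_saturated(self):
        series = simulate_spot(1e6, 100.0, NoiseModel.noiseless(), rng=0)
        assert series.saturated

    def test_invalid_plateau_rejected(self):
        with pytest.raises(ValueError):
            simulate_spot(10.0, 0.0, NoiseModel.noiseless())

    @given(
        v=st.floats(0.5, 200.0),
        ymax=st.floats(5e3, 5e5),
    )
    def test_rate_constant_inverts_second_point_tangent(self, v, ymax):
        k, sat = rate_constant(v, ymax, convention="second_point", v_cycle=4)
        assert not sat
        assert 2 * ymax * float(k) * np.exp(-4 * float(k)) == pytest.approx(v, rel=1e-9)


class TestExperiment:
    def test_custom_chip_dimensions(self, chip_noiseless):
        data, _ = chip_noiseless
        # 24 peptides x 6 concentrations x 30 images per run
        one = data[
            (data.construct == "JAK2_JH1JH2_WT") & (data.replicate == 1)
        ]
        assert one.peptide_id.nunique() == 24
        assert one.conc_uM.nunique() == 6
        assert sorted(one.cycle.unique()) == list(DEFAULT_CYCLES)
        assert len(one) == 24 * 6 * 30

    def test_same_master_seed_is_bit_identical(self, profiles):
        design = custom_chip_design(profiles, ("JAK2_JH1JH2_WT",), replicates=1)
        layout = custom_chip_layout()[:4]
        a, _ = simulate_experiment(design, layout, profiles, NoiseModel(), master_seed=7)
        b, _ = simulate_experiment(design, layout, profiles, NoiseModel(), master_seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_different_replicates_use_distinct_noise(self, profiles):
        design = custom_chip_design(profiles, ("JAK2_JH1JH2_WT",), replicates=2)
        layout = custom_chip_layout()[:4]
        data, _ = simulate_experiment(design, layout, profiles, NoiseModel(), master_seed=7)
        r1 = data[data.replicate == 1].signal.to_numpy()
        r2 = data[data.replicate == 2].signal.to_numpy()
        assert not np.allclose(r1, r2)

    def test_duplicate_conditions_rejected(self, profiles):
        c = RunCondition("JAK2_JH1JH2_WT", 2.0, 400.0, 1)
        with pytest.raises(ValueError, match="duplicate"):
            simulate_experiment([c, c], custom_chip_layout()[:2], profiles, NoiseModel())

    def test_control_runs_carry_no_substrate_signal(self, profiles):
        design = custom_chip_design(
            profiles, ("JAK2_JH1JH2_WT",), replicates=1, include_controls=True
        )
        layout = [p for p in custom_chip_layout() if p.peptide_id == "STA5A_687_699"]
        data, _ = simulate_experiment(
            design, layout, profiles, NoiseModel.noiseless(), master_seed=0
        )
        controls = data[data.control != "none"]
        assert len(controls) > 0
        assert np.all(controls.signal.to_numpy() == 0)

    def test_endpoint_monotone_in_enzyme_and_atp(self, profiles, wt):
        layout = [p for p in custom_chip_layout() if p.peptide_id == "STA5A_687_699"]
        design = [cond(pmol=p, atp=a, rep=1) for p, a in
                  [(0.5, 400), (1, 400), (2, 400), (2, 50), (2, 100), (2, 200)]]
        data, _ = simulate_experiment(
            design, layout, profiles, NoiseModel.noiseless(), master_seed=0
        )
        end = data[(data.cycle == 60) & (data.conc_uM == 1000.0)]
        by_pmol = end[end.atp_uM == 400].sort_values("enzyme_pmol").signal.to_numpy()
        by_atp = end[end.enzyme_pmol == 2].sort_values("atp_uM").signal.to_numpy()
        assert np.all(np.diff(by_pmol) >= 0)
        assert np.all(np.diff(by_atp) >= 0)

    def test_default_model_exactly_first_order_in_substrate(self, wt):
        concs = np.array([10.0, 50.0, 100.0, 500.0, 1000.0])
        ratios = [
            true_initial_rate(wt, "STA5A_687_699", c, cond()) / c for c in concs
        ]
        assert np.ptp(ratios) <= 1e-3 * ratios[0]
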