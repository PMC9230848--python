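"""Sorption-kinetics machinery: Crank series, Maxwell-Stefan mixing, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asdsorption import dvs, kinetics
from asdsorption.kinetics import (
    FilmGeometry,
    crank_fractional_uptake,
    crank_profile,
    fickian_from_ms,
    fit_fickian_d,
    interp_ms_diffusivity,
    mix_ms_diffusivity,
    predict_sorption_experiment,
    segmental_from_molecular,
    system_thermodynamic_factor,
    thermodynamic_factor,
    thickness_correction,
)

T = 298.15


class TestCrank:
    def test_initial_and_final_values(self):
        t = np.array([0.0, 1e9])
        mw = crank_profile(1e-6, 5e-6, 2e-14, 8e-6, t)
        # 20-term truncation leaves ~1% of the amplitude at t = 0
        assert mw[0] == pytest.approx(1e-6, abs=0.011 * 4e-6)
        assert mw[-1] == pytest.approx(5e-6, rel=1e-12)
        # with 10x the terms the t = 0 truncation shrinks by 10x
        mw200 = crank_profile(1e-6, 5e-6, 2e-14, 8e-6, t, n_terms=200)
        assert mw200[0] == pytest.approx(1e-6, abs=1.1e-3 * 4e-6)

    def test_fractional_uptake_at_unit_tau(self):
        # frozen from a direct numeric evaluation of the series
        assert crank_fractional_uptake(np.array([1.0]))[0] == pytest.approx(
            0.9312597, abs=1e-6
        )

    def test_strictly_increasing(self):
        t = np.linspace(0, 5000, 50)[1:]
        mw = crank_profile(0.0, 1e-5, 2e-14, 8e-6, t)
        assert np.all(np.diff(mw) > 0)

    def test_scale_invariance(self):
        t = np.linspace(0, 3000, 20)
        base = crank_profile(0.0, 1e-5, 2e-14, 8e-6, t)
        c = 4.0
        scaled = crank_profile(0.0, 1e-5, c * 2e-14, math.sqrt(c) * 8e-6, t)
        np.testing.assert_allclose(base, scaled, rtol=1e-12)

    def test_matches_pde_oracle(self):
        from oracle_pcsaft import pde_fractional_uptake

        taus = np.array([0.02, 0.1, 0.3, 1.0])
        crank = crank_fractional_uptake(taus)
        pde = pde_fractional_uptake(taus, nx=300, dt=1e-4)
        assert np.abs(crank - pde).max() < 1e-3


class TestInterpolation:
    def test_exact_node_value(self, registry):
        table = registry.ms_tables["ind"]
        assert interp_ms_diffusivity(table, 0.05414) == 44.8648e-15

    def test_midpoint_is_arithmetic_mean(self, registry):
        table = registry.ms_tables["ind"]
        mid = 0.5 * (table.psi[0] + table.psi[1])
        expected = 0.5 * (table.d_seg[0] + table.d_seg[1])
        assert interp_ms_diffusivity(table, mid) == pytest.approx(expected, rel=1e-12)

    def test_clamps_with_warning(self, registry):
        table = registry.ms_tables["ind"]
        with pytest.warns(UserWarning, match="clamping"):
            low = interp_ms_diffusivity(table, 0.001)
        assert low == table.d_seg[0]


class TestSegmentalConversion:
    def test_dilute_limit_identity(self):
        assert segmental_from_molecular(1e-14, 0.0, 18.02, 357.79) == 1e-14

    def test_water_in_ind_factor(self):
        d = segmental_from_molecular(1.0, 0.02, 18.02, 357.79)
        assert d == pytest.approx(0.726, abs=0.001)

    def test_factor_below_one_for_heavier_host(self):
        for ww in (0.01, 0.1, 0.3):
            assert segmental_from_molecular(1.0, ww, 18.02, 357.79) < 1.0


class TestMixing:
    def test_neat_limits(self):
        assert mix_ms_diffusivity(0.0, 5e-14, 3e-13) == 3e-13
        assert mix_ms_diffusivity(1.0, 5e-14, 3e-13) == 5e-14

    def test_equal_inputs(self):
        assert mix_ms_diffusivity(0.37, 7e-14, 7e-14) == pytest.approx(7e-14, rel=1e-12)

    def test_table_node_arithmetic(self):
        d = mix_ms_diffusivity(0.5, 44.8648e-15, 340.7e-15)
        assert d == pytest.approx(79.3e-15, rel=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        w=st.floats(0.0, 1.0),
        da=st.floats(1e-16, 1e-12),
        dp=st.floats(1e-16, 1e-12),
    )
    def test_betweenness(self, w, da, dp):
        d = mix_ms_diffusivity(w, da, dp)
        assert min(da, dp) * (1 - 1e-12) <= d <= max(da, dp) * (1 + 1e-12)


class TestThermodynamicFactor:
    def test_henry_behaviour_gives_one(self):
        gamma = thermodynamic_factor(lambda w: math.log(5.0 * w), 0.1)
        assert gamma == pytest.approx(1.0, rel=1e-6)

    def test_quadratic_gives_two(self):
        gamma = thermodynamic_factor(lambda w: math.log(5.0 * w * w), 0.1)
        assert gamma == pytest.approx(2.0, rel=1e-6)

    def test_edge_uses_one_sided_difference(self):
        with pytest.warns(UserWarning, match="one-sided"):
            thermodynamic_factor(lambda w: math.log(w), 1e-5, rel_step=10.0)

    def test_step_halving_stability_on_polymer_system(self, pvpva_system):
        g1 = system_thermodynamic_factor(pvpva_system, T, 0.1, "NE", 0.6, rel_step=1e-4)
        g2 = system_thermodynamic_factor(pvpva_system, T, 0.1, "NE", 0.6, rel_step=5e-5)
        assert g1 == pytest.approx(g2, rel=1e-4)
        assert g1 > 0


class TestThicknessCorrection:
    def test_dry_film_is_unity(self, film):
        assert thickness_correction(film, 0.0) == 1.0

    def test_hand_arithmetic(self):
        f = FilmGeometry.from_thickness(8e-6, 1250.0)
        ratio = 1.0 + (0.1 / 0.9) * 1250.0 / 997.0
        assert thickness_correction(f, 0.1) == pytest.approx(ratio**-2, rel=1e-12)
        assert thickness_correction(f, 0.1, flux_reduction=False) == pytest.approx(
            ratio**2, rel=1e-12
        )

    def test_monotone_decreasing_in_ww(self, film):
        vals = [thickness_correction(film, w) for w in np.linspace(0, 0.4, 9)]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestFickianComposition:
    def test_ideal_dilute_limit(self):
        assert fickian_from_ms(1.0, 1.0, 7e-14) == 7e-14

    def test_linear_in_gamma_and_round_trip(self):
        d = fickian_from_ms(0.9, 1.4, 7e-14)
        assert fickian_from_ms(0.9, 2.8, 7e-14) == pytest.approx(2 * d, rel=1e-12)
        assert d / (0.9 * 1.4) == pytest.approx(7e-14, rel=1e-12)


class TestFitting:
    def test_noise_free_recovery_within_one_percent(self, film):
        spec = dvs.SyntheticExperimentSpec(
            rh_schedule=[0.3], film=film, ww_end=[0.03], d_w=[20e-15]
        )
        trace, _ = dvs.generate_experiment(spec)
        step = _single_step(trace, film)
        fit = fit_fickian_d(step)
        assert fit.d_w == pytest.approx(20e-15, rel=0.01)
        assert not fit.sigmoidal
        # fit-then-simulate closes on the input trace
        model = crank_profile(
            step.water_mass[0], step.water_mass[-1], fit.d_w, film.dry_thickness,
            step.times,
        )
        assert np.abs(model - step.water_mass).max() < 0.02 * step.water_mass[-1]

    def test_confidence_interval_brackets_truth_on_noisy_data(self, film):
        spec = dvs.SyntheticExperimentSpec(
            rh_schedule=[0.3], film=film, ww_end=[0.03], d_w=[20e-15],
            noise_sigma=0.01, seed=11,
        )
        trace, _ = dvs.generate_experiment(spec)
        fit = fit_fickian_d(_single_step(trace, film))
        assert fit.ci_low < 20e-15 < fit.ci_high

    def test_zero_amplitude_rejected(self, film):
        step = kinetics.SorptionStep(
            rh_start=0.0, rh_end=0.0, times=np.arange(20.0) + 0.0,
            water_mass=np.zeros(20), film=film,
        )
        step.times = np.arange(20.0)
        with pytest.raises(ValueError, match="amplitude"):
            fit_fickian_d(step)


def _single_step(trace, film):
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "t.csv"
        trace.to_csv(p, index=False)
        return dvs.read_dvs_trace(p, film.dry_density)[0]


class TestExperimentPrediction:
    def test_degenerate_zero_step_is_flat(self, pvpva_ind_50, film, registry):
        preds = predict_sorption_experiment(pvpva_ind_50, T, [0.0], film, registry)
        assert len(preds) == 1
        assert preds[0].ww_end == 0.0
        assert np.all(preds[0].water_mass == 0.0)

    def test_six_step_schedule_consistency(self, pvpva_ind_50, film, registry):
        """Endpoints chain across steps; the mixed diffusivity lies between
        the polymer and API values at the same plasticization factor."""
        with pytest.warns(UserWarning):  # first step sits below the Psi table
            preds = predict_sorption_experiment(
                pvpva_ind_50, T, registry.rh_schedule, film, registry
            )
        assert len(preds) == 6
        for prev, cur in zip(preds, preds[1:]):
            assert cur.ww_start == prev.ww_end
        for p in preds:
            assert p.ww_end > p.ww_start
            lo = min(p.d_seg_api, p.d_seg_polymer)
            hi = max(p.d_seg_api, p.d_seg_polymer)
            assert lo <= p.d_seg <= hi
            assert p.d_fick == pytest.approx(
                p.omega0_sq * p.gamma_w * p.d_seg, rel=1e-12
            )
            assert 0 < p.omega0_sq <= 1
            assert p.gamma_w > 0
            # per-step evaluation composition follows the 0.3/0.7 rule
            assert p.ww_eval == pytest.approx(
                0.3 * p.ww_start + 0.7 * p.ww_end, rel=1e-12
            )


class TestGordonTaylorAcrossSystems:
    def test_tg_strictly_decreasing_in_ww(self, registry):
        from asdsorption.isotherm import SorptionSystem
        from asdsorption.netgp import DryASDSpec

        systems = [
            DryASDSpec(polymer="pvp", drug_load=0.0),
            DryASDSpec(polymer="pvpva", drug_load=0.0),
            DryASDSpec(polymer="pvp", api="ind", drug_load=0.5),
            DryASDSpec(polymer="pvpva", api="ind", drug_load=0.5),
        ]
        for spec in systems:
            s = SorptionSystem(registry, spec)
            tgs = [s.tg(w) for w in np.linspace(0.0, 0.3, 10)]
            assert all(b < a for a, b in zip(tgs, tgs[1:]))
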