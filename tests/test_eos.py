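"""Equation-of-state correctness: limits, derivatives, oracles, solvers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asdsorption.components import BinaryInteraction, MixtureSpec, PureComponent
from asdsorption.constants import ANGSTROM3_TO_M3, KB
from asdsorption.eos import PcSaft

from oracle_pcsaft import oracle_from_mixture

T = 298.15


def liquid_like_density(eos, x, eta=0.4):
    return eos._eta_to_rho(T, np.asarray(x, dtype=float), eta)


class TestIdealGasLimit:
    def test_helmholtz_and_z_vanish(self, ternary_mixture):
        eos = PcSaft(ternary_mixture)
        x = np.array([0.3, 1e-5, 0.69999])
        x = x / x.sum()
        rho = liquid_like_density(eos, x) * 1e-8
        res = eos.helmholtz(T, rho, x)
        assert abs(res.ares) < 1e-6
        assert abs(res.hc) < 1e-6 and abs(res.disp) < 1e-6 and abs(res.assoc) < 1e-6
        assert abs(eos.compressibility(T, rho, x) - 1.0) < 1e-6

    def test_fugacity_approaches_partial_pressure(self, water_eos):
        x = np.array([1.0])
        rho = 1e-12  # far into the dilute-gas regime
        p = rho * ANGSTROM3_TO_M3 * KB * T
        lnf = water_eos.ln_fugacity(T, rho, x)[0]
        assert math.exp(lnf) == pytest.approx(p, rel=1e-6)


class TestOracleAgreement:
    @pytest.mark.parametrize(
        "names,x,eta",
        [
            (("water",), (1.0,), 0.45),
            (("water", "ind"), (0.4, 0.6), 0.35),
            (("water", "pvp", "ind"), (0.3, 1e-5, 0.69999), 0.4),
        ],
    )
    def test_term_by_term(self, registry, names, x, eta):
        """Each Helmholtz term matches a literal transcription of the sums."""
        mix = registry.mixture(*names)
        eos = PcSaft(mix)
        x = np.asarray(x) / np.sum(x)
        rho = liquid_like_density(eos, x, eta)
        res = eos.helmholtz(T, rho, x)
        hc, disp, assoc = oracle_from_mixture(mix, T, rho, x)
        assert res.hc == pytest.approx(hc, rel=1e-10)
        assert res.disp == pytest.approx(disp, rel=1e-10)
        assert res.assoc == pytest.approx(assoc, rel=1e-8, abs=1e-12)

    def test_no_association_energy_means_no_association(self):
        """Sites with zero association energy contribute nothing at all."""
        a = PureComponent(
            name="a", molar_mass=100.0, segment_ratio=0.03, segment_diameter=3.0,
            dispersion_energy=250.0, assoc_energy=0.0, assoc_volume=0.02,
            assoc_sites=(5, 5),
        )
        b = a.model_copy(update={"name": "b"})
        eos = PcSaft(MixtureSpec(components=(a, b)))
        res = eos.helmholtz(T, 1e-3, np.array([0.5, 0.5]))
        assert res.assoc == 0.0


class TestDerivatives:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        eta=st.floats(1e-4, 0.55),
        t=st.floats(278.0, 420.0),
        a=st.floats(0.05, 0.9),
        b=st.floats(1e-6, 1e-4),
    )
    def test_analytic_matches_central_differences(self, registry, eta, t, a, b):
        """Analytic rho~ and x_k derivatives agree with finite differences."""
        mix = registry.mixture("water", "pvp", "ind")
        eos = PcSaft(mix)
        x = np.array([a, b, max(1.0 - a - b, 1e-4)])
        x = x / x.sum()
        rho = eos._eta_to_rho(t, x, eta)
        res = eos.helmholtz(t, rho, x)
        h = rho * 1e-6
        fd = (eos.helmholtz(t, rho + h, x).ares - eos.helmholtz(t, rho - h, x).ares) / (2 * h)
        assert res.dares_drho == pytest.approx(fd, rel=1e-6)
        for k in range(3):
            hx = max(x[k] * 1e-4, 1e-8)
            xp, xm = x.copy(), x.copy()
            xp[k] += hx
            xm[k] -= hx
            fdx = (eos.helmholtz(t, rho, xp).ares - eos.helmholtz(t, rho, xm).ares) / (2 * hx)
            assert res.dares_dx[k] == pytest.approx(fdx, rel=1e-6, abs=1e-10)

    def test_gibbs_duhem(self, registry):
        """sum_i x_i dln f_i/dx_w at fixed T, p vanishes on a water-IND state."""
        mix = registry.mixture("water", "ind")
        eos = PcSaft(mix)
        p = 3000.0

        def lnf(xw):
            x = np.array([xw, 1.0 - xw])
            st_ = eos.solve_density(T, p, x, "liquid")
            return eos.ln_fugacity(T, st_.number_density, x)

        xw, h = 0.3, 1e-6
        d = (lnf(xw + h) - lnf(xw - h)) / (2 * h)
        assert abs(np.array([xw, 1.0 - xw]) @ d) < 1e-6


class TestSymmetry:
    def test_component_permutation_permutes_outputs(self, registry):
        mix = registry.mixture("water", "ind")
        mix_rev = registry.mixture("ind", "water")
        x = np.array([0.3, 0.7])
        rho = liquid_like_density(PcSaft(mix), x, 0.35)
        f = PcSaft(mix).ln_fugacity(T, rho, x)
        f_rev = PcSaft(mix_rev).ln_fugacity(T, rho, x[::-1])
        np.testing.assert_allclose(f, f_rev[::-1], rtol=1e-12)

    def test_identical_components_have_identical_fugacity(self):
        a = PureComponent(name="a", molar_mass=50.0, segment_ratio=0.04,
                          segment_diameter=3.2, dispersion_energy=230.0)
        b = a.model_copy(update={"name": "b"})
        eos = PcSaft(MixtureSpec(components=(a, b)))
        x = np.array([0.5, 0.5])
        rho = liquid_like_density(eos, x, 0.3)
        f = eos.ln_fugacity(T, rho, x)
        assert f[0] == pytest.approx(f[1], rel=1e-12)

    def test_kij_zero_entry_equals_no_entry(self, registry):
        """An explicit kij = 0 reproduces the geometric-mean dispersion energy."""
        base = registry.mixture("water", "ind")
        no_kij = MixtureSpec(components=base.components)
        zero_kij = MixtureSpec(
            components=base.components,
            binaries=(BinaryInteraction(pair=("water", "ind")),),
        )
        x = np.array([0.4, 0.6])
        rho = liquid_like_density(PcSaft(no_kij), x, 0.35)
        r1 = PcSaft(no_kij).helmholtz(T, rho, x)
        r2 = PcSaft(zero_kij).helmholtz(T, rho, x)
        assert r1.disp == r2.disp


class TestDensitySolver:
    def test_water_liquid_density(self, water_eos, registry):
        """The liquid root at ambient conditions sits near the real density."""
        state = water_eos.solve_density(T, 1e5, np.array([1.0]), "liquid")
        M = registry.components["water"].molar_mass
        rho_mass = state.number_density * ANGSTROM3_TO_M3 / 6.02214076e23 * M / 1000.0
        assert rho_mass == pytest.approx(997.0, rel=0.03)

    def test_vapor_near_ideal(self, water_eos):
        state = water_eos.solve_density(T, 100.0, np.array([1.0]), "vapor")
        rho_ideal = 100.0 / (KB * T) / ANGSTROM3_TO_M3
        assert state.number_density == pytest.approx(rho_ideal, rel=0.01)

    def test_pressure_round_trip(self, water_eos):
        state = water_eos.solve_density(T, 1e5, np.array([1.0]), "liquid")
        p = water_eos.pressure(T, state.number_density, np.array([1.0]))
        assert p == pytest.approx(1e5, rel=1e-8)

    def test_dense_scan_locates_same_root(self, water_eos):
        """Brute-force scan oracle for the liquid root."""
        x = np.array([1.0])
        state = water_eos.solve_density(T, 1e5, x, "liquid")
        etas = np.linspace(0.3, 0.6, 20001)
        rhos = water_eos._eta_to_rho(T, x, etas)
        vals = np.array([water_eos.pressure(T, r, x) - 1e5 for r in rhos])
        sign_flips = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
        candidates = 0.5 * (rhos[sign_flips] + rhos[sign_flips + 1])
        assert np.min(np.abs(candidates / state.number_density - 1.0)) < 1e-4


class TestSaturation:
    def test_isofugacity_defining_property(self, water_eos):
        psat, rho_l, rho_v = water_eos.saturation_pressure(T)
        x = np.array([1.0])
        dlnf = (water_eos.ln_fugacity(T, rho_l, x)[0]
                - water_eos.ln_fugacity(T, rho_v, x)[0])
        assert abs(dlnf) < 1e-10

    def test_against_bisection_oracle_and_literature_band(self, water_eos):
        """Independent pressure bisection reproduces the solver; value ~3.17 kPa."""
        x = np.array([1.0])

        def dlnf(p):
            liq = water_eos.solve_density(T, p, x, "liquid")
            vap = water_eos.solve_density(T, p, x, "vapor")
            return (water_eos.ln_fugacity(T, liq.number_density, x)[0]
                    - water_eos.ln_fugacity(T, vap.number_density, x)[0])

        lo, hi = 1000.0, 10000.0
        assert dlnf(lo) > 0 > dlnf(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if dlnf(mid) > 0:
                lo = mid
            else:
                hi = mid
        oracle = 0.5 * (lo + hi)
        psat, _, _ = water_eos.saturation_pressure(T)
        assert psat == pytest.approx(oracle, rel=1e-9)
        assert psat == pytest.approx(3170.0, rel=0.05)

    def test_monotone_in_temperature(self, water_eos):
        assert (water_eos.saturation_pressure(303.15)[0]
                > water_eos.saturation_pressure(298.15)[0])
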