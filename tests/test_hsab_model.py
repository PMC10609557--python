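import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aunphsab import (
    ConfigurationError,
    GoldSurface,
    InvalidInputError,
    KCAL_PER_EV,
    LigandDescriptors,
    aunp_hardness,
    bind,
    binding_curve,
    binding_np,
    binding_plane,
    binding_small_r_limit,
    site_resolved_interaction,
)
from aunphsab.hsab_model import _plane_ev


class TestBindingPlane:
    def test_thiogenistein(self, table1):
        assert round(binding_plane(table1["thiogenistein"]), 1) == -21.2

    def test_thioabiraterone(self, table1):
        assert round(binding_plane(table1["thioabiraterone"]), 1) == -23.0

    def test_equal_chemical_potentials(self):
        lig = LigandDescriptors("matched", mu=-5.77, eta=3.0)
        assert binding_plane(lig) == 0.0

    def test_oracle_equivalence(self, table1, plane):
        # Independent brute-force evaluation of the quadratic, in eV.
        for lig in table1:
            oracle_ev = -((lig.mu - (-5.77)) ** 2) / (2.0 * lig.eta)
            assert _plane_ev(lig, plane) == pytest.approx(oracle_ev, abs=1e-12)

    @given(mu=st.floats(-10, 0), eta=st.floats(0.01, 20))
    def test_never_positive(self, mu, eta):
        assert binding_plane(LigandDescriptors("x", mu, eta)) <= 0.0


class TestAunpHardness:
    def test_coulomb_constant_definition(self):
        assert aunp_hardness(14.3996454, 1.0) == pytest.approx(1.0)

    def test_planar_limit(self):
        assert aunp_hardness(math.inf, 2.0) == 0.0

    def test_calibrated_contact_value(self):
        assert aunp_hardness(2.88, 4.349) == pytest.approx(1.1497, abs=5e-5)

    @pytest.mark.parametrize("r,alpha", [(-1.0, 1.0), (0.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_inputs(self, r, alpha):
        with pytest.raises(InvalidInputError):
            aunp_hardness(r, alpha)


class TestBindingNp:
    def test_thioabiraterone_held_out(self, table1, np_surface):
        # Prediction from the two-point calibration, never fitted on this row.
        assert round(binding_np(table1["thioabiraterone"], np_surface), 1) == -27.6

    def test_planar_limit_large_radius(self, table1, np_surface):
        for lig in table1:
            far = binding_np(lig, np_surface.at_radius(1e12))
            assert far == pytest.approx(binding_plane(lig), abs=1e-6)

    def test_small_radius_closed_form(self, table1):
        surf = GoldSurface(r=1e-9, alpha=4.349, ne2=1.0)
        lig = table1["methanethiol"]
        assert binding_np(lig, surf) == pytest.approx(-62.49, abs=0.01)
        assert binding_np(lig, surf) == pytest.approx(
            binding_small_r_limit(lig, 1.0), rel=1e-6
        )

    def test_uncalibrated_surface_rejected(self, table1):
        with pytest.raises(ConfigurationError):
            binding_np(table1["acetate"], GoldSurface(r=2.88))
        with pytest.raises(ConfigurationError):
            binding_np(table1["acetate"], GoldSurface(r=2.88, alpha=4.349))

    def test_limits_at_extreme_radii(self, table1, np_surface):
        # lim r->inf = planar value; lim r->0 = -ne2*eta/2, both at 1e+-6 A.
        # Convergence is O(1/r), so the residual at these radii is a few 1e-6
        # relative for the weakest binders; 1e-5 bounds every fixture row.
        for lig in table1:
            hi = binding_np(lig, np_surface.at_radius(1e6))
            lo = binding_np(lig, np_surface.at_radius(1e-6))
            assert hi == pytest.approx(binding_plane(lig), rel=1e-5)
            assert lo == pytest.approx(
                binding_small_r_limit(lig, np_surface.ne2), rel=1e-5
            )

    def test_first_order_consistency(self, table1, np_surface):
        # Expanding the rational form to first order in k (via sympy)
        # must reproduce the truncated-expansion value at f = 1.
        import sympy

        lig = table1["thioabiraterone"]
        k = sympy.Symbol("k")
        d = _plane_ev(lig, np_surface)
        rational = (d - np_surface.ne2 * k / 2) / (k / lig.eta + 1)
        first_order = sympy.series(rational, k, 0, 2).removeO()
        k0 = np_surface.eta_b
        with_fukui = LigandDescriptors(lig.name, lig.mu, lig.eta, fukui=np.array([1.0]))
        eq7 = site_resolved_interaction(with_fukui, np_surface, "large_r_expansion")[0]
        assert float(first_order.subs(k, k0)) * KCAL_PER_EV == pytest.approx(eq7, abs=1e-9)


class TestBindingSmallRLimit:
    def test_zero_effective_electrons(self, table1):
        assert binding_small_r_limit(table1["methanethiol"], 0.0) == 0.0

    def test_methanethiol(self, table1):
        assert binding_small_r_limit(table1["methanethiol"], 1.0) == pytest.approx(
            -62.49, abs=0.01
        )

    def test_citrate3(self, table1):
        assert binding_small_r_limit(table1["citrate(COO−)3"], 1.0) == pytest.approx(
            -80.14, abs=0.01
        )

    def test_exact_formula_in_ev(self, table1, np_surface):
        for lig in table1:
            res = bind(lig, np_surface)
            assert res.dE_0_ev == -np_surface.ne2 * lig.eta / 2.0


class TestSiteResolved:
    def test_zero_fukui_weight_pure_surface_term(self, np_surface):
        lig = LigandDescriptors("x", -2.5, 5.0, fukui=np.array([0.0, 1.0]))
        vals = site_resolved_interaction(lig, np_surface, "large_r_expansion")
        k = np_surface.eta_b
        assert vals[0] == pytest.approx(-k * np_surface.ne2 / 2.0 * KCAL_PER_EV)

    def test_whole_molecule_first_order_identity(self, table1, np_surface):
        lig0 = table1["thioabiraterone"]
        lig = LigandDescriptors(lig0.name, lig0.mu, lig0.eta, fukui=np.array([1.0]))
        val = site_resolved_interaction(lig, np_surface, "large_r_expansion")[0]
        k = np_surface.eta_b
        expected = binding_plane(lig) - k * (
            np_surface.ne2 / 2.0 + _plane_ev(lig, np_surface) / lig.eta
        ) * KCAL_PER_EV
        assert val == pytest.approx(expected, abs=1e-9)

    def test_thioabiraterone_truncated_value(self, table1, np_surface):
        # Frozen from direct evaluation of the truncated expansion with the
        # two-point-calibrated parameters; differs from the full rational
        # form's -27.6 because the O(1/r^2) remainder is dropped.
        lig0 = table1["thioabiraterone"]
        lig = LigandDescriptors(lig0.name, lig0.mu, lig0.eta, fukui=np.array([1.0]))
        val = site_resolved_interaction(lig, np_surface, "large_r_expansion")[0]
        assert val == pytest.approx(-29.0925, abs=5e-4)

    def test_finite_eta_b_mode_hand_formula(self, np_surface):
        lig = LigandDescriptors("x", -3.0, 4.0, fukui=np.array([0.3, 0.7]))
        eta_b = 1.2
        vals = site_resolved_interaction(lig, np_surface, "finite_eta_B", eta_b=eta_b)
        gap2 = (lig.mu - np_surface.mu_g) ** 2
        for f, v in zip(lig.fukui, vals):
            t1 = -0.5 * (f / lig.eta) * gap2
            t2 = 0.5 * np_surface.ne2 * eta_b / (f * eta_b / lig.eta + 1.0)
            assert v == pytest.approx((t1 + t2) * KCAL_PER_EV)

    def test_missing_fukui_rejected(self, table1, np_surface):
        with pytest.raises(InvalidInputError):
            site_resolved_interaction(table1["acetate"], np_surface)


class TestBindingCurve:
    def test_single_point_matches_binding_np(self, table1, np_surface):
        lig = table1["thioabiraterone"]
        df = binding_curve(lig, np_surface, [2.88])
        assert df["dE_kcal"].iloc[0] == pytest.approx(binding_np(lig, np_surface))

    def test_endpoints_bracket_limits(self, table1, np_surface):
        lig = table1["thioabiraterone"]
        df = binding_curve(lig, np_surface, [0.01, 1e6])
        de0 = binding_small_r_limit(lig, np_surface.ne2)
        dinf = binding_plane(lig)
        assert df["dE_kcal"].iloc[0] == pytest.approx(de0, rel=0.01)
        assert df["dE_kcal"].iloc[-1] == pytest.approx(dinf, rel=0.01)

    def test_monotone_nondecreasing_for_fixture_ligands(self, table1, two_point_cal):
        # With ne2 = 1 every fixture ligand has eta > |mu - mu_G|, so dE(r)
        # rises from dE_0 toward dE(inf).
        surf = GoldSurface(r=2.88, alpha=two_point_cal.alpha, ne2=1.0)
        grid = np.geomspace(0.1, 1e4, 200)
        for lig in table1:
            de = binding_curve(lig, surf, grid)["dE_kcal"].to_numpy()
            assert np.all(np.diff(de) >= -1e-12)

    @pytest.mark.parametrize("grid", [[], [-1.0, 2.0], [3.0, 1.0]])
    def test_bad_grids_rejected(self, table1, np_surface, grid):
        with pytest.raises(InvalidInputError):
            binding_curve(table1["acetate"], np_surface, grid)


class TestGoldSurface:
    def test_invalid_parameters(self):
        with pytest.raises(InvalidInputError):
            GoldSurface(r=-2.0)
        with pytest.raises(InvalidInputError):
            GoldSurface(alpha=-1.0)
        with pytest.raises(InvalidInputError):
            GoldSurface(ne2=0.0)

    def test_bind_planar_has_no_finite_r_value(self, table1):
        res = bind(table1["acetate"], GoldSurface())
        assert res.dE_r is None
        assert res.dE_inf <= 0.0
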