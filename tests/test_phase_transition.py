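"""Mixed-phase extension, inversion force, inverse inference and geometry."""

import math

import numpy as np
import pytest

from bldna.core_model import PhaseParams, wlc_extension
from bldna.phase_transition import (
    DegeneratePhasesError,
    HelixGeometry,
    ModelConfig,
    RegimeRangeError,
    bl_slope,
    compatibility_region,
    contour_ratio_from_sigma,
    default_config,
    inversion_force,
    l_fraction,
    lpl_from_inversion,
    mixed_extension,
)


class TestLFraction:
    def test_endpoints(self, wt_config):
        assert l_fraction(wt_config.n_b_max, wt_config) == 0.0
        assert l_fraction(wt_config.n_t_max, wt_config) == 1.0

    def test_midpoint_linearity(self, wt_config):
        mid = 0.5 * (wt_config.n_b_max + wt_config.n_t_max)
        assert l_fraction(mid, wt_config) == pytest.approx(0.5, rel=1e-12)

    def test_range_errors_name_regime(self, wt_config):
        with pytest.raises(RegimeRangeError) as exc:
            l_fraction(50.0, wt_config)
        assert exc.value.regime == "B-plectonemic"
        with pytest.raises(RegimeRangeError) as exc:
            l_fraction(-900.0, wt_config)
        assert exc.value.regime == "L-plectonemic"


class TestMixedExtension:
    def test_pure_phase_endpoints(self, wt_config):
        for force in (1.1, 2.3):
            le_b = wlc_extension(
                force, wt_config.phase_B, wt_config.tether, wt_config.thermal
            )
            le_l = wlc_extension(
                force, wt_config.phase_L, wt_config.tether, wt_config.thermal
            )
            assert mixed_extension(force, wt_config.n_b_max, wt_config) == le_b
            assert mixed_extension(force, wt_config.n_t_max, wt_config) == le_l

    def test_bounded_between_pure_phases(self, wt_config):
        for force in (1.0, 2.0, 3.5):
            le_b = wlc_extension(
                force, wt_config.phase_B, wt_config.tether, wt_config.thermal
            )
            le_l = wlc_extension(
                force, wt_config.phase_L, wt_config.tether, wt_config.thermal
            )
            lo, hi = min(le_b, le_l), max(le_b, le_l)
            for n_t in np.linspace(wt_config.n_t_max, wt_config.n_b_max, 9):
                assert lo <= mixed_extension(force, n_t, wt_config) <= hi

    def test_turn_independent_at_inversion_force(self, wt_config):
        f_star = inversion_force(wt_config).f_star
        ref = mixed_extension(f_star, wt_config.n_b_max, wt_config)
        for n_t in np.linspace(wt_config.n_t_max, wt_config.n_b_max, 11):
            assert mixed_extension(f_star, n_t, wt_config) == pytest.approx(
                ref, rel=1e-8
            )


class TestBlSlope:
    def test_zero_at_inversion_force(self, wt_config, dap_config):
        for cfg in (wt_config, dap_config):
            f_star = inversion_force(cfg).f_star
            assert abs(bl_slope(f_star, cfg)) < 1e-10

    def test_sign_straddles_inversion(self, wt_config):
        f_star = inversion_force(wt_config).f_star
        assert bl_slope(f_star - 0.5, wt_config) > 0
        assert bl_slope(f_star + 0.5, wt_config) < 0

    @pytest.mark.parametrize("force", [1.1, 2.3])
    def test_matches_finite_difference(self, force, wt_config):
        n0 = 0.5 * (wt_config.n_b_max + wt_config.n_t_max)
        fd = (
            mixed_extension(force, n0 + 0.5, wt_config)
            - mixed_extension(force, n0 - 0.5, wt_config)
        ) / 1.0
        assert bl_slope(force, wt_config) == pytest.approx(fd, rel=1e-8)

    def test_unique_zero_in_bracket(self, wt_config):
        forces = np.linspace(0.05, 45.0, 400)
        signs = np.sign([bl_slope(f, wt_config) for f in forces])
        changes = np.nonzero(np.diff(signs))[0]
        assert changes.size == 1


class TestInversionForce:
    def test_wt_value(self, wt_config):
        # measured F*_WT = 2.7 +/- 0.3 pN
        assert inversion_force(wt_config).f_star == pytest.approx(2.7, abs=0.3)

    def test_dap_value(self, dap_config):
        # measured F*_DAP = 1.6 +/- 0.3 pN
        assert inversion_force(dap_config).f_star == pytest.approx(1.6, abs=0.3)

    def test_degenerate_phases_rejected(self, tether, thermal):
        phase = PhaseParams(50.0, 0.34)
        cfg = ModelConfig(
            phase_B=phase, phase_L=phase, tether=tether, thermal=thermal
        )
        with pytest.raises(DegeneratePhasesError):
            inversion_force(cfg)

    def test_noncrossing_parameters_rejected(self, tether, thermal):
        # L form stiffer than B: curves need not cross
        cfg = ModelConfig(
            phase_B=PhaseParams(50.0, 0.34),
            phase_L=PhaseParams(80.0, 0.48),
            tether=tether,
            thermal=thermal,
        )
        with pytest.raises(ValueError):
            inversion_force(cfg)

    def test_monotone_in_lpl_and_ratio(self, wt_config):
        f_at_lpl = [
            inversion_force(default_config(lpl=lpl, ratio_l0=1.4)).f_star
            for lpl in np.linspace(2.0, 12.0, 15)
        ]
        assert np.all(np.diff(f_at_lpl) < 0)
        f_at_ratio = [
            inversion_force(default_config(lpl=3.8, ratio_l0=r)).f_star
            for r in np.linspace(1.15, 1.7, 15)
        ]
        assert np.all(np.diff(f_at_ratio) < 0)


class TestLplFromInversion:
    def test_wt_headline(self, wt_config):
        assert lpl_from_inversion(2.7, 1.4, wt_config) == pytest.approx(
            3.8, abs=0.3
        )

    def test_dap_headline(self, wt_config):
        assert lpl_from_inversion(1.6, 1.4, wt_config) == pytest.approx(
            6.0, abs=0.3
        )

    @pytest.mark.parametrize("f_star", [1.0, 2.0, 3.0])
    def test_round_trip_with_forward_model(self, f_star, wt_config):
        lpl = lpl_from_inversion(f_star, 1.4, wt_config)
        cfg = default_config(lpl=lpl, ratio_l0=1.4)
        assert inversion_force(cfg).f_star == pytest.approx(
            f_star, abs=1e-6
        )

    def test_invalid_inputs(self, wt_config):
        with pytest.raises(ValueError):
            lpl_from_inversion(-1.0, 1.4, wt_config)
        with pytest.raises(ValueError):
            lpl_from_inversion(2.7, 0.9, wt_config)


class TestCompatibilityRegion:
    ratios = np.linspace(1.2, 1.6, 9)
    lpls = np.linspace(1.0, 10.0, 19)

    def test_inferred_point_inside_mask(self, wt_config):
        f_star = 2.7
        lpl = lpl_from_inversion(f_star, 1.4, wt_config)
        ratios = np.array([1.4])
        lpls = np.array([lpl])
        reg = compatibility_region(f_star, 0.3, ratios, lpls, wt_config)
        assert reg.mask[0, 0]

    def test_masked_interval_contiguous_along_ratio_14(self, wt_config):
        lpls = np.linspace(1.0, 12.0, 111)
        reg = compatibility_region(
            2.7, 0.3, np.array([1.4]), lpls, wt_config
        )
        idx = np.nonzero(reg.mask[0])[0]
        assert idx.size > 0
        assert np.all(np.diff(idx) == 1)
        # dense 1-D scan: F* monotone decreasing in L_pL where defined
        fs = reg.f_star_grid[0][~reg.flagged[0]]
        assert np.all(np.diff(fs) < 0)

    def test_zero_width_band_unattained_is_empty(self, wt_config):
        reg = compatibility_region(
            2.712345678, 0.0, self.ratios, self.lpls, wt_config
        )
        assert not reg.mask.any()

    def test_infeasible_points_flagged_not_fatal(self, wt_config):
        # L_pL = 60 nm > L_pB: no crossing; must be flagged, not raised
        lpls = np.array([3.8, 60.0])
        reg = compatibility_region(
            2.7, 0.3, np.array([1.4]), lpls, wt_config
        )
        assert reg.flagged[0, 1]
        assert not reg.mask[0, 1]
        assert not reg.flagged[0, 0]


class TestContourRatio:
    def test_threshold_geometry_value(self):
        # sigma_max = -1.8, r = 0.92 nm reproduces the 1.4 rise ratio
        assert contour_ratio_from_sigma(-1.8) == pytest.approx(1.40, abs=0.01)

    def test_identity_at_zero_sigma(self):
        assert contour_ratio_from_sigma(0.0) == 1.0

    def test_straight_backbone_at_sigma_minus_one(self):
        geo = HelixGeometry()
        s = math.hypot(
            geo.rise_B, 2 * math.pi * geo.radius / geo.bp_per_turn_B
        )
        assert contour_ratio_from_sigma(-1.0) == pytest.approx(
            s / geo.rise_B, rel=1e-12
        )

    def test_monotone_continuous_in_radius(self):
        # rise_L^2 = rise_B^2 + (2 pi r / n_B)^2 (1 - (1+sigma)^2): the
        # ratio grows smoothly with radius for sigma in (-2, 0)
        radii = np.linspace(0.7, 1.1, 9)
        ratios = [
            contour_ratio_from_sigma(-1.8, HelixGeometry(radius=r))
            for r in radii
        ]
        assert np.all(np.diff(ratios) > 0)
        assert np.all(np.abs(np.diff(ratios)) < 0.05)

    def test_out_of_range_sigma_rejected(self):
        for bad in (-2.0, -2.5, 0.5):
            with pytest.raises(ValueError):
                contour_ratio_from_sigma(bad)
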