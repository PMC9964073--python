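import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from formuopt.biometrics import (
    DissolutionProfile,
    PKProfile,
    PermeabilityAssay,
    ViabilityPlate,
    apparent_permeability,
    auc_trapezoid,
    cell_viability_percent,
    fold_change,
    intrinsic_dissolution_rate,
    nca,
    relative_bioavailability,
    withdrawal_corrected_cumulative,
)


class TestViability:
    def test_group_equals_control(self):
        plate = ViabilityPlate(1.1, 0.1, 1.1)
        assert cell_viability_percent(plate) == pytest.approx(100.0)

    def test_half_viability(self):
        assert cell_viability_percent(ViabilityPlate(0.6, 0.1, 1.1)) == pytest.approx(50.0)

    def test_group_equals_blank(self):
        assert cell_viability_percent(ViabilityPlate(0.1, 0.1, 1.1)) == pytest.approx(0.0)

    def test_invalid_assay(self):
        with pytest.raises(ValueError):
            cell_viability_percent(ViabilityPlate(0.5, 1.0, 0.9))


class TestPermeability:
    def test_zero_flux(self):
        assert apparent_permeability(PermeabilityAssay(0.0, 1.13, 50.0)) == 0.0

    def test_insert_area_arithmetic(self):
        # flux and C0 chosen so Papp = 1e-6 cm/s with the 1.13 cm^2 insert
        assay = PermeabilityAssay(flux=1.13e-4, area=1.13, initial_conc=100.0)
        assert apparent_permeability(assay) == pytest.approx(1e-6)

    def test_doubling_c0_halves_papp(self):
        a1 = PermeabilityAssay(2.0, 1.13, 50.0)
        a2 = PermeabilityAssay(2.0, 1.13, 100.0)
        assert apparent_permeability(a1) == pytest.approx(2 * apparent_permeability(a2))

    def test_minute_flux_conversion(self):
        per_min = PermeabilityAssay(60.0, 1.0, 1.0)
        assert apparent_permeability(per_min, seconds_per_time_unit=60.0) == pytest.approx(1.0)

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            apparent_permeability(PermeabilityAssay(1.0, 0.0, 1.0))


class TestWithdrawalCorrection:
    def test_zero_sample_volume_identity(self):
        p = DissolutionProfile((1, 2, 3), (5.0, 6.0, 7.0), sample_volume=0.0)
        np.testing.assert_allclose(withdrawal_corrected_cumulative(p), [5.0, 6.0, 7.0])

    def test_hand_recursion(self):
        p = DissolutionProfile((1, 2, 3), (10.0, 10.0, 10.0), medium_volume=500, sample_volume=5)
        np.testing.assert_allclose(withdrawal_corrected_cumulative(p), [10.0, 10.1, 10.2])

    def test_correction_is_nondecreasing_addon(self):
        p = DissolutionProfile((1, 2, 3, 4), (3.0, 1.0, 4.0, 1.0))
        corr = withdrawal_corrected_cumulative(p) - np.array(p.concentrations)
        assert np.all(np.diff(corr) >= 0)
        assert np.all(corr >= 0)

    def test_sample_volume_validation(self):
        with pytest.raises(ValueError):
            DissolutionProfile((1, 2), (1.0, 1.0), medium_volume=5.0, sample_volume=5.0)


class TestIDR:
    def test_exact_line(self):
        # V=1000 mL, area=1 cm^2, no withdrawal: mass/area == concentration
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = 2.5
        p = DissolutionProfile(tuple(t), tuple(s * t), medium_volume=1000,
                               sample_volume=0, disc_area=1.0)
        assert intrinsic_dissolution_rate(p) == pytest.approx(s, abs=1e-10)

    def test_flat_profile(self):
        p = DissolutionProfile((1, 2, 3), (4.0, 4.0, 4.0), sample_volume=0)
        assert intrinsic_dissolution_rate(p) == pytest.approx(0.0, abs=1e-12)

    def test_early_window_of_exponential(self):
        # C(t) = C_inf (1 - exp(-k t)): initial slope = C_inf * k
        k, c_inf = 0.01, 100.0
        t = np.linspace(0.25, 3.0, 12)
        c = c_inf * (1 - np.exp(-k * t))
        p = DissolutionProfile(tuple(t), tuple(c), medium_volume=1000,
                               sample_volume=0, disc_area=1.0)
        assert intrinsic_dissolution_rate(p, window=(0, 3)) == pytest.approx(c_inf * k, rel=0.02)

    def test_too_few_points(self):
        p = DissolutionProfile((1, 2, 3), (1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            intrinsic_dissolution_rate(p, window=(0, 2.5))


class TestFoldChange:
    def test_water_solubility_fold(self):
        assert fold_change(8.6, 1.8, 1) == 4.8

    def test_idr_fold_integer(self):
        assert fold_change(6.43, 0.0667, 0) == 96

    def test_identity(self):
        assert fold_change(3.14, 3.14, 2) == 1.0

    def test_half_up_rounding(self):
        assert fold_change(2.5, 1.0, 0) == 3  # not banker's rounding

    def test_nonpositive_denominator(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestNCA:
    def test_rectangle_auc(self):
        profile = PKProfile((0.0, 12.0, 24.0), (1.0, 1.0, 1.0))
        params = nca(profile)
        assert params.auc_0_t == pytest.approx(24.0)
        # flat terminal phase: elimination undefined
        assert params.ke is None and params.auc_0_inf is None and params.mrt is None

    def test_tmax_lookup(self):
        profile = PKProfile((0.5, 1.0, 1.6, 2.0, 4.0), (1.0, 3.0, 5.0, 4.0, 2.0))
        assert nca(profile).tmax == 1.6
        assert nca(profile).cmax == 5.0

    def test_one_compartment_closed_form(self):
        from formuopt.oracle import PKSimConfig, simulate_pk_profile

        ka, ke = 1.2, 0.15
        t_end = 6 * np.log(2) / ke
        cfg = PKSimConfig(dose=5.0, ka=ka, ke=ke, volume_over_F=1.5,
                          sample_times=tuple(np.linspace(0, t_end, 300)))
        params = nca(simulate_pk_profile(cfg), terminal_points=5)
        assert params.auc_0_inf == pytest.approx(5.0 / (1.5 * ke), rel=0.01)
        assert params.t_half == pytest.approx(np.log(2) / ke, rel=0.01)

    def test_terminal_half_life_recovery_grid(self):
        from formuopt.oracle import PKSimConfig, simulate_pk_profile

        for ka in (0.8, 2.0):
            for ke in (0.08, 0.2):
                t_end = 5.5 * np.log(2) / ke
                cfg = PKSimConfig(dose=1.0, ka=ka, ke=ke, volume_over_F=1.0,
                                  sample_times=tuple(np.linspace(0, t_end, 240)))
                params = nca(simulate_pk_profile(cfg), terminal_points=5)
                assert params.t_half == pytest.approx(np.log(2) / ke, rel=0.02)

    def test_auc_additivity(self):
        t = (0.0, 1.0, 2.5, 4.0, 8.0, 12.0)
        c = (0.0, 4.0, 6.0, 5.0, 2.0, 1.0)
        full = auc_trapezoid(t, c, 0, 12)
        assert auc_trapezoid(t, c, 0, 4) + auc_trapezoid(t, c, 4, 12) == pytest.approx(full)

    @given(scale=st.floats(0.1, 50))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        t = (0.5, 1, 2, 3, 4, 6, 12, 24)
        c = np.array([2.0, 4.0, 5.0, 4.5, 3.8, 2.9, 1.2, 0.3])
        base = nca(PKProfile(t, tuple(c)))
        scaled = nca(PKProfile(t, tuple(c * scale)))
        assert scaled.cmax == pytest.approx(base.cmax * scale, rel=1e-9)
        assert scaled.auc_0_t == pytest.approx(base.auc_0_t * scale, rel=1e-9)
        assert scaled.auc_0_inf == pytest.approx(base.auc_0_inf * scale, rel=1e-9)
        assert scaled.tmax == base.tmax
        assert scaled.ke == pytest.approx(base.ke, rel=1e-9)
        assert scaled.t_half == pytest.approx(base.t_half, rel=1e-9)
        assert scaled.mrt == pytest.approx(base.mrt, rel=1e-9)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            PKProfile((1.0, 0.5), (1.0, 2.0))
        with pytest.raises(ValueError):
            PKProfile((0.0, 1.0), (1.0, -2.0))


class TestRelativeBioavailability:
    def test_40mg_dose(self):
        assert relative_bioavailability(110.94, 76.42) == pytest.approx(145.2, abs=0.05)

    def test_10mg_dose(self):
        assert relative_bioavailability(41.75, 41.97) == pytest.approx(99.5, abs=0.05)

    def test_equal_auc(self):
        assert relative_bioavailability(50.0, 50.0) == pytest.approx(100.0)

    def test_dose_normalization(self):
        assert relative_bioavailability(100.0, 50.0, dose_test=40, dose_ref=20) == (
            pytest.approx(100.0)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            relative_bioavailability(1.0, 0.0)
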