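"""Tests for the analytic beam simulator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import erfinv

import beamqa as bq
from beamqa.dose_model import closed_form_dmax, buildup_rate_for_dmax
from beamqa.errors import DegenerateModelError, InputError, ResourceError


@pytest.fixture
def grid_spec():
    return bq.GridSpec(
        x_mm=np.linspace(-60.0, 60.0, 25),
        y_mm=np.linspace(-60.0, 60.0, 25),
        z_cm=np.round(np.arange(0.0, 30.0 + 1e-9, 0.5), 10),
    )


class TestPddCurve:
    def test_peak_location_matches_closed_form(self, depths_fine):
        # mu fixed at a typical 6 MV value, k solved for a 1.4 cm peak
        mu = 0.046
        k = buildup_rate_for_dmax(mu, 1.4)
        assert closed_form_dmax(mu, k) == pytest.approx(1.4, abs=1e-10)
        params = bq.BeamModelParams(mu=mu, k_buildup=k, noise_sd=0.0)
        curve = bq.make_pdd_curve(params, depths_fine)
        assert depths_fine[np.argmax(curve.doses)] == pytest.approx(1.4, abs=0.1)

    def test_noiseless_maximum_is_exactly_100(self, depths_fine):
        curve = bq.make_pdd_curve(bq.BeamModelParams.for_energy("6MV"), depths_fine)
        assert curve.doses.max() == 100.0

    def test_single_point_normalizes_to_100(self):
        params = bq.BeamModelParams.for_energy("6MV")
        curve = bq.make_pdd_curve(params, [params.dmax_cm])
        assert curve.doses[0] == 100.0

    @pytest.mark.parametrize("energy, lo, hi", [("6MV", 0.40, 0.44), ("12MV", 0.49, 0.52)])
    def test_default_beam_quality_in_clinical_band(self, depths_fine, energy, lo, hi):
        curve = bq.make_pdd_curve(bq.BeamModelParams.for_energy(energy), depths_fine)
        summary = bq.pdd_summary(curve)
        assert lo < summary.d20_d5 < hi

    def test_non_increasing_depths_rejected(self):
        params = bq.BeamModelParams.for_energy("6MV")
        with pytest.raises(InputError):
            bq.make_pdd_curve(params, [0.0, 1.0, 1.0])
        with pytest.raises(InputError):
            bq.make_pdd_curve(params, [])

    def test_noise_is_seeded_and_multiplicative(self, depths_fine):
        params = bq.BeamModelParams.for_energy("6MV", noise_sd=0.02, seed=42)
        a = bq.make_pdd_curve(params, depths_fine)
        b = bq.make_pdd_curve(params, depths_fine)
        assert np.array_equal(a.doses, b.doses)
        clean = bq.make_pdd_curve(bq.BeamModelParams.for_energy("6MV"), depths_fine)
        rel = a.doses[clean.doses > 10] / clean.doses[clean.doses > 10] - 1.0
        assert 0.01 < np.std(rel) < 0.04  # noise scales with local dose

    @given(mu=st.floats(0.02, 0.09), k=st.floats(0.5, 5.0))
    def test_argmax_within_one_grid_step_of_closed_form(self, mu, k):
        depths = np.round(np.arange(0.0, 30.0 + 1e-9, 0.1), 10)
        curve = bq.make_pdd_curve(bq.BeamModelParams(mu=mu, k_buildup=k), depths)
        z_star = closed_form_dmax(mu, k)
        assert abs(depths[np.argmax(curve.doses)] - z_star) <= 0.1 + 1e-12


class TestProfile:
    def test_even_without_horns_or_wedge(self, positions_mm):
        params = bq.BeamModelParams.for_energy("6MV", horn_amplitude=0.0)
        prof = bq.make_profile(params, 10.0, positions_mm)
        np.testing.assert_allclose(prof.doses, prof.doses[::-1], rtol=1e-12, atol=1e-12)

    @given(
        sigma=st.floats(1.0, 6.0),
        field=st.floats(5.0, 20.0),
        depth=st.floats(0.0, 20.0),
    )
    def test_evenness_property(self, sigma, field, depth):
        params = bq.BeamModelParams.for_energy(
            "6MV", penumbra_sigma=sigma, field_size=field, horn_amplitude=0.0
        )
        x = np.linspace(-2.0 * params.field_width_mm(depth), 2.0 * params.field_width_mm(depth), 201)
        prof = bq.make_profile(params, depth, x)
        np.testing.assert_allclose(prof.doses, prof.doses[::-1], rtol=1e-12, atol=1e-12)

    def test_edge_width_matches_erf_closed_form(self):
        sigma = 3.0
        params = bq.BeamModelParams.for_energy(
            "6MV", penumbra_sigma=sigma, horn_amplitude=0.0, ssd=100.0, field_size=10.0
        )
        prof = bq.make_profile(params, 0.0, np.linspace(-90, 90, 1441))  # 0.125 mm pitch
        left, right, avg = bq.penumbra_widths(prof)
        expected = 2.0 * np.sqrt(2.0) * erfinv(0.6) * sigma
        assert avg == pytest.approx(expected, rel=0.01)

    def test_sharp_edge_limit_is_top_hat(self):
        params = bq.BeamModelParams.for_energy(
            "6MV", penumbra_sigma=1e-6, horn_amplitude=0.0, field_size=10.0
        )
        prof = bq.make_profile(params, 0.0, np.linspace(-80, 80, 161))  # w = 100 mm at surface
        inside = np.abs(prof.positions) <= 49.0
        outside = np.abs(prof.positions) >= 51.0
        assert np.allclose(prof.doses[inside], 100.0)
        assert np.allclose(prof.doses[outside], 0.0)

    def test_wedge_tilts_the_normalized_profile(self, positions_mm):
        g = 0.05
        params = bq.BeamModelParams.for_energy(
            "6MV", horn_amplitude=0.0, wedge_transmission_gradient=g
        )
        prof = bq.make_profile(params, 10.0, positions_mm)
        open_prof = bq.make_profile(
            bq.BeamModelParams.for_energy("6MV", horn_amplitude=0.0), 10.0, positions_mm
        )
        core = np.abs(positions_mm) < 30
        # normalized wedge profile equals open profile times exp(-g*x/10)
        np.testing.assert_allclose(
            prof.doses[core],
            open_prof.doses[core] * np.exp(-g * positions_mm[core] / 10.0),
            rtol=1e-9,
        )

    def test_empty_positions_rejected(self):
        with pytest.raises(InputError):
            bq.make_profile(bq.BeamModelParams.for_energy("6MV"), 10.0, [])


class TestDoseGrid:
    def test_noiseless_global_maximum_is_100(self, grid_spec):
        grid = bq.make_dose_grid(bq.BeamModelParams.for_energy("6MV"), grid_spec)
        assert grid.values.max() == 100.0

    def test_central_axis_equals_pdd_curve(self, grid_spec):
        params = bq.BeamModelParams.for_energy("6MV", horn_amplitude=0.0)
        grid = bq.make_dose_grid(params, grid_spec)
        ix = np.flatnonzero(grid.axes[0].coords == 0.0)[0]
        iy = np.flatnonzero(grid.axes[1].coords == 0.0)[0]
        curve = bq.make_pdd_curve(params, grid.axes[2].coords)
        np.testing.assert_allclose(grid.values[ix, iy, :], curve.doses, rtol=1e-9)

    def test_same_seed_gives_identical_grids(self, grid_spec):
        params = bq.BeamModelParams.for_energy("6MV", noise_sd=0.02, seed=7)
        a = bq.make_dose_grid(params, grid_spec)
        b = bq.make_dose_grid(params, grid_spec)
        assert np.array_equal(a.values, b.values)

    def test_grid_size_limit(self):
        spec = bq.GridSpec(
            x_mm=np.arange(0.0, 300.0), y_mm=np.arange(0.0, 300.0), z_cm=np.arange(0.0, 30.0)
        )
        with pytest.raises(ResourceError):
            bq.make_dose_grid(bq.BeamModelParams.for_energy("6MV"), spec)


class TestPerturbGrid:
    def test_identity_perturbation(self, grid_spec):
        grid = bq.make_dose_grid(bq.BeamModelParams.for_energy("6MV"), grid_spec)
        out = bq.perturb_grid(grid, shift=[0.0, 0.0, 0.0], scale=1.0, noise_sd=0.0)
        assert np.array_equal(out.values, grid.values)
        assert out is not grid

    def test_input_grid_unmodified(self, grid_spec):
        grid = bq.make_dose_grid(bq.BeamModelParams.for_energy("6MV"), grid_spec)
        before = grid.values.copy()
        bq.perturb_grid(grid, shift=[2.0, -1.0, 0.2], scale=1.1, noise_sd=0.01, seed=3)
        assert np.array_equal(grid.values, before)

    def test_shift_beyond_extent_rejected(self, grid_spec):
        grid = bq.make_dose_grid(bq.BeamModelParams.for_energy("6MV"), grid_spec)
        with pytest.raises(InputError):
            bq.perturb_grid(grid, shift=[500.0, 0.0, 0.0])

    def test_uniform_scale_bounds_gamma_by_one(self):
        # 3% rescale vs 3%/3mm global criterion: gamma <= 1 everywhere,
        # and gamma can only reach 1 where the dose equals the global maximum
        x = np.linspace(-60.0, 60.0, 121)
        dose = 100.0 * np.exp(-((x / 30.0) ** 2))
        ref = bq.DoseGrid(dose, (bq.Axis("x", "mm", x),))
        ev = bq.perturb_grid(ref, scale=1.03)
        gamma = bq.compute_gamma(ref, ev).gamma
        assert np.all(gamma <= 1.0 + 1e-12)
        at_one = np.flatnonzero(gamma > 1.0 - 1e-9)
        assert np.all(dose[at_one] == 100.0)

    def test_pure_shift_within_dta_passes_everywhere(self):
        x = np.linspace(-60.0, 60.0, 121)
        dose = 100.0 * np.exp(-((x / 25.0) ** 2))
        ref = bq.DoseGrid(dose, (bq.Axis("x", "mm", x),))
        ev = bq.perturb_grid(ref, shift=2.0)
        summary = bq.summarize_gamma(bq.compute_gamma(ref, ev))
        assert summary.pass_rate == 1.0


class TestFactorTable:
    def test_reference_only_gives_unity(self):
        table = bq.model_factor_table([bq.BeamModelParams.for_energy("6MV", field_size=10.0)])
        assert table.frame["s_cp"].tolist() == [1.0]

    def test_sweep_stays_in_clinical_output_band_and_is_monotone(self):
        fields = [1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0]
        params = [bq.BeamModelParams.for_energy("6MV", field_size=f) for f in fields]
        scp = bq.model_factor_table(params).frame["s_cp"].to_numpy()
        assert np.all(scp >= 0.55 - 1e-12) and np.all(scp <= 1.22 + 1e-12)
        assert np.all(np.diff(scp) >= 0)

    @given(a=st.floats(1.0, 39.0), b=st.floats(1.0, 39.0))
    def test_scp_monotone_for_any_field_pair(self, a, b):
        lo, hi = sorted((a, b))
        params = [
            bq.BeamModelParams.for_energy("6MV", field_size=lo),
            bq.BeamModelParams.for_energy("6MV", field_size=hi),
            bq.BeamModelParams.for_energy("6MV", field_size=10.0),
        ]
        frame = bq.model_factor_table(params).frame.sort_values("field_size")
        scp = frame["s_cp"].to_numpy()
        assert np.all(np.diff(scp) >= -1e-12)

    def test_missing_reference_field_rejected(self):
        with pytest.raises(InputError):
            bq.model_factor_table([bq.BeamModelParams.for_energy("6MV", field_size=5.0)])

    def test_head_scatter_increases_with_field_size(self):
        fields = [3.0, 5.0, 10.0, 20.0, 40.0]
        params = [bq.BeamModelParams.for_energy("12MV", field_size=f) for f in fields]
        sc = bq.model_factor_table(params).frame["s_c"].to_numpy()
        assert np.all(np.diff(sc) > 0)

    def test_generated_wedge_factor_below_one_and_decreasing_in_gradient(self):
        factors = []
        for g in (0.02, 0.05, 0.10):
            params = [
                bq.BeamModelParams.for_energy(
                    "6MV", field_size=10.0, wedge_transmission_gradient=g
                )
            ]
            factors.append(bq.model_factor_table(params).frame["wedge_factor"].iloc[0])
        assert all(f < 1.0 for f in factors)
        assert factors[0] > factors[1] > factors[2]


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu": -0.01, "k_buildup": 1.0},
            {"field_size": 0.0},
            {"ssd": -1.0},
            {"penumbra_sigma": 0.0},
            {"noise_sd": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InputError):
            bq.BeamModelParams.for_energy("6MV", **kwargs)

    def test_unknown_energy_label_rejected(self):
        with pytest.raises(InputError):
            bq.BeamModelParams.for_energy("4MV")

    def test_degenerate_scatter_multiplier_detected(self):
        params = bq.BeamModelParams.for_energy("6MV", field_size=1.0, scatter_slope=0.5)
        with pytest.raises(DegenerateModelError):
            bq.make_pdd_curve(params, [0.0, 1.0, 2.0])
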