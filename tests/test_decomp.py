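"""Decomposition tests: dynamic difference spectra, the four scale-factor
markers (with grid-search oracles), species subtraction and steady-state
absorption decomposition."""

import numpy as np
import pytest

from tadecomp import decomp, synthgen as sg
from tadecomp.containers import DelayAxis, SpectralAxis, Spectrum, TAMap

from conftest import grid_search_factor


def _simple_axes():
    saxis = SpectralAxis(np.linspace(430, 700, 28))
    taxis = DelayAxis(np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]))
    return saxis, taxis


class TestDynamicDifference:
    def test_time_constant_map_gives_zero(self):
        saxis, taxis = _simple_axes()
        tamap = TAMap(saxis, taxis, np.ones((8, 28)) * 1e-3)
        ddod = decomp.dynamic_difference(tamap, [(0, 3), (2, 5)])
        np.testing.assert_array_equal(ddod.stack(), 0.0)

    def test_linear_in_time_map_gives_delay_difference(self):
        saxis, taxis = _simple_axes()
        tamap = TAMap(saxis, taxis, np.outer(taxis.delays, np.ones(28)))
        ddod = decomp.dynamic_difference(tamap, [(0, 3), (1, 4)])
        for t1, t2, spec in ddod.entries:
            np.testing.assert_allclose(spec.values, t2 - t1)

    def test_single_exponential_closed_form(self):
        """For dOD(λ,t) = S(λ) e^(−t/0.5), the ΔΔOD between 0.5 and 1.0 ps
        is S(λ)(e^−2 − e^−1)."""
        saxis, taxis = _simple_axes()
        shape = np.exp(-((saxis.wavelengths - 520.0) ** 2) / (2 * 40.0**2))
        tamap = TAMap(saxis, taxis, np.outer(np.exp(-taxis.delays / 0.5), shape))
        i, j = 2, 3  # delays 0.5 and 1.0 ps
        ddod = decomp.dynamic_difference(tamap, [(i, j)])
        _, _, spec = ddod.entries[0]
        np.testing.assert_allclose(
            spec.values, shape * (np.exp(-2.0) - np.exp(-1.0)), rtol=1e-12
        )

    def test_bad_pairs_are_rejected(self):
        saxis, taxis = _simple_axes()
        tamap = TAMap(saxis, taxis, np.zeros((8, 28)))
        with pytest.raises(IndexError):
            decomp.dynamic_difference(tamap, [(0, 99)])
        with pytest.raises(ValueError, match="exceed"):
            decomp.dynamic_difference(tamap, [(3, 1)])


class TestDDoDFactor:
    def test_identity_gives_exactly_one(self, at_map):
        est = decomp.estimate_scale_factor_ddod(at_map, at_map)
        assert est.factor == 1.0
        assert est.residual_norm == 0.0
        assert est.method is decomp.ScaleMethod.DDOD

    def test_scaled_map_recovers_scale_exactly(self, at_map):
        mix = TAMap(at_map.saxis, at_map.taxis, 0.65 * at_map.dod)
        est = decomp.estimate_scale_factor_ddod(mix, at_map)
        assert est.factor == pytest.approx(0.65, abs=1e-12)

    def test_da_fixture_recovery_and_grid_oracle(self, da_mix_factory, at_map):
        """A dark-adapted mixture (0.65 AT + 0.35 fast 13C) yields the AT
        weight once the fast species' excited signal is gone; the closed
        form agrees with a brute-force factor scan to 2e-4."""
        mix = da_mix_factory(0.65, noise_sigma=1e-5, seed=11)
        est = decomp.estimate_scale_factor_ddod(mix, at_map, t_min=0.6)
        assert est.factor == pytest.approx(0.65, abs=0.02)

        pairs = decomp.anchored_pairs(mix, 0.6)
        cols = decomp._mask_columns(mix, decomp.DEFAULT_EXCITED_STATE_MASK)
        dmix = decomp.dynamic_difference(mix, pairs).stack()[:, cols]
        dpure = decomp.dynamic_difference(at_map, pairs).stack()[:, cols]
        oracle = grid_search_factor(dmix, dpure)
        assert abs(est.factor - oracle) <= 2e-4
        assert est.stderr > 0

    def test_closed_form_matches_grid_oracle_on_random_fixtures(self):
        """Oracle equivalence on 10 random mixtures with known factors."""
        rng = np.random.default_rng(2024)
        saxis = SpectralAxis(np.linspace(430, 1400, 40))
        taxis = DelayAxis(np.linspace(0.0, 10.0, 20))
        for _ in range(10):
            pure = TAMap(saxis, taxis, rng.normal(0, 1e-3, (20, 40)))
            c_true = rng.uniform(0.1, 0.9)
            mix = TAMap(
                saxis, taxis, c_true * pure.dod + rng.normal(0, 1e-5, (20, 40))
            )
            est = decomp.estimate_scale_factor_ddod(mix, pure, t_min=0.0)
            pairs = decomp.anchored_pairs(mix, 0.0)
            cols = decomp._mask_columns(mix, decomp.DEFAULT_EXCITED_STATE_MASK)
            dmix = decomp.dynamic_difference(mix, pairs).stack()[:, cols]
            dpure = decomp.dynamic_difference(pure, pairs).stack()[:, cols]
            assert abs(est.factor - grid_search_factor(dmix, dpure)) <= 2e-4

    def test_static_pure_map_is_unidentifiable(self):
        saxis, taxis = _simple_axes()
        pure = TAMap(saxis, taxis, np.ones((8, 28)) * 1e-3)
        mix = TAMap(saxis, taxis, np.outer(taxis.delays, np.ones(28)))
        with pytest.raises(ValueError, match="unidentifiable"):
            decomp.estimate_scale_factor_ddod(mix, pure, t_min=0.0, mask=[(430, 700)])


class TestSubtraction:
    def test_zero_factor_is_identity(self, at_map):
        out = decomp.subtract_species(at_map, at_map, 0.0)
        np.testing.assert_array_equal(out.dod, at_map.dod)

    def test_known_superposition_is_removed_exactly(self, at_map, c13_map):
        mix = TAMap(at_map.saxis, at_map.taxis, at_map.dod + 0.5 * c13_map.dod)
        out = decomp.subtract_species(mix, at_map, 1.0)
        np.testing.assert_allclose(out.dod, 0.5 * c13_map.dod, atol=1e-14)

    def test_mixture_subtraction_identity(self, at_spec, c13_spec, saxis_full, taxis_linlog):
        """subtract(gen_mixture([A,B],[c,1−c],σ=0), A, c) == (1−c)·B."""
        c = 0.65
        mixture = sg.MixtureSpec((at_spec, c13_spec), (c, 1 - c), 0.0, 0)
        mix = sg.gen_mixture(mixture, saxis_full, taxis_linlog)
        a = sg.gen_species_map(at_spec, saxis_full, taxis_linlog)
        b = sg.gen_species_map(c13_spec, saxis_full, taxis_linlog)
        out = decomp.subtract_species(mix, a, c)
        np.testing.assert_allclose(out.dod, (1 - c) * b.dod, atol=1e-14)

    def test_estimated_factor_recovers_minor_species(
        self, da_mix_factory, at_map, c13_map
    ):
        mix = da_mix_factory(0.65, noise_sigma=1e-5, seed=21)
        est = decomp.estimate_scale_factor_ddod(mix, at_map)
        residual = decomp.subtract_species(mix, at_map, est.factor)
        np.testing.assert_allclose(residual.dod, 0.35 * c13_map.dod, atol=5e-4)

    def test_axis_mismatch_is_error(self, at_map):
        other = TAMap(
            SpectralAxis(at_map.saxis.wavelengths + 1.0), at_map.taxis, at_map.dod
        )
        with pytest.raises(ValueError, match="axes"):
            decomp.subtract_species(at_map, other, 0.5)


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestOscillationFactor:
    def test_identity_gives_one(self, at_map_vis):
        est = decomp.estimate_factor_from_oscillations(at_map_vis, at_map_vis)
        assert est.factor == pytest.approx(1.0, abs=1e-12)

    def test_two_pump_fraction_recovered(self, at_spec, k_spec, saxis_vis, taxis_uniform, at_map_vis):
        """The coherent modulation near 520 nm is an AT-exclusive marker:
        its amplitude in the two-pump mixture recovers f_AT (the 0.6 of
        the K-isolation subtraction) within 0.02."""
        mix = sg.gen_double_pump(
            at_spec, k_spec, 0.6, saxis_vis, taxis_uniform, noise_sigma=1e-5, seed=7
        )
        est = decomp.estimate_factor_from_oscillations(mix, at_map_vis)
        assert est.factor == pytest.approx(0.6, abs=0.02)
        assert est.method is decomp.ScaleMethod.OSCILLATION

    def test_contaminating_coherence_biases_upward(
        self, at_spec, saxis_vis, taxis_uniform, at_map_vis
    ):
        """If the second species carries its own (10%-amplitude) coherence
        at the same mode, the factor is biased upward — quantifying the
        'oscillation exclusively due to the pure species' assumption."""
        k_osc = sg.SpeciesSpec(
            gsb_band=sg.Band(590, 50, 0.01),
            esa_bands=(sg.Band(480, 32, 0.008),),
            se_bands=(sg.Band(860, 110, 0.007),),
            product_band=sg.Band(570, 45, 0.0096),
            kinetics=(sg.KineticComponent(0.5, 1.7), sg.KineticComponent(0.5, 11.0)),
            phi_iso=0.5,
            oscillations=(
                sg.OscComponent(180.0, 0.6, 0.0, 0.008, 520.0, 30.0),
            ),
        )
        mix = sg.gen_double_pump(
            at_spec, k_osc, 0.6, saxis_vis, taxis_uniform, noise_sigma=1e-5, seed=7
        )
        est = decomp.estimate_factor_from_oscillations(mix, at_map_vis)
        assert est.factor > 0.605
        assert est.factor < 0.7

    def test_missing_coherence_marker_is_error(
        self, k_spec, saxis_vis, taxis_uniform
    ):
        quiet = sg.gen_species_map(k_spec, saxis_vis, taxis_uniform)
        with pytest.raises(ValueError, match="no coherence marker"):
            decomp.estimate_factor_from_oscillations(quiet, quiet)


class TestSEFactor:
    def test_scaled_window_recovers_exactly(self, at_map):
        mix = TAMap(at_map.saxis, at_map.taxis, 0.65 * at_map.dod)
        est = decomp.estimate_factor_from_se(mix, at_map)
        assert est.factor == pytest.approx(0.65, abs=1e-12)
        assert est.method is decomp.ScaleMethod.NIR_SE

    def test_da_fixture_recovery_after_fast_decay(self, da_mix_factory, at_map):
        mix = da_mix_factory(0.65, noise_sigma=1e-5, seed=31)
        est = decomp.estimate_factor_from_se(mix, at_map, t_range=(0.6, 5.0))
        assert est.factor == pytest.approx(0.65, abs=0.02)

    def test_early_window_is_biased_upward(self, da_mix_factory, at_map):
        """Before the fast isomer's SE has decayed, its emission adds to
        the mixture signal and inflates the inferred factor."""
        mix = da_mix_factory(0.65, noise_sigma=1e-5, seed=31)
        late = decomp.estimate_factor_from_se(mix, at_map, t_range=(0.6, 5.0))
        early = decomp.estimate_factor_from_se(mix, at_map, t_range=(0.0, 0.3))
        assert early.factor - 0.65 > 0.05
        assert early.factor > late.factor

    def test_estimators_agree_within_uncertainty(self, da_mix_factory, at_map):
        mix = da_mix_factory(0.65, noise_sigma=5e-5, seed=41)
        ddod = decomp.estimate_scale_factor_ddod(mix, at_map)
        se = decomp.estimate_factor_from_se(mix, at_map)
        # the two markers measure the same mixing fraction
        assert abs(ddod.factor - se.factor) <= 0.04


class TestLateSpectrumMatch:
    def test_identity_gives_one(self, at_map):
        est = decomp.late_spectrum_match(at_map, at_map, t_min=50.0)
        assert est.factor == pytest.approx(1.0, abs=1e-12)

    def test_reciprocal_scaling(self, at_map):
        scaled = TAMap(at_map.saxis, at_map.taxis, 0.8 * at_map.dod)
        est = decomp.late_spectrum_match(at_map, scaled, t_min=50.0)
        assert est.factor == pytest.approx(1.25, abs=1e-12)

    def test_two_pump_late_match_exceeds_unity(
        self, at_spec, k_spec, saxis_full, taxis_linlog, at_map
    ):
        """With K photoproducts feeding the all-trans ground state, the
        two-pump mixture's late spectrum is a fraction of the single-pump
        one, so matching it onto the pure experiment needs a factor > 1."""
        mix = sg.gen_double_pump(at_spec, k_spec, 0.6, saxis_full, taxis_linlog)
        est = decomp.late_spectrum_match(at_map, mix, t_min=50.0)
        assert est.factor > 1.0

    def test_no_late_delays_is_error(self, at_map):
        with pytest.raises(ValueError, match="no delays"):
            decomp.late_spectrum_match(at_map, at_map, t_min=1e4)


class TestAbsorptionDecomposition:
    @pytest.fixture(scope="class")
    def vis_axis(self):
        return SpectralAxis(np.arange(430.0, 700.0 + 0.5, 1.0))

    def test_equal_spectra_return_the_reference(self, vis_axis):
        a_la = sg.gen_absorption([sg.Band(570, 40, 1.0)], SpectralAxis(vis_axis.wavelengths))
        comp = decomp.IsomerComposition.from_at_fraction(0.65)
        result = decomp.decompose_absorption(a_la, a_la, comp)
        np.testing.assert_allclose(result.spectrum.values, a_la.values, atol=1e-14)

    def test_zero_at_fraction_returns_da_spectrum(self, vis_axis):
        a_da = sg.gen_absorption([sg.Band(560, 40, 1.0)], SpectralAxis(vis_axis.wavelengths))
        a_la = sg.gen_absorption([sg.Band(570, 40, 1.0)], SpectralAxis(vis_axis.wavelengths))
        comp = decomp.IsomerComposition.from_at_fraction(0.0)
        result = decomp.decompose_absorption(a_da, a_la, comp)
        np.testing.assert_allclose(result.spectrum.values, a_da.values, atol=1e-14)

    def test_gaussian_mixture_recovers_543_peak(self, vis_axis):
        """LA = G(570, 40); true 13C = G(543, 40); DA = 0.65 LA + 0.35 13C
        → the decomposed spectrum peaks at 543.0 ± 0.5 nm."""
        axis = SpectralAxis(vis_axis.wavelengths)
        a_la = sg.gen_absorption([sg.Band(570, 40, 1.0)], axis)
        a_13c = sg.gen_absorption([sg.Band(543, 40, 1.0)], axis)
        a_da = Spectrum(axis, 0.65 * a_la.values + 0.35 * a_13c.values)
        comp = decomp.IsomerComposition(x_13c=0.35, x_at=0.65)
        result = decomp.decompose_absorption(a_da, a_la, comp)
        assert result.lambda_max_nm == pytest.approx(543.0, abs=0.5)
        np.testing.assert_allclose(result.spectrum.values, a_13c.values, atol=1e-12)

    def test_zero_minor_fraction_is_error(self, vis_axis):
        axis = SpectralAxis(vis_axis.wavelengths)
        a_la = sg.gen_absorption([sg.Band(570, 40, 1.0)], axis)
        with pytest.raises(ValueError, match="x_13c"):
            decomp.decompose_absorption(
                a_la, a_la, decomp.IsomerComposition(x_13c=0.0, x_at=1.0)
            )

    def test_negative_dips_warn_but_are_not_clipped(self, vis_axis):
        axis = SpectralAxis(vis_axis.wavelengths)
        a_la = sg.gen_absorption([sg.Band(570, 40, 1.0)], axis)
        a_da = Spectrum(axis, 0.5 * a_la.values + 0.35 * sg.gen_absorption(
            [sg.Band(500, 30, 0.3)], axis).values)
        comp = decomp.IsomerComposition(x_13c=0.35, x_at=0.65)
        with pytest.warns(UserWarning, match="negative"):
            result = decomp.decompose_absorption(a_da, a_la, comp)
        assert result.spectrum.values.min() < 0

    def test_composition_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            decomp.IsomerComposition(x_13c=0.3, x_at=0.6)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            decomp.IsomerComposition(x_13c=-0.1, x_at=1.1)
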