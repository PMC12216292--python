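import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoswitch.errors import SingularInterfaceError, ValidationError
from nanoswitch.forward_model import (
    DemodResult,
    Layer,
    LayerStack,
    TipModel,
    beta_effective,
    beta_layers,
    demodulate,
    disc_profile,
    fdm_contrast,
    make_permittivity,
    normalized_spectrum,
    profile_fwhm_crossing,
    sphere_profile,
    wrap_phase_deg,
)

GRID = np.linspace(1400.0, 1800.0, 41)


class TestTipModel:
    def test_defaults_match_published_parameters(self, tip):
        assert tip.tapping_amplitude_a == 80.0
        assert tip.apex_radius_r == 60.0
        assert tip.spheroid_length_L == 300.0
        assert abs(tip.g_factor) == pytest.approx(0.7)
        assert cmath.phase(tip.g_factor) == pytest.approx(0.06)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tapping_amplitude_a": 0.0},
            {"apex_radius_r": -1.0},
            {"spheroid_length_L": 50.0},  # must exceed r=60
            {"g_factor": 2.5},
            {"g_factor": 0.0},
            {"min_height": -1.0},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            TipModel(**kwargs)


class TestMakePermittivity:
    def test_no_oscillators_is_constant(self):
        spec = make_permittivity([], 2.1, GRID)
        assert np.allclose(spec.epsilon, 2.1 + 0j)

    def test_resonance_imaginary_part_closed_form(self):
        center, strength, damping = 1603.0, 0.05, 12.0
        spec = make_permittivity([(center, strength, damping)], 2.0, GRID)
        # at nu = nu_j: eps = eps_inf + i S nu_j / gamma
        assert spec.eps_at(center).imag == pytest.approx(strength * center / damping)

    def test_two_oscillators_equal_sum_of_singles(self):
        o1, o2 = (1496.0, 0.02, 15.0), (1603.0, 0.05, 12.0)
        both = make_permittivity([o1, o2], 2.0, GRID)
        s1 = make_permittivity([o1], 2.0, GRID)
        s2 = make_permittivity([o2], 0.0, GRID)
        assert np.allclose(both.epsilon, s1.epsilon + s2.epsilon)

    def test_nonpositive_damping_rejected(self):
        with pytest.raises(ValidationError):
            make_permittivity([(1600.0, 0.1, 0.0)], 2.0, GRID)

    def test_passivity_on_grid(self):
        spec = make_permittivity([(1600.0, 0.3, 25.0)], 2.0, GRID)
        assert np.all(spec.epsilon.imag >= 0)


class TestBetaLayers:
    def test_single_interface_closed_form(self):
        stack = LayerStack.from_media([1.0, 4.0], [])
        for q in (1e-4, 0.01, 1.0, 9.0):
            assert beta_layers(stack, q) == pytest.approx(0.6 + 0j, abs=1e-15)

    def test_film_matching_substrate_is_transparent(self):
        stack = LayerStack.from_media([1.0, 4.0, 4.0], [10.0])
        assert beta_layers(stack, 0.3) == pytest.approx(0.6 + 0j, abs=1e-14)

    def test_three_layer_against_closed_form_oracle(self):
        # independent 3-interface algebra: r01, r12 with one exponential factor
        eps0, eps1, eps2, d, q = 1.0, 4.0, 1.0, 10.0, 1.0
        r01 = (eps1 - eps0) / (eps1 + eps0)
        r12 = (eps2 - eps1) / (eps2 + eps1)
        decay = math.exp(-2.0 * q * d)
        oracle = (r01 + r12 * decay) / (1.0 + r01 * r12 * decay)
        stack = LayerStack.from_media([eps0, eps1, eps2], [d])
        assert beta_layers(stack, q) == pytest.approx(oracle, abs=1e-15)

    @settings(max_examples=30, deadline=None)
    @given(q=st.floats(min_value=1e-4, max_value=9.9))
    def test_two_layer_is_q_independent(self, q):
        stack = LayerStack.from_media([1.0, 11.7 + 0.5j], [])
        assert abs(beta_layers(stack, q) - beta_layers(stack, 1.0)) < 1e-12

    @pytest.mark.parametrize("position", [1, 2])
    def test_zero_thickness_layer_is_identity(self, position):
        base = LayerStack.from_media([1.0, 4.0 + 0.3j, 2.0 + 1.0j], [12.0])
        layers = list(base.layers)
        layers.insert(position, Layer(7.0 + 0.1j, 0.0))
        augmented = LayerStack(layers)
        for q in (0.01, 0.2, 3.0):
            assert abs(beta_layers(augmented, q) - beta_layers(base, q)) < 1e-12

    def test_singular_interface_raises(self):
        stack = LayerStack.from_media([1.0 + 0j, -1.0 + 0j], [])
        with pytest.raises(SingularInterfaceError):
            beta_layers(stack, 1.0)

    def test_nonpositive_q_rejected(self, si_stack):
        with pytest.raises(ValidationError):
            beta_layers(si_stack, 0.0)


class TestBetaEffective:
    def test_uniform_stack_gives_zero(self, uniform_stack):
        for z in (10.0, 50.0, 200.0):
            assert beta_effective(uniform_stack, z) == pytest.approx(0j, abs=1e-15)

    def test_two_layer_returns_fresnel_value(self, si_stack):
        expected = (11.7 - 1.0) / (11.7 + 1.0)
        assert beta_effective(si_stack, 30.0) == pytest.approx(expected, abs=1e-14)

    @pytest.mark.parametrize("z", [10.0, 50.0, 200.0])
    def test_three_layer_matches_high_resolution_oracle(self, z, background_stack):
        nu = 1603.0
        got = beta_effective(background_stack, z, nu)
        # oracle: 1e5-node trapezoid on an independent log grid
        q = np.logspace(-7, 2, 100_000)
        beta_q = np.asarray(beta_layers(background_stack, q, nu))
        w = q * np.exp(-2.0 * q * z)
        oracle = np.trapezoid(beta_q * w, q) / np.trapezoid(w, q)
        assert abs(got - oracle) / abs(oracle) < 1e-4

    def test_zero_height_rejected(self, si_stack):
        with pytest.raises(ValidationError):
            beta_effective(si_stack, 0.0)


class TestFdmContrast:
    def test_no_sample_limit(self, tip, uniform_stack):
        for H in (0.0, 40.0, 200.0):
            assert fdm_contrast(tip, uniform_stack, H) == pytest.approx(1.0 + 0j, abs=1e-14)

    def test_near_field_decays_with_height(self, tip, si_stack):
        assert abs(fdm_contrast(tip, si_stack, 200.0) - 1.0) < abs(
            fdm_contrast(tip, si_stack, 0.0) - 1.0
        )

    def test_against_independent_transcription(self, tip, si_stack):
        """Double-implementation oracle: same closed form, scalar cmath code."""
        H = 0.0
        r, L, g, a = 60.0, 300.0, 0.7 * cmath.exp(0.06j), 80.0
        beta = (11.7 - 1.0) / (11.7 + 1.0)
        w0 = 1.31 * r * L / (L + 2 * r)
        w1 = r / 2
        f0 = (g - (r + 2 * H + w0) / (2 * L)) * math.log(
            4 * L / (r + 4 * H + 2 * w0)
        ) / math.log(4 * L / r)
        f1 = (g - (r + 2 * H + w1) / (2 * L)) * math.log(
            4 * L / (r + 4 * H + 2 * w1)
        ) / math.log(4 * L / r)
        oracle = 1 + beta * f0 / (2 * (1 - beta * f1))
        assert fdm_contrast(tip, si_stack, H) == pytest.approx(oracle, abs=1e-12)

    def test_negative_height_rejected(self, tip, si_stack):
        with pytest.raises(ValidationError):
            fdm_contrast(tip, si_stack, -1.0)


class TestDemodulate:
    def test_uniform_stack_has_no_harmonics(self, tip, uniform_stack):
        for n in range(1, 5):
            assert demodulate(tip, uniform_stack, harmonic_n=n).sigma_n == 0

    def test_harmonics_decay(self, tip, si_stack):
        s2 = demodulate(tip, si_stack, harmonic_n=2).s_n
        s3 = demodulate(tip, si_stack, harmonic_n=3).s_n
        assert s3 <= s2

    @pytest.mark.parametrize("stack_name", ["si_stack", "background_stack", "vesicle_stack"])
    def test_fft_matches_brute_force_quadrature(self, tip, stack_name, request):
        stack = request.getfixturevalue(stack_name)
        nu = 1603.0 if stack_name != "si_stack" else None
        got = demodulate(tip, stack, nu, harmonic_n=2, n_theta_samples=256).sigma_n
        theta = np.linspace(0.0, 2.0 * np.pi, 10_001)
        H = tip.min_height + tip.tapping_amplitude_a * (1.0 + np.cos(theta))
        sigma = np.asarray(fdm_contrast(tip, stack, H, nu))
        oracle = np.trapezoid(sigma * np.exp(-2j * theta), theta) / (2.0 * np.pi)
        assert abs(got - oracle) / abs(oracle) < 1e-8

    def test_result_invariants(self, tip, si_stack):
        res = demodulate(tip, si_stack, harmonic_n=2)
        assert res.s_n == abs(res.sigma_n)
        assert -180.0 < res.phi_n <= 180.0

    @pytest.mark.parametrize("n_theta", [32, 100, 63])
    def test_bad_sampling_rejected(self, tip, si_stack, n_theta):
        with pytest.raises(ValidationError):
            demodulate(tip, si_stack, harmonic_n=2, n_theta_samples=n_theta)

    def test_unresolvable_harmonic_rejected(self, tip, si_stack):
        with pytest.raises(ValidationError):
            demodulate(tip, si_stack, harmonic_n=40, n_theta_samples=64)


class TestNormalizedSpectrum:
    def test_self_reference_is_unity(self, tip, vesicle_stack):
        out = normalized_spectrum(tip, vesicle_stack, vesicle_stack, [1500.0, 1603.0])
        for nc in out:
            assert nc.eta_n == pytest.approx(1.0 + 0j, abs=1e-15)
            assert nc.s_ratio == pytest.approx(1.0)
            assert nc.phi_diff == pytest.approx(0.0)

    def test_real_media_real_tip_give_zero_phase(self, real_tip):
        sample = LayerStack.from_media([1.0, 4.0, 2.2, 1.8], [10.0, 4.0])
        reference = LayerStack.from_media([1.0, 11.7], [])
        out = normalized_spectrum(real_tip, sample, reference, [1500.0, 1700.0])
        for nc in out:
            assert abs(nc.phi_diff) < 1e-9

    def test_cis_surrogate_has_smaller_phase_at_1603(self, tip, material_table, background_stack):
        from nanoswitch.materials import membrane_stack

        trans = membrane_stack("lipid_trans", table=material_table)
        cis = membrane_stack("lipid_cis", table=material_table)
        phi_trans = normalized_spectrum(tip, trans, background_stack, [1603.0])[0].phi_diff
        phi_cis = normalized_spectrum(tip, cis, background_stack, [1603.0])[0].phi_diff
        assert phi_cis < phi_trans

    def test_phase_monotone_in_oscillator_strength(self, tip, material_table, background_stack):
        from nanoswitch.materials import _as_layer_eps

        sin_eps = _as_layer_eps(material_table["sin_membrane"])
        d2o_eps = _as_layer_eps(material_table["d2o"])
        phases = []
        for strength in np.linspace(0.0, 0.08, 6):
            eps = make_permittivity([(1603.0, strength, 12.0)], 2.1, GRID)
            stack = LayerStack(
                [Layer(1.0, None), Layer(sin_eps, 10.0), Layer(eps, 4.0), Layer(d2o_eps, None)]
            )
            phases.append(
                normalized_spectrum(tip, stack, background_stack, [1603.0])[0].phi_diff
            )
        assert np.all(np.diff(phases) > 0)


@pytest.fixture(scope="module")
def lipid_eps(material_table):
    from nanoswitch.materials import _as_layer_eps

    return _as_layer_eps(material_table["lipid_trans"])


class TestSphereProfile:
    NU = 1603.0

    def test_far_offsets_equal_background(self, tip, background_stack, lipid_eps):
        prof = sphere_profile(
            tip, 660.0, lipid_eps, background_stack, [-2000.0, 2000.0], self.NU
        )
        assert prof["phi_n_deg"][0] == pytest.approx(prof["background_phi_deg"])
        assert prof["s_n"][0] == pytest.approx(prof["background_s_n"])

    def test_symmetric_with_peak_at_center(self, tip, background_stack, lipid_eps):
        offsets = np.linspace(-600.0, 600.0, 25)
        prof = sphere_profile(tip, 660.0, lipid_eps, background_stack, offsets, self.NU)
        phi = prof["phi_n_deg"]
        assert np.argmax(phi) == len(offsets) // 2
        assert np.allclose(phi, phi[::-1], atol=1e-9)

    def test_sphere_narrower_than_flattened_disc(self, tip, background_stack, lipid_eps):
        offsets = np.linspace(-600.0, 600.0, 61)
        sphere = sphere_profile(tip, 660.0, lipid_eps, background_stack, offsets, self.NU)
        disc = disc_profile(
            tip, 660.0, 100.0, lipid_eps, background_stack, offsets, self.NU
        )
        fwhm_sphere = profile_fwhm_crossing(
            offsets, sphere["phi_n_deg"], sphere["background_phi_deg"]
        )
        fwhm_disc = profile_fwhm_crossing(
            offsets, disc["phi_n_deg"], disc["background_phi_deg"]
        )
        assert fwhm_sphere < fwhm_disc

    def test_asymmetric_offsets_rejected(self, tip, background_stack, lipid_eps):
        with pytest.raises(ValidationError):
            sphere_profile(tip, 660.0, lipid_eps, background_stack, [0.0, 100.0], self.NU)


class TestWrapPhase:
    @pytest.mark.parametrize(
        "phi,expected", [(0.0, 0.0), (180.0, 180.0), (-180.0, 180.0), (190.0, -170.0), (540.0, 180.0)]
    )
    def test_wrapping(self, phi, expected):
        assert wrap_phase_deg(phi) == pytest.approx(expected)


class TestStackValidation:
    def test_needs_two_layers(self):
        with pytest.raises(ValidationError):
            LayerStack([Layer(1.0, None)])

    def test_interior_must_be_finite(self):
        with pytest.raises(ValidationError):
            LayerStack([Layer(1.0, None), Layer(4.0, None), Layer(2.0, None)])

    def test_outer_layers_must_be_half_spaces(self):
        with pytest.raises(ValidationError):
            LayerStack([Layer(1.0, 10.0), Layer(4.0, None)])

    def test_gain_medium_rejected(self):
        with pytest.raises(ValidationError):
            Layer(2.0 - 0.5j, 10.0)
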