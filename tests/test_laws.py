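"""Constitutive-law evaluation: scalar laws, tensors, tangents."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myopassive import (DomainError, DeformationState, ECMParams,
                        FibreLawParams, TangLawParams, VolumeFractions,
                        ZhangLawParams, bundle_stress_tensor,
                        bundle_uniaxial_stress, ecm_stress_tensor,
                        ecm_uniaxial_stress, fibre_stress,
                        fibre_tangent_modulus, tang_stress,
                        uniaxial_incompressible_F, zhang_stress,
                        zhang_initial_modulus,
                        UNIAXIAL_TENSOR_SCALAR_RATIO, BundleModel)


class TestFibreLaw:
    def test_zero_at_slack_and_in_shortening(self, pooled_fibre_params):
        assert fibre_stress(2.44, pooled_fibre_params) == 0.0
        assert fibre_stress(2.0, pooled_fibre_params) == 0.0

    def test_direct_evaluation(self, pooled_fibre_params):
        # independent scalar oracle: A (exp(lambda^2 - 1) - 1)
        lam = 3.0 / 2.44
        expected = 6.93 * (math.exp(lam ** 2 - 1.0) - 1.0)
        assert fibre_stress(3.0, pooled_fibre_params) == pytest.approx(expected)
        assert expected == pytest.approx(4.63, rel=1e-3)

    def test_fibre_fraction_scaled_values(self, pooled_fibre_params):
        # fibre contribution per unit bundle area at 3.5 um
        assert 0.85 * fibre_stress(3.5, pooled_fibre_params) == pytest.approx(
            11.2, rel=0.02)

    def test_vectorised_matches_scalar(self, pooled_fibre_params):
        grid = np.linspace(2.0, 4.2, 23)
        vec = fibre_stress(grid, pooled_fibre_params)
        assert vec.shape == grid.shape
        for L, v in zip(grid, vec):
            assert fibre_stress(float(L), pooled_fibre_params) == v

    @given(A=st.floats(0.5, 50), L0=st.floats(1.6, 3.0),
           lam=st.floats(0.2, 2.5))
    @settings(derandomize=True, max_examples=60)
    def test_clamp_and_growth(self, A, L0, lam):
        params = FibreLawParams(A=A, L0=L0)
        stress = fibre_stress(lam * L0, params)
        if lam < 1:
            assert stress == 0.0
        else:
            assert stress >= 0.0
            # strictly increasing beyond slack
            assert fibre_stress(lam * L0 * 1.01, params) > stress

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            fibre_stress(-1.0, FibreLawParams(1.0, 2.0))
        with pytest.raises(DomainError):
            FibreLawParams(A=-1.0, L0=2.0)
        with pytest.raises(DomainError):
            FibreLawParams(A=1.0, L0=0.0)


class TestFibreTangent:
    def test_initial_modulus_is_twice_A(self):
        params = FibreLawParams(A=6.93, L0=2.44)
        assert fibre_tangent_modulus(2.44, params) == pytest.approx(
            2 * 6.93, rel=1e-9)
        assert fibre_tangent_modulus(2.0, params) == 0.0

    def test_matches_central_difference(self, pooled_fibre_params, rng):
        # finite-difference oracle at 50 random (lambda, params) draws
        for _ in range(50):
            A = rng.uniform(1.0, 20.0)
            L0 = rng.uniform(1.8, 3.0)
            lam = rng.uniform(1.05, 1.8)
            params = FibreLawParams(A=A, L0=L0)
            L = lam * L0
            h = 1e-6 * L
            num = (fibre_stress(L + h, params) - fibre_stress(L - h, params)) \
                / (2 * h) * L0
            assert fibre_tangent_modulus(L, params) == pytest.approx(
                num, rel=1e-6)


class TestLiteratureLaws:
    def test_quadratic_law_closed_form(self):
        params = TangLawParams(P0=17.20, L0=2.36)
        assert tang_stress(2.36, params) == 0.0
        # lambda = 1.5 -> 4 P0 (0.5)^2 = P0
        assert tang_stress(1.5 * 2.36, params) == pytest.approx(17.20)
        # null initial stiffness: forward difference at slack ~ 0
        h = 1e-8
        assert (tang_stress(2.36 * (1 + h), params) / h) < 1e-5

    def test_zhang_law_closed_form(self):
        params = ZhangLawParams(P0=137.5, a=0.040, A=0.65, L0=1.71)
        assert zhang_stress(1.71, params) == 0.0
        expected = 2 * 137.5 * 0.040 * 0.65 * 1.0 * math.exp(0.040)
        assert zhang_stress(2 * 1.71, params) == pytest.approx(expected)
        assert zhang_initial_modulus(params) == pytest.approx(7.15)

    def test_compression_clamp_all_laws(self):
        L = 1.0
        assert tang_stress(L, TangLawParams(10.0, 2.0)) == 0.0
        assert zhang_stress(L, ZhangLawParams(10.0, 1.0, 1.0, 2.0)) == 0.0
        assert fibre_stress(L, FibreLawParams(10.0, 2.0)) == 0.0


class TestECMUniaxial:
    def test_zero_at_reference(self):
        ecm = ECMParams(beta=3.0, k_v=0.0, L0b=1.6)
        assert ecm_uniaxial_stress(1.6, ecm) == 0.0

    def test_direct_evaluation(self):
        # beta = 1, lambda = 1.1: I1 (lam - 1/lam^2) exp(I1 - 3)
        lam = 1.1
        i1 = lam ** 2 + 2 / lam
        expected = i1 * (lam - lam ** -2) * math.exp(i1 - 3)
        assert ecm_uniaxial_stress(1.1, ECMParams(1.0, 0.0, 1.0)) == \
            pytest.approx(expected)
        assert expected == pytest.approx(0.852, rel=1e-3)

    def test_monotone_increasing_in_tension(self):
        ecm = ECMParams(beta=7.3, k_v=0.0, L0b=1.2)
        grid = np.linspace(1.2, 3 * 1.2, 500)
        values = ecm_uniaxial_stress(grid, ecm)
        assert np.all(np.diff(values) > 0)

    def test_negative_below_reference(self):
        ecm = ECMParams(beta=1.0, k_v=0.0, L0b=2.0)
        assert ecm_uniaxial_stress(1.8, ecm) < 0.0

    def test_mpa_conversion(self):
        ecm = ECMParams.from_mpa(beta_mpa=168.55, k_v_mpa=0.0, L0b=1.60)
        assert ecm.beta == pytest.approx(168550.0)


class TestECMTensor:
    def test_identity_gives_zero_stress(self):
        ecm = ECMParams(beta=4.0, k_v=11.0, L0b=1.6)
        assert np.allclose(ecm_stress_tensor(np.eye(3), ecm), 0.0)

    def test_volumetric_term_vanishes_when_isochoric(self):
        # same deviatoric deformation, two bulk moduli: identical stress
        F = uniaxial_incompressible_F(1.4)
        a = ecm_stress_tensor(F, ECMParams(2.0, 0.0, 1.6))
        b = ecm_stress_tensor(F, ECMParams(2.0, 1e4, 1.6))
        assert np.array_equal(a, b)

    def test_uniaxial_component_family(self):
        # (1,1) component under isochoric uniaxial stretch is proportional
        # to (lam - 1/lam^2) exp(I1 - 3); independent tensor-algebra oracle
        beta = 2.5
        ecm = ECMParams(beta, 7.0, 1.0)
        for lam in (1.1, 1.3, 1.7):
            F = uniaxial_incompressible_F(lam)
            i1 = lam ** 2 + 2 / lam
            oracle = beta * i1 * math.exp(i1 - 3) * (2.0 / 3.0) * (lam - lam ** -2)
            assert ecm_stress_tensor(F, ecm)[0, 0] == pytest.approx(oracle)

    def test_tensor_scalar_reduction_ratio(self):
        # the printed scalar law omits the deviatoric 2/3 of the tensor law
        ecm = ECMParams(beta=3.7, k_v=123.0, L0b=1.0)
        for lam in np.linspace(1.05, 2.5, 9):
            t11 = ecm_stress_tensor(uniaxial_incompressible_F(lam), ecm)[0, 0]
            scalar = ecm_uniaxial_stress(lam, ecm)
            assert t11 / scalar == pytest.approx(UNIAXIAL_TENSOR_SCALAR_RATIO)

    def test_deformation_state_invariants(self):
        state = DeformationState(F=np.diag([2.0, 1.0, 1.0]))
        assert state.J == pytest.approx(2.0)
        assert state.I1 == pytest.approx(6.0)
        assert state.I1_bar == pytest.approx(2.0 ** (-2 / 3) * 6.0)
        with pytest.raises(DomainError):
            DeformationState(F=np.diag([-1.0, 1.0, 1.0]))


class TestBundleComposition:
    def test_degenerate_compositions(self, pooled_fibre_params):
        ecm = ECMParams(beta=5.0, k_v=0.0, L0b=1.6)
        pure_ecm = BundleModel(pooled_fibre_params, pooled_fibre_params, ecm,
                               VolumeFractions(0.0, 0.0, 1.0))
        comp = bundle_uniaxial_stress(3.0, pure_ecm)
        assert comp.total == pytest.approx(ecm_uniaxial_stress(3.0, ecm))
        pure_fibre = BundleModel(pooled_fibre_params, pooled_fibre_params, ecm,
                                 VolumeFractions(0.5, 0.5, 0.0))
        assert bundle_uniaxial_stress(2.44, pure_fibre).total == 0.0

    def test_addends_sum_exactly(self, bundle_model):
        grid = np.linspace(2.2, 4.2, 40)
        comp = bundle_uniaxial_stress(grid, bundle_model)
        assert np.array_equal(comp.total, comp.fast + comp.slow + comp.ecm)

    def test_fibre_part_scale(self, bundle_model):
        comp = bundle_uniaxial_stress(2.5, bundle_model)
        assert comp.fast + comp.slow == pytest.approx(0.3, abs=0.05)

    def test_volume_fraction_validation(self):
        with pytest.raises(DomainError):
            VolumeFractions(0.5, 0.5, 0.5)
        with pytest.raises(DomainError):
            VolumeFractions(-0.1, 0.6, 0.5)


class TestBundleTensor:
    def test_identity_gives_zero(self, bundle_model):
        assert np.allclose(bundle_stress_tensor(np.eye(3), bundle_model), 0.0)

    def test_uniaxial_matches_scalar_fibre_addends(self, pooled_fibre_params,
                                                   study_fractions):
        # common reference length for fibres and ECM makes the tensor and
        # scalar decompositions directly comparable
        ecm = ECMParams(beta=2.0, k_v=500.0, L0b=2.44)
        model = BundleModel(pooled_fibre_params, pooled_fibre_params, ecm,
                            study_fractions)
        lam = 1.35
        L = lam * ecm.L0b
        P = bundle_stress_tensor(uniaxial_incompressible_F(lam), model)
        comp = bundle_uniaxial_stress(L, model)
        fibre_tensor_part = P[0, 0] - study_fractions.alpha_c * \
            ecm_stress_tensor(uniaxial_incompressible_F(lam), ecm)[0, 0]
        assert fibre_tensor_part == pytest.approx(comp.fast + comp.slow)

    def test_fibres_orthogonal_to_stretch_do_not_load(self, pooled_fibre_params):
        # stretch along x, fibres along y: fibre stretch < 1, term clamps
        ecm = ECMParams(beta=2.0, k_v=0.0, L0b=2.44)
        model = BundleModel(pooled_fibre_params, pooled_fibre_params, ecm,
                            VolumeFractions(0.5, 0.5, 0.0),
                            fibre_direction=(0.0, 1.0, 0.0))
        P = bundle_stress_tensor(uniaxial_incompressible_F(1.5), model)
        assert np.allclose(P, 0.0)
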