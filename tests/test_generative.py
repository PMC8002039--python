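"""Bilinear neural dynamics, hemodynamics and BOLD simulation."""

import numpy as np
import pytest

import fesdcm as fd
from fesdcm.generative import (
    SystemState,
    pack_parameters,
    parameter_names,
    simulate_bold_reference,
    unpack_parameters,
)
from fesdcm.paradigm import input_matrix


def two_region_model(A, C):
    return fd.ConnectivityModel(
        A=np.asarray(A, float),
        B=np.zeros((1, 2, 2)),
        C=np.asarray(C, float),
        regions=("R1", "R2"),
        inputs=("u1",),
        modulatory=("u1",),
        a_mask=np.ones((2, 2), bool),
        b_mask=np.zeros((1, 2, 2), bool),
        c_mask=np.ones((2, 1), bool),
    )


class TestNeuralDerivative:
    def test_rest_fixed_point(self):
        m = two_region_model([[-1, 0], [0.5, -1]], [[1], [0]])
        assert np.allclose(fd.neural_derivative([0, 0], [0], m), 0)

    def test_driving_term_only(self):
        m = two_region_model([[-1, 0], [0.5, -1]], [[1], [0]])
        assert np.allclose(fd.neural_derivative([0, 0], [2.0], m), [2.0, 0.0])

    def test_hand_evaluated_example(self):
        m = two_region_model([[-1, 0], [0.5, -1]], [[1], [0]])
        dx = fd.neural_derivative([0.2, 0.1], [1.0], m)
        assert np.allclose(dx, [0.8, 0.0])

    def test_dimension_mismatch_rejected(self):
        m = two_region_model([[-1, 0], [0.5, -1]], [[1], [0]])
        with pytest.raises(ValueError, match="mismatch"):
            fd.neural_derivative([0.2, 0.1, 0.3], [1.0], m)


class TestHemodynamics:
    def test_rest_is_fixed_point(self, hemo):
        state = SystemState.rest(4)
        for d in fd.hemodynamic_derivative(state, hemo):
            assert np.allclose(d, 0)

    def test_neural_drive_raises_vasodilatory_signal(self, hemo):
        state = SystemState.rest(4)
        state.x = np.full(4, 0.3)
        ds, *_ = fd.hemodynamic_derivative(state, hemo)
        assert np.all(ds > 0)

    def test_bold_zero_at_rest(self, hemo):
        assert np.allclose(fd.bold_observe(SystemState.rest(4), hemo), 0)

    def test_bold_ignores_flow_perturbation(self, hemo):
        state = SystemState.rest(4)
        state.log_f = np.full(4, 0.3)
        assert np.allclose(fd.bold_observe(state, hemo), 0)

    def test_impulse_response_peaks_4_to_6_s(self, hemo):
        # brief neural impulse via a 0.5 s unit drive into one region
        m = two_region_model([[-1, 0], [0, -1]], [[1], [0]])
        p = fd.build_paradigm(0.1, 30.0, 9.0, 21.0, 1, seed=0,
                              microtime_dt=0.05)
        U = np.zeros((p.n_bins, 1))
        U[: int(0.5 / p.microtime_dt)] = 1.0
        Y = fd.simulate_bold(m, hemo, p, U)
        t_peak = np.argmax(Y[0]) * p.tr
        assert 4.0 <= t_peak <= 6.0
        # positive peak then undershoot
        assert Y[0].max() > 0
        assert Y[0].min() < 0


class TestStability:
    def test_negative_identity_stable(self):
        ok, _ = fd.check_stability(-np.eye(3))
        assert ok

    def test_positive_scalar_unstable(self):
        ok, report = fd.check_stability(np.array([[0.1]]))
        assert not ok
        assert "eigenvalue" in report

    def test_diagonally_dominant_random_stable(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            A = rng.uniform(-0.2, 0.2, (4, 4))
            np.fill_diagonal(A, -1.0)
            assert fd.check_stability(A)[0]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            fd.check_stability(np.zeros((2, 3)))


class TestSimulateBold:
    def test_no_input_no_response(self, short_paradigm, hemo, control_model):
        from dataclasses import replace

        m = replace(
            control_model,
            C=np.zeros_like(control_model.C),
            a_mask=control_model.a_mask.copy(),
            b_mask=control_model.b_mask.copy(),
            c_mask=np.zeros_like(control_model.c_mask),
        )
        Y = fd.simulate_bold(m, hemo, short_paradigm,
                             fd.build_inputs(short_paradigm))
        assert np.allclose(Y, 0)

    def test_standard_run_yields_200_volumes(self, standard_paradigm, hemo,
                                             control_model):
        Y = fd.simulate_bold(control_model, hemo, standard_paradigm,
                             fd.build_inputs(standard_paradigm))
        assert Y.shape == (4, 200)

    def test_noise_sd_matches_request(self, short_paradigm, hemo,
                                      control_model):
        inputs = fd.build_inputs(short_paradigm)
        clean = fd.simulate_bold(control_model, hemo, short_paradigm, inputs)
        noisy = fd.simulate_bold(control_model, hemo, short_paradigm, inputs,
                                 noise_sd=1.0, seed=0)
        resid_sd = (noisy - clean).std()
        assert abs(resid_sd - 1.0) < 0.1

    def test_deterministic_given_seed(self, short_paradigm, hemo,
                                      control_model):
        inputs = fd.build_inputs(short_paradigm)
        a = fd.simulate_bold(control_model, hemo, short_paradigm, inputs,
                             noise_sd=0.5, seed=42)
        b = fd.simulate_bold(control_model, hemo, short_paradigm, inputs,
                             noise_sd=0.5, seed=42)
        assert np.array_equal(a, b)

    def test_unstable_model_rejected_with_eigenvalue(self, short_paradigm,
                                                     hemo, control_model):
        from dataclasses import replace

        A = control_model.A.copy()
        np.fill_diagonal(A, 0.2)
        bad = replace(control_model, A=A,
                      a_mask=control_model.a_mask.copy(),
                      b_mask=control_model.b_mask.copy(),
                      c_mask=control_model.c_mask.copy())
        with pytest.raises(ValueError):
            fd.simulate_bold(bad, hemo, short_paradigm,
                             fd.build_inputs(short_paradigm))

    def test_kernel_matches_reference_integrator(self, short_paradigm, hemo,
                                                 control_model):
        inputs = fd.build_inputs(short_paradigm)
        fast = fd.simulate_bold(control_model, hemo, short_paradigm, inputs)
        ref = simulate_bold_reference(control_model, hemo, short_paradigm,
                                      inputs)
        assert np.max(np.abs(fast - ref)) < 1e-10

    def test_modulation_equals_shifted_endogenous(self, short_paradigm, hemo,
                                                  control_model):
        # with u_E held at 1, simulate(A, B) == simulate(A+B, 0) exactly
        from dataclasses import replace

        U = input_matrix(fd.build_inputs(short_paradigm)).copy()
        U[:, 1] = 1.0
        m1 = control_model
        m2 = replace(
            control_model,
            A=control_model.A + control_model.B[0],
            B=np.zeros_like(control_model.B),
            a_mask=np.ones_like(control_model.a_mask),
            b_mask=np.zeros_like(control_model.b_mask),
            c_mask=control_model.c_mask.copy(),
        )
        Y1 = fd.simulate_bold(m1, hemo, short_paradigm, U)
        Y2 = fd.simulate_bold(m2, hemo, short_paradigm, U)
        assert np.max(np.abs(Y1 - Y2)) < 1e-12

    def test_linearity_in_drive_for_small_inputs(self, short_paradigm, hemo):
        m = two_region_model([[-1, 0], [0.4, -1]], [[0.01], [0.0]])
        from dataclasses import replace

        m2 = replace(m, C=m.C * 2, c_mask=m.c_mask.copy(),
                     a_mask=m.a_mask.copy(), b_mask=m.b_mask.copy())
        U = np.ones((short_paradigm.n_bins, 1))
        Y1 = fd.simulate_bold(m, hemo, short_paradigm, U)
        Y2 = fd.simulate_bold(m2, hemo, short_paradigm, U)
        assert np.allclose(Y2, 2 * Y1, rtol=0.05, atol=1e-4)

    def test_integration_accuracy_halved_step(self, hemo, control_model):
        p1 = fd.build_paradigm(seed=1, microtime_dt=3 / 16)
        p2 = fd.build_paradigm(seed=1, microtime_dt=3 / 32)
        Y1 = fd.simulate_bold(control_model, hemo, p1, fd.build_inputs(p1))
        Y2 = fd.simulate_bold(control_model, hemo, p2, fd.build_inputs(p2))
        rel = np.linalg.norm(Y1 - Y2) / np.linalg.norm(Y2)
        assert rel < 1e-3


class TestParameterPacking:
    def test_round_trip(self, control_model):
        theta = pack_parameters(control_model)
        rebuilt = unpack_parameters(theta, control_model)
        assert np.array_equal(rebuilt.A, control_model.A)
        assert np.array_equal(rebuilt.B, control_model.B)
        assert np.array_equal(rebuilt.C, control_model.C)

    def test_names_follow_target_source_convention(self, control_model):
        names = parameter_names(control_model)
        assert len(names) == len(pack_parameters(control_model))
        assert "A:SMA->M1" in names
        assert "C:V->M1" in names

    def test_json_round_trip(self, control_model):
        again = fd.ConnectivityModel.from_json(control_model.to_json())
        assert np.array_equal(again.A, control_model.A)
        assert np.array_equal(again.b_mask, control_model.b_mask)
        assert again.regions == control_model.regions
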