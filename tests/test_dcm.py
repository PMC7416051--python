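"""Bilinear neural dynamics and balloon hemodynamics against closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from meridian import dcm, synthetic
from meridian.constants import BINS_PER_TR, NODES


def simple_model(a=None, b=None, c=None):
    n = len(NODES)
    A = np.diag(np.full(n, -0.5)) if a is None else a
    B = np.zeros((4, n, n)) if b is None else b
    C = np.zeros((n, 4)) if c is None else c
    return dcm.DCMModel(a=A, b=B, c=C)


def single_impulse_inputs(stream=0, bin_index=50, n_vol=40, tr=2.2):
    T = n_vol * BINS_PER_TR
    u = np.zeros((T, 4))
    dt = tr / BINS_PER_TR
    u[bin_index, stream] = 1.0 / dt
    return dcm.InputSet(
        u=u, dt=dt, tr=tr, bins_per_tr=BINS_PER_TR,
        run_slices=((0, T),), volumes_per_run=(n_vol,),
    )


class TestNeuralDerivative:
    def test_fixed_point_at_origin(self):
        m = simple_model()
        assert np.allclose(dcm.neural_derivative(np.zeros(6), np.zeros(4), m), 0.0)

    def test_linear_reduction_hand_computed(self):
        # 2-active-node case embedded in the 6-node model
        a = np.diag(np.full(6, -0.5))
        a[0, 1] = 0.3
        c = np.zeros((6, 4))
        c[0, 0] = 1.0
        m = simple_model(a=a, c=c)
        z = np.zeros(6)
        z[0], z[1] = 1.0, 2.0
        u = np.array([0.5, 0.0, 0.0, 0.0])
        expected0 = -0.5 * 1.0 + 0.3 * 2.0 + 1.0 * 0.5
        out = dcm.neural_derivative(z, u, m)
        assert np.isclose(out[0], expected0)
        assert np.isclose(out[1], -1.0)

    def test_bilinear_term_is_exactly_b_z(self, rng):
        b = np.zeros((4, 6, 6))
        b[0, 2, 4] = 0.7
        b[0, 1, 1] = -0.2
        m = simple_model(b=b)
        z = rng.normal(size=6)
        u1 = np.array([1.0, 0, 0, 0])
        diff = dcm.neural_derivative(z, u1, m) - dcm.neural_derivative(z, np.zeros(4), m)
        assert np.allclose(diff, b[0] @ z, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            dcm.neural_derivative(np.zeros(5), np.zeros(4), simple_model())


class TestIntegrateNeural:
    def test_zero_inputs_identically_zero(self):
        m = simple_model()
        quiet = dcm.InputSet(
            u=np.zeros((720, 4)), dt=2.2 / 36, tr=2.2, bins_per_tr=36,
            run_slices=((0, 720),), volumes_per_run=(20,),
        )
        assert np.allclose(dcm.integrate_neural(m, quiet), 0.0)

    def test_matches_matrix_exponential_closed_form(self):
        """With B = 0 and piecewise-constant u the exact solution per bin is
        z -> e^{A dt} z + A^{-1}(e^{A dt} - I) C u."""
        a = np.diag(np.full(6, -0.5))
        a[1, 0] = 0.2
        c = np.zeros((6, 4))
        c[:, 0] = 0.3
        m = simple_model(a=a, c=c)
        inputs = single_impulse_inputs(stream=0, bin_index=5, n_vol=10)
        traj = dcm.integrate_neural(m, inputs)
        dt = inputs.dt
        ea = expm(a * dt)
        z = np.zeros(6)
        exact = np.zeros_like(traj)
        for t in range(inputs.u.shape[0]):
            exact[t] = z
            u = inputs.u[t]
            z = ea @ z + np.linalg.solve(a, (ea - np.eye(6)) @ (c @ u))
        scale = np.abs(exact).max()
        assert np.max(np.abs(traj - exact)) / scale < 1e-6

    def test_mono_exponential_decay(self):
        m = simple_model(c=np.eye(6, 4) * 1.0)
        inputs = single_impulse_inputs(stream=0, bin_index=0, n_vol=20)
        traj = dcm.integrate_neural(m, inputs)
        dt = inputs.dt
        t = np.arange(1, 200) * dt
        # after the unit-area impulse, node 0 decays as z1 * exp(-0.5 (t - dt))
        z1 = traj[1, 0]
        expected = z1 * np.exp(-0.5 * (t - dt))
        assert np.allclose(traj[1:200, 0], expected, rtol=1e-5)

    def test_halving_dt_converged(self):
        a = np.diag(np.full(6, -0.5))
        a[0, 1] = a[1, 0] = 0.2
        c = np.full((6, 4), 0.2)
        m = simple_model(a=a, c=c)
        inputs = single_impulse_inputs(stream=1, bin_index=8, n_vol=10)
        traj = dcm.integrate_neural(m, inputs)
        # identical forcing on a twice-finer grid: the one-bin impulse
        # becomes two half-bins at the same height
        T2 = inputs.u.shape[0] * 2
        u2 = np.zeros((T2, 4))
        u2[16, 1] = u2[17, 1] = 1.0 / inputs.dt
        inputs2 = dcm.InputSet(
            u=u2, dt=inputs.dt / 2, tr=inputs.tr, bins_per_tr=72,
            run_slices=((0, T2),), volumes_per_run=(10,),
        )
        traj2 = dcm.integrate_neural(m, inputs2)
        scale = np.abs(traj).max()
        assert np.max(np.abs(traj - traj2[::2])) / scale < 1e-6


class TestHemodynamics:
    def test_resting_state_zero_bold(self):
        z = np.zeros((200, 6))
        bold = dcm.hemodynamic_observe(z, dcm.HemodynamicParams(), dt=2.2 / 36)
        assert np.allclose(bold, 0.0, atol=1e-14)

    def test_pulse_response_shape_and_peak_lag(self):
        dt = 2.2 / 36
        T = int(30 / dt)
        z = np.zeros((T, 1))
        z[: int(0.5 / dt)] = 1.0  # brief neural pulse
        bold = dcm.hemodynamic_observe(z, dcm.HemodynamicParams(), dt=dt)[:, 0]
        peak = np.argmax(bold)
        assert 3.0 < peak * dt < 7.0
        assert bold[peak] > 0
        assert abs(bold[-1]) < 0.05 * bold[peak]  # returns to baseline

    def test_near_linearity_for_small_pulses(self):
        dt = 2.2 / 36
        T = int(30 / dt)
        z = np.zeros((T, 1))
        z[: int(0.25 / dt)] = 0.05
        small = dcm.hemodynamic_observe(z, dcm.HemodynamicParams(), dt=dt)[:, 0]
        double = dcm.hemodynamic_observe(2 * z, dcm.HemodynamicParams(), dt=dt)[:, 0]
        ratio = double.max() / small.max()
        assert abs(ratio - 2.0) < 0.2


class TestSimulateBold:
    def test_output_length_and_determinism(self):
        truth = synthetic.default_ground_truth(snr=None, noise_sd=0.0)
        inputs = single_impulse_inputs(stream=0, bin_index=40, n_vol=30)
        out1 = dcm.simulate_bold(truth.model, inputs)
        out2 = dcm.simulate_bold(truth.model, inputs)
        assert out1.shape == (30, 6)
        assert np.array_equal(out1, out2)

    def test_time_shift_equivariance(self):
        truth = synthetic.default_ground_truth(snr=None, noise_sd=0.0)
        n_vol = 60
        i1 = single_impulse_inputs(stream=0, bin_index=5 * 36, n_vol=n_vol)
        i2 = single_impulse_inputs(stream=0, bin_index=6 * 36, n_vol=n_vol)
        y1 = dcm.simulate_bold(truth.model, i1)
        y2 = dcm.simulate_bold(truth.model, i2)
        # shifting the impulse by one TR shifts the output by one volume
        assert np.allclose(y1[10:50], y2[11:51], atol=1e-10)

    def test_b2_b4_structurally_zero_enforced(self):
        b = np.zeros((4, 6, 6))
        b[1, 0, 1] = 0.5
        with pytest.raises(ValueError, match="structurally zero"):
            simple_model(b=b)

    def test_stability_guard_names_eigenvalue(self):
        a = np.diag(np.full(6, -0.5))
        a[0, 0] = 0.2
        m = simple_model(a=a)
        with pytest.raises(ValueError, match="eigenvalue"):
            dcm.simulate_bold(m, single_impulse_inputs())

    def test_model_json_roundtrip(self, tmp_path):
        truth = synthetic.default_ground_truth(snr=None)
        path = tmp_path / "model.json"
        truth.model.save(path)
        back = dcm.DCMModel.load(path)
        assert np.allclose(back.a, truth.model.a)
        assert np.allclose(back.b, truth.model.b)


class TestIntegratorBackends:
    def test_numpy_fallback_matches_compiled_kernel(self, desk_design_pair, desk_spec):
        """The pure-numpy integrator and the compiled kernel share the same
        scheme and must agree to machine precision."""
        if not dcm._HAVE_NUMBA:
            pytest.skip("numba unavailable; only one backend to test")
        truth = synthetic.default_ground_truth(snr=None, noise_sd=0.0)
        events = pd.concat(desk_design_pair, ignore_index=True)
        inputs = dcm.build_inputs(
            events, tr=desk_spec.tr_seconds,
            volumes_per_run=[desk_spec.volumes_per_run] * 2,
        )
        kappa, gamma, tau, alpha, rho = truth.model.hemo.as_arrays()
        hemo_arrays = tuple(h[None, :] for h in (kappa, gamma, tau, alpha, rho))
        obs = (truth.model.hemo.v0, truth.model.hemo.k1,
               truth.model.hemo.k2, truth.model.hemo.k3)
        args = (truth.model.a[None], truth.model.b[None], truth.model.c[None],
                hemo_arrays, inputs)
        out_jit = dcm.simulate_bold_batch(*args, hemo_obs=obs)
        try:
            dcm._HAVE_NUMBA = False
            out_np = dcm.simulate_bold_batch(*args, hemo_obs=obs)
        finally:
            dcm._HAVE_NUMBA = True
        err = np.max(np.abs(out_jit - out_np)) / np.abs(out_jit).max()
        assert err < 1e-12


class TestBuildInputs:
    def test_streams_disjoint_and_at_target_onsets(self, desk_design_pair, desk_spec):
        events = pd.concat(desk_design_pair, ignore_index=True)
        inputs = dcm.build_inputs(
            events, tr=desk_spec.tr_seconds,
            volumes_per_run=[desk_spec.volumes_per_run] * 2,
        )
        assert inputs.n_impulses == len(events)
        # each impulse bin feeds exactly one stream
        assert (np.count_nonzero(inputs.u, axis=1) <= 1).all()
        # horizontal run occupies streams 1-2 only, vertical 3-4
        h = inputs.u[slice(*inputs.run_slices[0])]
        v = inputs.u[slice(*inputs.run_slices[1])]
        assert np.count_nonzero(h[:, 2:]) == 0
        assert np.count_nonzero(v[:, :2]) == 0

    def test_unit_area_impulses(self, desk_design_pair, desk_spec):
        events = pd.concat(desk_design_pair, ignore_index=True)
        inputs = dcm.build_inputs(
            events, tr=desk_spec.tr_seconds,
            volumes_per_run=[desk_spec.volumes_per_run] * 2,
        )
        vals = inputs.u[inputs.u != 0]
        assert np.allclose(vals * inputs.dt, 1.0)

    def test_onset_beyond_run_raises(self, desk_spec):
        events = pd.DataFrame(
            {"run": ["horizontal"], "cueing": ["valid"], "onset": [desk_spec.run_duration + 5]}
        )
        with pytest.raises(ValueError, match="beyond"):
            dcm.build_inputs(events, tr=desk_spec.tr_seconds,
                             volumes_per_run=[desk_spec.volumes_per_run] * 2)
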