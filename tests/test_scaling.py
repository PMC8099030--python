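"""Scaling transformations: closed forms, composition, connectivity laws."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaledcm.dcm import DCMModel, integrate_model
from scaledcm.scaling import (
    ScaleParams,
    alpha_from_z,
    kepler_alpha,
    scale_connectivity,
    scale_inputs,
    scale_trajectory,
    z_from_alpha,
)
from scaledcm.timeseries import InputSeries, Timeseries


def _sine_traj(freq=1.0, dt=0.01, T=6000):
    t = np.arange(T) * dt
    return Timeseries(np.vstack([np.cos(freq * t), np.sin(freq * t)]), dt=dt)


class TestScaleTrajectory:
    def test_identity_at_b1(self):
        traj = _sine_traj()
        for alpha in (-1.5, -1.0, 0.0):
            out = scale_trajectory(traj, ScaleParams(b=1.0, alpha=alpha))
            assert np.allclose(out.values, traj.values, atol=1e-12)

    def test_circular_orbit_closed_form(self):
        """b=4, alpha=-3/2: radius x4, period x8 (the Kepler relation)."""
        traj = _sine_traj(freq=1.0, dt=0.01, T=6000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = scale_trajectory(traj, ScaleParams(b=4.0, alpha=-1.5))
        t = out.times
        assert np.abs(out.values[0] - 4 * np.cos(t / 8)).max() < 1e-6
        assert np.abs(out.values[1] - 4 * np.sin(t / 8)).max() < 1e-6

    def test_truncation_warned_not_extrapolated(self):
        traj = _sine_traj(T=500)
        with pytest.warns(UserWarning, match="truncated"):
            out = scale_trajectory(traj, ScaleParams(b=2.0, alpha=1.0, beta=0.0))
        assert out.n_samples < traj.n_samples

    def test_beta_amplitude_exponent(self):
        traj = _sine_traj(T=500)
        out = scale_trajectory(traj, ScaleParams(b=2.0, alpha=0.0, beta=1.0))
        assert np.allclose(out.values, 4 * traj.values, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        b1=st.floats(1.0, 2.0),
        b2=st.floats(1.0, 2.0),
        alpha=st.floats(-2.0, -0.5),
    )
    def test_composition_property(self, b1, b2, alpha):
        """Scaling by (b1, a) then (b2, a) equals scaling by (b1*b2, a)."""
        traj = _sine_traj(dt=0.01, T=4000)
        two = scale_trajectory(
            scale_trajectory(traj, ScaleParams(b=b1, alpha=alpha)),
            ScaleParams(b=b2, alpha=alpha),
        )
        one = scale_trajectory(traj, ScaleParams(b=b1 * b2, alpha=alpha))
        n = min(two.n_samples, one.n_samples) - 5  # stay off truncation edges
        assert np.abs(two.values[:, :n] - one.values[:, :n]).max() < 1e-6


class TestScaleInputs:
    def test_zero_maps_to_zero(self):
        u = InputSeries.zeros(1, 100, 0.1)
        out = scale_inputs(u, ScaleParams(b=3.0, alpha=-1.0))
        assert not out.values.any()

    def test_pulse_time_substitution(self):
        dt = 0.01
        vals = np.zeros((1, 1000))
        vals[0, 200] = 1.0  # pulse at t = 2
        out = scale_inputs(InputSeries(vals, dt=dt), ScaleParams(b=2.0, alpha=-1.0))
        # v(t/2): the pulse appears at t = 4
        assert abs(out.values[0, 350:450].argmax() + 350 - 400) <= 1

    def test_sinusoid_frequency_shift_fft(self):
        dt, T = 0.01, 8192
        f0 = 2.0  # Hz
        t = np.arange(T) * dt
        u = InputSeries(np.sin(2 * np.pi * f0 * t)[None, :], dt=dt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = scale_inputs(u, ScaleParams(b=2.0, alpha=-1.0))
        spec = np.abs(np.fft.rfft(out.values[0]))
        freqs = np.fft.rfftfreq(out.n_samples, dt)
        assert abs(freqs[spec.argmax()] - f0 * 2.0**-1.0) < 0.05


class TestScaleConnectivity:
    def test_identity_at_b1(self):
        A = np.array([[-1.0, 0.5], [0.2, -1.0]])
        C = np.array([[1.0], [0.0]])
        As, Cs = scale_connectivity(A, C, ScaleParams(b=1.0, alpha=-1.5))
        assert np.allclose(As, A) and np.allclose(Cs, C)

    def test_uniform_arithmetic(self):
        A = np.array([[-1.0, 0.5], [0.2, -1.0]])
        As, _ = scale_connectivity(A, None, ScaleParams(b=4.0, alpha=-1.5))
        assert np.allclose(As, [[-0.125, 0.0625], [0.025, -0.125]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.5, 3.0),
        alpha=st.floats(-2.0, 0.0),
        seed=st.integers(0, 100),
    )
    def test_elementwise_reduces_to_uniform(self, b, alpha, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3))
        C = rng.standard_normal((3, 3))
        uni = scale_connectivity(A, C, ScaleParams(b=b, alpha=alpha))
        elem = scale_connectivity(
            A, C, ScaleParams(b=b, alpha=alpha, b_per_node=[b, b, b])
        )
        assert np.allclose(uni[0], elem[0], atol=1e-12)
        assert np.allclose(uni[1], elem[1], atol=1e-12)

    def test_connectivity_composition(self):
        A = np.random.default_rng(4).standard_normal((2, 2))
        one, _ = scale_connectivity(A, None, ScaleParams(b=6.0, alpha=-1.2))
        step, _ = scale_connectivity(A, None, ScaleParams(b=2.0, alpha=-1.2))
        two, _ = scale_connectivity(step, None, ScaleParams(b=3.0, alpha=-1.2))
        assert np.allclose(one, two, atol=1e-9)


class TestExponentMaps:
    def test_alpha_z_duality(self):
        assert alpha_from_z(1.5) == -1.5
        assert alpha_from_z(0.0) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(z=st.floats(-10, 10, allow_nan=False))
    def test_round_trip_involution(self, z):
        assert z_from_alpha(alpha_from_z(z)) == z

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            alpha_from_z(np.inf)


class TestKeplerAlpha:
    def test_value(self):
        assert kepler_alpha() == -1.5

    def test_residual_exponent_vanishes(self):
        a = kepler_alpha()
        for b in (2.0, 10.0):
            assert b ** (2 * a + 3) == 1.0

    def test_unique_on_grid_by_dynamics_residual(self):
        """Only alpha=-3/2 keeps the rescaled orbit on Newton's flow.

        Oracle: finite-difference acceleration of the scaled series compared
        with the inverse-square force it should equal.
        """
        dt = 0.002
        t = np.arange(0, 30, dt)
        # eccentric Kepler orbit, GM=1, integrated accurately
        from scipy.integrate import solve_ivp

        def rhs(_, s):
            x, y, vx, vy = s
            r3 = (x * x + y * y) ** 1.5
            return [vx, vy, -x / r3, -y / r3]

        sol = solve_ivp(
            rhs, (0, t[-1]), [1.0, 0.0, 0.0, 1.1], t_eval=t, rtol=1e-11, atol=1e-12
        )
        traj = Timeseries(sol.y[:2], dt=dt)
        residuals = {}
        for alpha in (-2.5, -2.0, -1.5, -1.0, -0.5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = scale_trajectory(traj, ScaleParams(b=2.0, alpha=alpha))
            xy = s.values[:, 1:-1]
            acc = (s.values[:, 2:] - 2 * s.values[:, 1:-1] + s.values[:, :-2]) / dt**2
            r = np.linalg.norm(xy, axis=0)
            force = -xy / r**3
            scale = np.linalg.norm(force, axis=0).mean()
            residuals[alpha] = np.linalg.norm(acc - force, axis=0).mean() / scale
        best = min(residuals, key=residuals.get)
        assert best == kepler_alpha()
        assert residuals[-1.5] < 1e-3


class TestEquationClosure:
    def test_scaled_model_reproduces_scaled_trajectory(self):
        """Integrating (b^a A, b^(a+1) C) with v(b^a t) from b*x0 equals the
        scaled solution of the original system."""
        A = np.array([[-1.0, 0.6], [-0.4, -0.8]])
        C = np.array([[0.5], [0.0]])
        dt, T = 0.01, 3000
        u = InputSeries(
            np.sin(2 * np.pi * 0.2 * np.arange(T) * dt)[None, :], dt=dt
        )
        x0 = np.array([1.0, -0.5])
        sol = integrate_model(DCMModel(A, C), x0, u, T, dt)
        p = ScaleParams(b=2.0, alpha=-1.5)
        As, Cs = scale_connectivity(A, C, p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            us = scale_inputs(u, p)
            target = scale_trajectory(sol, p)
        again = integrate_model(
            DCMModel(As, Cs), x0 * p.b, us, target.n_samples, dt
        )
        err = np.abs(again.values - target.values).max()
        assert err < 5e-3  # interpolation tolerance
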