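"""Hill-type muscle-tendon model: curves, kinematics, dynamics, moments."""

import numpy as np
import pytest

from gaitmet import musclemodel as mmod
from gaitmet.musclemodel import (CurveSet, MuscleGeometry, MuscleParams,
                                 activation_dynamics, force_velocity,
                                 integrate_muscle_state, net_joint_moments)

FS = 200.0


def _params(**kw):
    base = dict(name="test", f_max=1000.0, l_opt=0.05, l_slack=0.20,
                pennation_opt=0.2, v_max=10.0, slow_twitch_ratio=0.5, width=0.6)
    base.update(kw)
    return MuscleParams(**base)


class TestMuscleParams:
    def test_table_values_loaded(self, model):
        p = model["params"]
        assert len(p) == 8
        assert p["soleus"].f_max == 6195
        assert p["soleus"].l_opt == 0.04
        assert p["soleus"].width == 0.80
        assert p["gluteus_maximus"].l_opt == 0.15

    @pytest.mark.parametrize("kw", [{"f_max": -1}, {"width": 1.5},
                                    {"slow_twitch_ratio": 1.2}, {"l_opt": 0}])
    def test_invariants(self, kw):
        with pytest.raises(ValueError):
            _params(**kw)


class TestCurves:
    def test_active_fl_peaks_at_optimum(self):
        assert mmod.active_force_length(1.0, 0.6) == 1.0
        assert mmod.active_force_length(1.6, 0.6) < 0.05

    def test_force_velocity_endpoints(self):
        curves = CurveSet()
        assert force_velocity(0.0, curves) == 1.0
        assert abs(force_velocity(-1.0, curves)) < 1e-12     # concentric at v_max
        assert force_velocity(5.0, curves) < curves.ecc_plateau

    def test_damped_inversion_is_inverse_of_curve(self):
        curves = CurveSet()
        for act_fl in (0.05, 0.3, 1.0):
            for vn_true in (-0.8, -0.2, 0.0, 0.3, 1.5):
                load = act_fl * force_velocity(vn_true, curves) \
                    + curves.fiber_damping * vn_true
                vn = float(mmod._inverse_fv_damped_vec(
                    np.array([load]), np.array([act_fl]), curves)[0])
                assert abs(vn - vn_true) < 1e-9

    def test_tendon_curve_anchors(self):
        curves = CurveSet()
        assert mmod.tendon_force_length(0.0, curves) == 0.0
        assert abs(mmod.tendon_force_length(curves.tendon_strain_iso, curves) - 1.0) < 1e-12
        assert mmod.tendon_force_length(-0.01, curves) == 0.0


class TestGeometry:
    def test_constant_arm_linear_length_change(self):
        geo = MuscleGeometry(reference_lengths={"m": 0.3},
                             moment_arm_coeffs={"m": {"ankle": [0.05]}})
        l0, _ = geo.muscle_tendon_length({"ankle": np.array([0.0])}, "m")
        l1, arms = geo.muscle_tendon_length({"ankle": np.array([0.4])}, "m")
        assert abs((l1[0] - l0[0]) - (-0.05 * 0.4)) < 1e-12
        assert arms["ankle"][0] == 0.05

    def test_length_derivative_is_negative_moment_arm(self, model):
        """d l_mt / d theta = -r to finite-difference accuracy (1e-6 m/rad)."""
        geo = model["geometry"]
        eps = 1e-6
        for muscle in geo.muscles:
            for joint in geo.joints_of(muscle):
                angles = {j: np.array([0.1]) for j in ("hip", "knee", "ankle")}
                lo, arms = geo.muscle_tendon_length(angles, muscle)
                angles[joint] = angles[joint] + eps
                hi, _ = geo.muscle_tendon_length(angles, muscle)
                deriv = (hi[0] - lo[0]) / eps
                assert abs(deriv + arms[joint][0]) < 1e-6

    def test_gastrocnemius_is_biarticular(self, model):
        joints = model["geometry"].joints_of("gastrocnemius_medialis")
        assert set(joints) == {"ankle", "knee"}

    def test_unknown_muscle_rejected(self, model):
        with pytest.raises(KeyError):
            model["geometry"].muscle_tendon_length({"ankle": np.zeros(1)}, "psoas")


class TestActivationDynamics:
    def test_constant_excitation_fixed_point(self):
        u = np.full(4000, 0.6)
        a = activation_dynamics(u, fs=FS)
        assert abs(a[-1] - 0.6) < 1e-6

    def test_step_response_time_constant(self):
        fs, tau = 1000.0, 0.010
        u = np.concatenate([np.zeros(100), np.ones(1000)])
        a = activation_dynamics(u, tau_act=tau, tau_deact=0.04, fs=fs)
        # the step acts from sample 100 on, so t = tau is reached at
        # sample 99 + tau*fs
        idx = 99 + int(tau * fs)
        assert abs(a[idx] - (1 - np.exp(-1))) < 1e-9

    def test_zero_stays_zero(self):
        assert np.all(activation_dynamics(np.zeros(100), fs=FS) == 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            activation_dynamics(np.zeros(10), tau_act=0.0, fs=FS)
        with pytest.raises(ValueError):
            activation_dynamics(np.full(10, 1.5), fs=FS)


class TestIntegration:
    def test_isometric_optimum_rigid_tendon(self):
        p = _params()
        l_iso = p.l_slack + p.l_opt * np.cos(p.pennation_opt)
        n = 50
        traj = integrate_muscle_state(np.ones(n), np.full(n, l_iso), p, FS,
                                      rigid_tendon=True)
        assert abs(traj.f_ce[25] - p.f_max) < 1e-6 * p.f_max
        assert abs(traj.f_tendon[25] - p.f_max * np.cos(p.pennation_opt)) \
            < 1e-6 * p.f_max
        np.testing.assert_allclose(traj.l_fiber, p.l_opt, rtol=1e-12)

    def test_rigid_tendon_fiber_length_exact(self):
        p = _params()
        n = 100
        l_mt = p.l_slack + p.l_opt * (1.0 + 0.1 * np.sin(np.linspace(0, 2 * np.pi, n)))
        traj = integrate_muscle_state(np.full(n, 0.5), l_mt, p, FS, rigid_tendon=True)
        h = p.l_opt * np.sin(p.pennation_opt)
        np.testing.assert_allclose(traj.l_fiber,
                                   np.sqrt((l_mt - p.l_slack) ** 2 + h**2),
                                   rtol=1e-12)

    def test_concentric_at_vmax_gives_near_zero_force(self):
        """At full shortening speed the contractile force vanishes (the Hill
        multiplier is zero and the damped force cannot push)."""
        assert abs(force_velocity(-1.0)) < 1e-12
        p = _params(pennation_opt=0.01)
        n, fs = 200, 1000.0
        v = -p.v_max * p.l_opt
        l_mt = p.l_slack + 1.4 * p.l_opt + v * np.arange(n) / fs
        traj = integrate_muscle_state(np.ones(n), l_mt, p, fs, rigid_tendon=True)
        window = slice(20, 110)  # fiber shortening at v_max, not yet clamped
        np.testing.assert_allclose(traj.v_fiber[window], v, rtol=1e-3)
        assert np.all(traj.f_ce[window] < 1e-6 * p.f_max)

    def test_equilibrium_residual_below_tolerance(self, model, simulated_states):
        for name, traj in simulated_states["states"].items():
            tol = 1e-3 * model["params"][name].f_max
            assert np.abs(traj.equilibrium_residual()).max() < tol

    def test_tendon_force_nonnegative(self, simulated_states):
        for traj in simulated_states["states"].values():
            assert traj.f_tendon.min() >= 0.0

    def test_stride_periodic_after_warmup(self, model, level_trial):
        """After two warm-up strides the trajectory repeats within 1%."""
        states, _, _ = mmod.simulate_trial(level_trial, model["params"],
                                           model["geometry"],
                                           curves=model["curves"])
        spp = level_trial.meta["samples_per_stride"]
        for name, traj in states.items():
            a = traj.l_fiber[spp:2 * spp]
            b = traj.l_fiber[2 * spp:3 * spp]
            scale = model["params"][name].l_opt
            assert np.abs(a - b).max() < 0.01 * scale

    def test_halving_step_size_converged(self, model, participant):
        from gaitmet import synthetic
        p = model["params"]["soleus"]
        geometry = model["geometry"]
        trial = synthetic.generate_trial(participant, synthetic.ConditionSpec(),
                                         n_strides=2, noise_sd=0.0, seed=1,
                                         sampling_rate=400.0)
        from gaitmet.signals import normalize_emg
        exc = normalize_emg(trial.emg_envelope["soleus"],
                            participant.mvc["soleus"])
        act = mmod.activation_dynamics(exc, fs=400.0)
        l_mt, _ = geometry.muscle_tendon_length(trial.joint_angles, "soleus")
        coarse = integrate_muscle_state(act[::2], l_mt[::2], p, 200.0)
        fine = integrate_muscle_state(act, l_mt, p, 400.0)
        diff = np.abs(fine.l_fiber[::2] - coarse.l_fiber) / p.l_opt
        assert diff.max() < 1e-3

    def test_misaligned_inputs_rejected(self):
        p = _params()
        with pytest.raises(ValueError):
            mmod.integrate_muscle_states(np.zeros((1, 10)), np.zeros((1, 9)), [p], FS)


class TestNetJointMoments:
    def _traj(self, n, force):
        z = np.zeros(n)
        return mmod.MuscleStateTrajectory(
            time=np.arange(n) / FS, activation=z, l_mt=z, l_fiber=z + 0.05,
            v_fiber=z, pennation=z, f_ce=z, f_tendon=np.full(n, force), f_pe=z)

    def test_single_muscle_constant_moment(self):
        geo = MuscleGeometry(reference_lengths={"m": 0.3},
                             moment_arm_coeffs={"m": {"ankle": [0.05]}})
        mom = net_joint_moments({"m": self._traj(10, 100.0)}, geo,
                                {j: np.zeros(10) for j in ("hip", "knee", "ankle")})
        np.testing.assert_allclose(mom["ankle"], 5.0)
        np.testing.assert_allclose(mom["knee"], 0.0)

    def test_antagonists_cancel(self):
        geo = MuscleGeometry(
            reference_lengths={"ext": 0.3, "flx": 0.3},
            moment_arm_coeffs={"ext": {"knee": [0.04]}, "flx": {"knee": [-0.04]}})
        mom = net_joint_moments({"ext": self._traj(5, 50.0), "flx": self._traj(5, 50.0)},
                                geo, {j: np.zeros(5) for j in ("hip", "knee", "ankle")})
        np.testing.assert_allclose(mom["knee"], 0.0, atol=1e-12)

    def test_lateral_gastrocnemius_contributes_to_both_joints(self, model, simulated_states):
        """The mirrored lateral gastrocnemius produces ankle and knee moments."""
        states = {"gastrocnemius_lateralis": simulated_states["states"]["gastrocnemius_lateralis"]}
        angles = {j: np.zeros(len(states["gastrocnemius_lateralis"].time))
                  for j in ("hip", "knee", "ankle")}
        mom = net_joint_moments(states, model["geometry"], angles)
        assert np.abs(mom["ankle"]).max() > 0
        assert np.abs(mom["knee"]).max() > 0

    def test_mismatched_time_bases_rejected(self, model):
        with pytest.raises(ValueError):
            net_joint_moments({"a": self._traj(5, 1.0), "b": self._traj(6, 1.0)},
                              model["geometry"], {j: np.zeros(5) for j in
                                                  ("hip", "knee", "ankle")})
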