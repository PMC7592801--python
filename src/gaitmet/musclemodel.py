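"""Hill-type muscle-tendon simulation driven by activation and prescribed kinematics.

Each muscle-tendon unit has a contractile element (Gaussian active
force-length, Hill force-velocity with an eccentric plateau, linear fiber
damping), a parallel elastic fiber element, a nonlinear-toe series tendon and
a constant-thickness pennation model.  Fiber length is the state variable;
fiber velocity follows from inverting the damped force-velocity relation so
that the contractile and tendon forces are in equilibrium at every step.

Sign conventions used throughout the package:

* generalized sagittal coordinates: hip extension, knee extension and ankle
  plantarflexion angles, all positive in those directions;
* a positive moment arm produces a positive (extension / plantarflexion)
  moment, and ``d l_mt / d theta = -r`` by construction;
* fiber velocity is the time derivative of fiber length, positive while
  lengthening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from . import _core

JOINTS = ("hip", "knee", "ankle")

MUSCLES = (
    "tibialis_anterior",
    "soleus",
    "gastrocnemius_medialis",
    "gastrocnemius_lateralis",
    "vastus_medialis",
    "rectus_femoris",
    "biceps_femoris",
    "gluteus_maximus",
)

PLANTARFLEXORS = ("soleus", "gastrocnemius_medialis", "gastrocnemius_lateralis")


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of one Hill-type muscle-tendon unit.

    f_max : maximum isometric force (N)
    l_opt : optimal fiber length (m)
    l_slack : tendon slack length (m)
    pennation_opt : pennation angle at optimal fiber length (rad)
    v_max : maximum contraction velocity (optimal fiber lengths per second)
    slow_twitch_ratio : anatomical slow-twitch fiber fraction (0-1)
    width : force-length width coefficient (0-1)
    """

    name: str
    f_max: float
    l_opt: float
    l_slack: float
    pennation_opt: float
    v_max: float
    slow_twitch_ratio: float
    width: float

    def __post_init__(self):
        for attr in ("f_max", "l_opt", "l_slack", "pennation_opt", "v_max"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be positive")
        if not 0.0 <= self.slow_twitch_ratio <= 1.0:
            raise ValueError(f"{self.name}: slow_twitch_ratio must be in [0, 1]")
        if not 0.0 < self.width < 1.0:
            raise ValueError(f"{self.name}: width must be in (0, 1)")


@dataclass(frozen=True)
class CurveSet:
    """Shape constants of the muscle and tendon curves (configuration)."""

    fl_shape: float = 0.5        # Gaussian active FL: exp(-((ln-1)/(fl_shape*width))^2)
    af: float = 0.25             # Hill concentric curvature
    ecc_plateau: float = 1.5     # eccentric force plateau (x f_max)
    ecc_curvature: float = 10.0  # eccentric hyperbola curvature
    fiber_damping: float = 0.1   # normalized linear fiber damping
    tendon_strain_iso: float = 0.045  # tendon strain at f_max
    tendon_shape: float = 40.0
    pe_shape: float = 4.0
    pe_strain: float = 0.7       # passive fiber strain at f_max

    @property
    def tendon_c1(self) -> float:
        return 1.0 / (np.exp(self.tendon_shape * self.tendon_strain_iso) - 1.0)


def active_force_length(lnorm, width, curves: CurveSet = CurveSet()):
    """Normalized active force-length curve (Gaussian, unit peak at l_opt)."""
    z = (np.asarray(lnorm, dtype=float) - 1.0) / (curves.fl_shape * width)
    return np.exp(-(z**2))


def passive_force_length(lnorm, curves: CurveSet = CurveSet()):
    ln = np.asarray(lnorm, dtype=float)
    out = np.expm1(curves.pe_shape * np.maximum(ln - 1.0, 0.0) / curves.pe_strain)
    return np.where(ln > 1.0, out / np.expm1(curves.pe_shape), 0.0)


def tendon_force_length(strain, curves: CurveSet = CurveSet()):
    """Normalized tendon force; reaches 1 at ``tendon_strain_iso``, 0 when slack.

    The exponential toe continues linearly above 10% strain so extreme
    candidate geometries during calibration keep finite forces.
    """
    return _core.tendon_force_np(strain, curves.tendon_shape, curves.tendon_c1)


def force_velocity(vnorm, curves: CurveSet = CurveSet()):
    """Hill force-velocity multiplier; vnorm = fiber velocity / (v_max l_opt), lengthening positive."""
    v = np.asarray(vnorm, dtype=float)
    u = np.clip(-v, 0.0, None)
    conc = (1.0 - u) / (1.0 + u / curves.af)
    ecc = curves.ecc_plateau - (curves.ecc_plateau - 1.0) / (1.0 + curves.ecc_curvature * np.clip(v, 0.0, None))
    return np.where(v < 0.0, conc, ecc)


@dataclass(frozen=True)
class MuscleGeometry:
    """Moment-arm polynomials and reference muscle-tendon lengths.

    ``moment_arm_coeffs[muscle][joint]`` holds ascending polynomial
    coefficients of the signed moment arm r(theta) in meters; the
    muscle-tendon length is the reference length minus the antiderivative of
    each arm, which makes d l_mt / d theta = -r exact by construction.
    """

    reference_lengths: dict
    moment_arm_coeffs: dict

    def __post_init__(self):
        for m, joints in self.moment_arm_coeffs.items():
            if len(joints) < 1:
                raise ValueError(f"muscle {m} actuates no joint")

    @property
    def muscles(self):
        return tuple(self.moment_arm_coeffs)

    def joints_of(self, muscle):
        self._check(muscle)
        return tuple(self.moment_arm_coeffs[muscle])

    def _check(self, muscle):
        if muscle not in self.moment_arm_coeffs:
            raise KeyError(f"unknown muscle {muscle!r}")

    def moment_arm(self, muscle, joint, theta):
        self._check(muscle)
        coeffs = self.moment_arm_coeffs[muscle].get(joint)
        if coeffs is None:
            return np.zeros_like(np.asarray(theta, dtype=float))
        return np.polynomial.polynomial.polyval(np.asarray(theta, dtype=float), coeffs)

    def muscle_tendon_length(self, joint_angles, muscle):
        """Return (l_mt series, {joint: moment-arm series})."""
        self._check(muscle)
        arms = {}
        l_mt = None
        for joint, coeffs in self.moment_arm_coeffs[muscle].items():
            theta = np.asarray(joint_angles[joint], dtype=float)
            arms[joint] = np.polynomial.polynomial.polyval(theta, coeffs)
            anti = np.polynomial.polynomial.polyint(coeffs)
            contrib = np.polynomial.polynomial.polyval(theta, anti)
            l_mt = contrib if l_mt is None else l_mt + contrib
        return self.reference_lengths[muscle] - l_mt, arms

    @classmethod
    def from_params(cls, params: dict, moment_arm_coeffs: dict,
                    reference_fiber_norm: dict | None = None):
        """Reference lengths from a chosen neutral-pose fiber operating point.

        ``reference_fiber_norm[name]`` is the normalized fiber length in the
        neutral (standing) pose, default 1.0.  The defaults are set so each
        muscle's fiber excursion during gait straddles its optimal length,
        as in vivo imaging suggests; this also makes the two calibrated
        length parameters jointly identifiable from joint moments.
        """
        norm = reference_fiber_norm or {}
        ref = {
            name: p.l_slack + norm.get(name, 1.0) * p.l_opt * np.cos(p.pennation_opt)
            for name, p in params.items()
        }
        return cls(reference_lengths=ref, moment_arm_coeffs=moment_arm_coeffs)


@dataclass
class MuscleStateTrajectory:
    """Simulated states of one muscle over time (SI units)."""

    time: np.ndarray
    activation: np.ndarray
    l_mt: np.ndarray
    l_fiber: np.ndarray
    v_fiber: np.ndarray
    pennation: np.ndarray
    f_ce: np.ndarray
    f_tendon: np.ndarray
    f_pe: np.ndarray

    def equilibrium_residual(self):
        return self.f_tendon - (self.f_ce + self.f_pe) * np.cos(self.pennation)


def load_default_model():
    """Load the packaged model file: (muscle params, geometry, curves)."""
    text = resources.files("gaitmet.data").joinpath("default_model.json").read_text()
    raw = json.loads(text)
    params = {name: MuscleParams(name=name, **vals) for name, vals in raw["muscles"].items()}
    geometry = MuscleGeometry.from_params(params, raw["moment_arms"],
                                          raw.get("reference_fiber_norm"))
    c = raw["curves"]
    curves = CurveSet(
        fl_shape=c["fl_shape"], af=c["af"], ecc_plateau=c["ecc_plateau"],
        ecc_curvature=c["ecc_curvature"], fiber_damping=c["fiber_damping"],
        tendon_strain_iso=c["tendon_strain_iso"], tendon_shape=c["tendon_shape"],
        pe_shape=c["pe_shape"], pe_strain=c["pe_strain"],
    )
    return params, geometry, curves


def default_params() -> dict:
    return load_default_model()[0]


def default_geometry() -> MuscleGeometry:
    return load_default_model()[1]


def activation_dynamics(excitation, tau_act=0.010, tau_deact=0.040, fs=2000.0, a0=None):
    """First-order activation dynamics with asymmetric time constants.

    Uses the exact exponential update per sample, so a constant excitation
    step follows 1 - exp(-t/tau) exactly at the sample times.
    """
    if tau_act <= 0 or tau_deact <= 0:
        raise ValueError("time constants must be positive")
    u = np.asarray(excitation, dtype=float)
    if u.min() < -1e-12 or u.max() > 1.0 + 1e-12:
        raise ValueError("excitation must lie in [0, 1]")
    u = np.clip(u, 0.0, 1.0)
    dt = 1.0 / float(fs)
    g_act = 1.0 - np.exp(-dt / tau_act)
    g_deact = 1.0 - np.exp(-dt / tau_deact)
    a = np.empty_like(u)
    a[0] = u[0] if a0 is None else float(a0)
    for i in range(1, u.size):
        g = g_act if u[i] > a[i - 1] else g_deact
        a[i] = a[i - 1] + (u[i] - a[i - 1]) * g
    return np.clip(a, 0.0, 1.0)


def _pennation_height(p: MuscleParams):
    return p.l_opt * np.sin(p.pennation_opt)


def _initial_fiber_length(p: MuscleParams, l_mt0: float):
    h = _pennation_height(p)
    proj = max(l_mt0 - p.l_slack, 0.5 * p.l_opt)
    return float(np.sqrt(proj**2 + h**2))


#: A tendon shorter than this fraction of the optimal fiber length is treated
#: as rigid in "auto" mode (the standard recommendation for short tendons,
#: whose compliant dynamics are numerically stiff and physically negligible).
RIGID_TENDON_RATIO = 0.5


def _rigid_mask(params_list, rigid_tendon):
    m = len(params_list)
    if isinstance(rigid_tendon, str):
        if rigid_tendon != "auto":
            raise ValueError("rigid_tendon must be a bool, a mask or 'auto'")
        return np.array([p.l_slack < RIGID_TENDON_RATIO * p.l_opt
                         for p in params_list])
    if np.isscalar(rigid_tendon) or isinstance(rigid_tendon, bool):
        return np.full(m, bool(rigid_tendon))
    mask = np.asarray(rigid_tendon, dtype=bool)
    if mask.shape != (m,):
        raise ValueError("rigid_tendon mask must have one entry per muscle")
    return mask


def integrate_muscle_states(activations, l_mts, params_list, fs,
                            curves: CurveSet = CurveSet(), l_f0=None,
                            rigid_tendon=False):
    """Integrate M muscles simultaneously.

    activations, l_mts : (M, N) arrays sharing one time base.
    ``rigid_tendon`` may be a bool, a per-muscle mask, or "auto" (rigid where
    the tendon is shorter than half the optimal fiber length).
    Returns a list of :class:`MuscleStateTrajectory`.
    Raises RuntimeError naming the muscle and sample if the integration
    diverges.
    """
    act = np.asarray(activations, dtype=float)
    lmt = np.asarray(l_mts, dtype=float)
    if act.shape != lmt.shape:
        raise ValueError("activation and l_mt arrays must share one time base")
    m, n = act.shape
    if m != len(params_list):
        raise ValueError("need one MuscleParams per row")
    dt = 1.0 / float(fs)
    time = np.arange(n) * dt

    l_opt = np.array([p.l_opt for p in params_list])
    l_slack = np.array([p.l_slack for p in params_list])
    h = np.array([_pennation_height(p) for p in params_list])
    v_max = np.array([p.v_max for p in params_list])
    width = np.array([p.width for p in params_list])
    f_max = np.array([p.f_max for p in params_list])
    rigid = _rigid_mask(params_list, rigid_tendon)

    l_f = np.empty((m, n))
    comp = ~rigid
    if comp.any():
        if l_f0 is None:
            lf0 = np.array([_initial_fiber_length(p, lmt[j, 0])
                            for j, p in enumerate(params_list)])
        else:
            lf0 = np.asarray(l_f0, dtype=float)
        l_f[comp] = _core.integrate_fibers(
            np.ascontiguousarray(act[comp]), np.ascontiguousarray(lmt[comp]),
            lf0[comp], l_opt[comp], l_slack[comp], h[comp], v_max[comp],
            width[comp], dt,
            curves.fl_shape, curves.af, curves.ecc_plateau, curves.ecc_curvature,
            curves.fiber_damping, curves.tendon_shape, curves.tendon_c1,
            curves.pe_shape, curves.pe_strain,
        )
        bad = np.argwhere(l_f[comp] < 0)
        if bad.size:
            j, i = bad[0]
            name = [p.name for p, c in zip(params_list, comp) if c][j]
            raise RuntimeError(
                f"muscle state integration diverged for {name} at sample {i}"
            )
    if rigid.any():
        proj = lmt[rigid] - l_slack[rigid, None]
        l_f[rigid] = np.sqrt(proj**2 + h[rigid, None] ** 2)

    sin_a = np.clip(h[:, None] / l_f, 0.0, 0.985)
    cos_a = np.sqrt(1.0 - sin_a**2)
    pennation = np.arcsin(sin_a)
    lnorm = l_f / l_opt[:, None]
    f_pe = passive_force_length(lnorm, curves) * f_max[:, None]
    fl = active_force_length(lnorm, width[:, None], curves)

    v_f = np.empty((m, n))
    f_ce = np.empty((m, n))
    f_t = np.empty((m, n))
    if comp.any():
        strain = (lmt[comp] - l_f[comp] * cos_a[comp] - l_slack[comp, None]) \
            / l_slack[comp, None]
        f_t[comp] = tendon_force_length(strain, curves) * f_max[comp, None]
        load = f_t[comp] / (f_max[comp, None] * cos_a[comp]) \
            - f_pe[comp] / f_max[comp, None]
        act_fl = act[comp] * fl[comp]
        vn = _inverse_fv_damped_vec(load, act_fl, curves)
        v_f[comp] = vn * v_max[comp, None] * l_opt[comp, None]
        f_ce[comp] = f_max[comp, None] * (act_fl * force_velocity(vn, curves)
                                          + curves.fiber_damping * vn)
    if rigid.any():
        v_f[rigid] = np.gradient(l_f[rigid], dt, axis=-1)
        vn = v_f[rigid] / (v_max[rigid, None] * l_opt[rigid, None])
        raw = f_max[rigid, None] * (act[rigid] * fl[rigid] * force_velocity(vn, curves)
                                    + curves.fiber_damping * vn)
        # a muscle cannot push: a net pushing force would simply unload the
        # (rigid) tendon, so the contractile force is floored at -f_pe
        f_ce[rigid] = np.maximum(raw, -f_pe[rigid])
        f_t[rigid] = (f_ce[rigid] + f_pe[rigid]) * cos_a[rigid]

    out = []
    for j in range(m):
        out.append(MuscleStateTrajectory(
            time=time, activation=act[j], l_mt=lmt[j], l_fiber=l_f[j],
            v_fiber=v_f[j], pennation=pennation[j], f_ce=f_ce[j],
            f_tendon=f_t[j], f_pe=f_pe[j],
        ))
    return out


def _inverse_fv_damped_vec(load, act_fl, curves: CurveSet):
    """Vectorized closed-form inversion of act_fl*fv(v) + beta*v = load."""
    beta, af = curves.fiber_damping, curves.af
    plateau, k = curves.ecc_plateau, curves.ecc_curvature
    b_e = act_fl * plateau * k + beta - load * k
    v_e = (-b_e + np.sqrt(b_e**2 - 4.0 * beta * k * (act_fl - load))) / (2.0 * beta * k)
    a_q = beta / af
    b_q = act_fl + beta + load / af
    u = (-b_q + np.sqrt(np.maximum(b_q**2 + 4.0 * a_q * (act_fl - load), 0.0))) / (2.0 * a_q)
    return np.clip(np.where(load >= act_fl, v_e, -u), -_core._V_CAP, _core._V_CAP)


def integrate_muscle_state(activation, l_mt, params: MuscleParams, fs,
                           curves: CurveSet = CurveSet(), l_f0=None,
                           rigid_tendon=False) -> MuscleStateTrajectory:
    """Single-muscle convenience wrapper around :func:`integrate_muscle_states`."""
    a = np.atleast_2d(np.asarray(activation, dtype=float))
    l = np.atleast_2d(np.asarray(l_mt, dtype=float))
    l_f0v = None if l_f0 is None else np.atleast_1d(l_f0)
    return integrate_muscle_states(a, l, [params], fs, curves=curves,
                                   l_f0=l_f0v, rigid_tendon=rigid_tendon)[0]


def muscle_tendon_length(joint_angles, geometry: MuscleGeometry, muscle):
    """Module-level alias of :meth:`MuscleGeometry.muscle_tendon_length`."""
    return geometry.muscle_tendon_length(joint_angles, muscle)


def net_joint_moments(states: dict, geometry: MuscleGeometry, joint_angles: dict):
    """Signed sum of tendon force x moment arm per joint (N m series)."""
    lengths = {len(t.time) for t in states.values()}
    if len(lengths) != 1:
        raise ValueError("muscle state trajectories must share one time base")
    (n,) = lengths
    for theta in joint_angles.values():
        if len(theta) != n:
            raise ValueError("joint angles must share the muscle time base")
    moments = {j: np.zeros(n) for j in JOINTS}
    for name, traj in states.items():
        for joint in geometry.joints_of(name):
            arm = geometry.moment_arm(name, joint, joint_angles[joint])
            moments[joint] += traj.f_tendon * arm
    return moments


def simulate_trial(trial, params: dict, geometry: MuscleGeometry,
                   curves: CurveSet = CurveSet(), warmup_strides: int = 2,
                   tau_act=0.010, tau_deact=0.040, rigid_tendon="auto"):
    """EMG-driven forward simulation of the muscle states of one trial.

    A copy of the first ``warmup_strides`` stride periods of input is
    prepended so the default initial state washes out, then discarded from
    the outputs.  Returns (states dict, net moments dict in N m, per-kg
    moments dict in N m / kg).
    """
    from .signals import normalize_emg  # local import to avoid a cycle

    fs = trial.sampling_rate
    names = list(params)
    n = len(trial.time)
    stride_samples = int(round(trial.participant.stride_period * fs))
    pad = min(warmup_strides * stride_samples, n)

    act_rows, lmt_rows = [], []
    for name in names:
        env = trial.emg_envelope[name]
        exc = normalize_emg(env, trial.participant.mvc[name])
        a = activation_dynamics(np.concatenate([exc[:pad], exc]),
                                tau_act, tau_deact, fs)
        l_mt, _ = geometry.muscle_tendon_length(trial.joint_angles, name)
        act_rows.append(a)
        lmt_rows.append(np.concatenate([l_mt[:pad], l_mt]))

    trajs = integrate_muscle_states(np.vstack(act_rows), np.vstack(lmt_rows),
                                    [params[name] for name in names], fs,
                                    curves=curves, rigid_tendon=rigid_tendon)
    states = {}
    for name, traj in zip(names, trajs):
        states[name] = MuscleStateTrajectory(
            time=trial.time,
            activation=traj.activation[pad:], l_mt=traj.l_mt[pad:],
            l_fiber=traj.l_fiber[pad:], v_fiber=traj.v_fiber[pad:],
            pennation=traj.pennation[pad:], f_ce=traj.f_ce[pad:],
            f_tendon=traj.f_tendon[pad:], f_pe=traj.f_pe[pad:],
        )
    moments = net_joint_moments(states, geometry, trial.joint_angles)
    mass = trial.participant.body_mass
    moments_per_kg = {j: m / mass for j, m in moments.items()}
    return states, moments, moments_per_kg
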