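"""Per-muscle calibration of tendon slack length and optimal fiber length.

The two length parameters are the strongest determinants of muscle-generated
joint moments, so they are optimized per participant against reference joint
moments with a generalized pattern search, minimizing

    cost = MSE_ankle + MSE_knee + MSE_hip-extension
           + c1 * ZeroForcePenalty
           + c2 * PlantarflexorDistributionPenalty
           + c3 * PhysiologicalRangePenalty

with c1 = c2 = c3 = 1e6, chosen much larger than the moment errors so the
search quickly leaves penalized regions.  The hip error is evaluated only
where the reference hip moment acts in the extension direction, because the
model contains no uni-articular hip flexor.  Iterates are box-constrained to
50-150% of the starting values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import musclemodel
from .musclemodel import (CurveSet, MuscleGeometry, MuscleParams, PLANTARFLEXORS)
from .signals import normalize_emg

log = logging.getLogger(__name__)

SENTINEL_COST = 1e12


@dataclass(frozen=True)
class CalibrationConfig:
    """Cost weights and pattern-search settings."""

    c1: float = 1e6
    c2: float = 1e6
    c3: float = 1e6
    bounds_fraction: tuple = (0.5, 1.5)
    improvement_tol: float = 1e-6
    max_iterations: int = 300
    mesh_init: float = 0.25
    mesh_tol: float = 1e-3
    zero_force_epsilon: float = 1.0   # N; "stays zero" tolerance
    max_failures: int = 50

    def __post_init__(self):
        if min(self.c1, self.c2, self.c3) <= 0:
            raise ValueError("penalty weights must be positive")
        lo, hi = self.bounds_fraction
        if not 0 < lo < 1 < hi:
            raise ValueError("bounds_fraction must straddle 1")


@dataclass
class CostBreakdown:
    """Itemized calibration cost; total = MSE terms + weighted penalties."""

    mse_ankle: float
    mse_knee: float
    mse_hip_extension: float
    zero_force_penalty: int
    plantarflexor_distribution_penalty: int
    physiological_range_penalty: int
    total: float = field(init=False)
    weights: tuple = (1e6, 1e6, 1e6)

    def __post_init__(self):
        c1, c2, c3 = self.weights
        self.total = (self.mse_ankle + self.mse_knee + self.mse_hip_extension
                      + c1 * self.zero_force_penalty
                      + c2 * self.plantarflexor_distribution_penalty
                      + c3 * self.physiological_range_penalty)

    @property
    def mse_sum(self):
        return self.mse_ankle + self.mse_knee + self.mse_hip_extension

    @property
    def penalties_zero(self):
        return (self.zero_force_penalty == 0
                and self.plantarflexor_distribution_penalty == 0
                and self.physiological_range_penalty == 0)


def zero_force_penalty(states: dict, epsilon: float = 1.0) -> int:
    """Number of muscles whose tendon force never exceeds ``epsilon`` newtons."""
    count = 0
    for name, traj in states.items():
        if traj.f_tendon.size == 0:
            raise ValueError(f"empty trajectory for {name}")
        if traj.f_tendon.max() <= epsilon:
            count += 1
    return count


def plantarflexor_distribution_penalty(states: dict) -> int:
    """1 if the soleus stride-mean tendon force is below the gastrocnemii mean."""
    try:
        sol = states["soleus"].f_tendon.mean()
        gas = np.mean([states["gastrocnemius_medialis"].f_tendon.mean(),
                       states["gastrocnemius_lateralis"].f_tendon.mean()])
    except KeyError as exc:
        raise ValueError(f"missing plantarflexor {exc}")
    return int(sol < gas)


def physiological_range_penalty(states: dict, params: dict) -> int:
    """Muscles whose fiber length leaves [l_opt (1-w), l_opt (1+w)] at any sample."""
    count = 0
    for name, traj in states.items():
        p = params[name]
        lo = p.l_opt * (1.0 - p.width)
        hi = p.l_opt * (1.0 + p.width)
        if traj.l_fiber.min() < lo or traj.l_fiber.max() > hi:
            count += 1
    return count


def hip_extension_mse(muscle_moments, reference_moments) -> float:
    """MSE restricted to samples where the reference hip moment is extension.

    Extension is positive in the package's sign convention.
    """
    sim = np.asarray(muscle_moments, dtype=float)
    ref = np.asarray(reference_moments, dtype=float)
    if sim.shape != ref.shape:
        raise ValueError("moment series must be aligned")
    mask = ref > 0.0
    if not mask.any():
        raise ValueError("reference hip moment is never in the extension direction")
    return float(np.mean((sim[mask] - ref[mask]) ** 2))


class CalibrationProblem:
    """Precomputed cost function for one trial.

    Activation and muscle-tendon length series depend only on the trial and
    geometry, not on the candidate lengths, so they are computed once; each
    cost evaluation then only re-integrates the muscle states.
    """

    def __init__(self, trial, reference_moments, base_params: dict,
                 geometry: MuscleGeometry, config: CalibrationConfig = CalibrationConfig(),
                 curves: CurveSet = CurveSet(), warmup_strides: int = 2):
        self.names = list(base_params)
        self.base_params = base_params
        self.geometry = geometry
        self.config = config
        self.curves = curves
        self.fs = trial.sampling_rate
        self.mass = trial.participant.body_mass
        self.reference = reference_moments

        fs = trial.sampling_rate
        spp = int(round(trial.participant.stride_period * fs))
        self.pad = min(warmup_strides * spp, len(trial.time))
        act_rows, lmt_rows = [], []
        for name in self.names:
            exc = normalize_emg(trial.emg_envelope[name], trial.participant.mvc[name])
            a = musclemodel.activation_dynamics(
                np.concatenate([exc[:self.pad], exc]), fs=fs)
            l_mt, _ = geometry.muscle_tendon_length(trial.joint_angles, name)
            act_rows.append(a)
            lmt_rows.append(np.concatenate([l_mt[:self.pad], l_mt]))
        self.activations = np.vstack(act_rows)
        self.l_mts = np.vstack(lmt_rows)
        self.joint_angles = trial.joint_angles
        # tendon mode is fixed from the base parameters so the cost surface
        # stays continuous while the candidate lengths vary
        self.rigid_mask = np.array(
            [base_params[n].l_slack < musclemodel.RIGID_TENDON_RATIO
             * base_params[n].l_opt for n in self.names])

    def params_from_candidate(self, candidate: dict) -> dict:
        out = {}
        for name in self.names:
            l_opt, l_slack = candidate[name]
            out[name] = replace(self.base_params[name], l_opt=float(l_opt),
                                l_slack=float(l_slack))
        return out

    def _strip_pad(self, traj):
        return musclemodel.MuscleStateTrajectory(
            time=traj.time[self.pad:] - traj.time[self.pad],
            activation=traj.activation[self.pad:],
            l_mt=traj.l_mt[self.pad:], l_fiber=traj.l_fiber[self.pad:],
            v_fiber=traj.v_fiber[self.pad:], pennation=traj.pennation[self.pad:],
            f_ce=traj.f_ce[self.pad:], f_tendon=traj.f_tendon[self.pad:],
            f_pe=traj.f_pe[self.pad:])

    def simulate(self, candidate: dict):
        params = self.params_from_candidate(candidate)
        trajs = musclemodel.integrate_muscle_states(
            self.activations, self.l_mts, [params[n] for n in self.names],
            self.fs, curves=self.curves, rigid_tendon=self.rigid_mask)
        states = {name: self._strip_pad(traj)
                  for name, traj in zip(self.names, trajs)}
        moments = musclemodel.net_joint_moments(states, self.geometry, self.joint_angles)
        per_kg = {j: m / self.mass for j, m in moments.items()}
        return states, per_kg

    def simulate_one(self, name: str, lengths):
        """Re-integrate a single muscle under new (l_opt, l_slack)."""
        j = self.names.index(name)
        p = replace(self.base_params[name], l_opt=float(lengths[0]),
                    l_slack=float(lengths[1]))
        traj = musclemodel.integrate_muscle_states(
            self.activations[j:j + 1], self.l_mts[j:j + 1], [p], self.fs,
            curves=self.curves, rigid_tendon=self.rigid_mask[j:j + 1])[0]
        return self._strip_pad(traj)

    def moment_contribution(self, name: str, traj):
        """This muscle's signed joint-moment contribution, N m/kg per joint."""
        out = {}
        for joint in self.geometry.joints_of(name):
            arm = self.geometry.moment_arm(name, joint, self.joint_angles[joint])
            out[joint] = traj.f_tendon * arm / self.mass
        return out

    def cost_from_states(self, states: dict, params: dict) -> CostBreakdown:
        moments = musclemodel.net_joint_moments(states, self.geometry,
                                                self.joint_angles)
        per_kg = {j: m / self.mass for j, m in moments.items()}
        return self._breakdown(states, params, per_kg)

    def _breakdown(self, states, params, per_kg) -> CostBreakdown:
        mse_a = float(np.mean((per_kg["ankle"] - self.reference["ankle"]) ** 2))
        mse_k = float(np.mean((per_kg["knee"] - self.reference["knee"]) ** 2))
        mse_h = hip_extension_mse(per_kg["hip"], self.reference["hip"])
        return CostBreakdown(
            mse_ankle=mse_a, mse_knee=mse_k, mse_hip_extension=mse_h,
            zero_force_penalty=zero_force_penalty(states, self.config.zero_force_epsilon),
            plantarflexor_distribution_penalty=plantarflexor_distribution_penalty(states),
            physiological_range_penalty=physiological_range_penalty(states, params),
            weights=(self.config.c1, self.config.c2, self.config.c3))

    def _sentinel(self) -> CostBreakdown:
        return CostBreakdown(
            mse_ankle=SENTINEL_COST, mse_knee=0.0, mse_hip_extension=0.0,
            zero_force_penalty=0, plantarflexor_distribution_penalty=0,
            physiological_range_penalty=0,
            weights=(self.config.c1, self.config.c2, self.config.c3))

    def cost(self, candidate: dict) -> CostBreakdown:
        try:
            states, per_kg = self.simulate(candidate)
        except (RuntimeError, FloatingPointError) as exc:
            log.warning("simulation failed during calibration: %s", exc)
            return self._sentinel()
        params = self.params_from_candidate(candidate)
        return self._breakdown(states, params, per_kg)

    # vector interface for the pattern search -------------------------------

    def vector_to_candidate(self, x) -> dict:
        return {name: (x[2 * i], x[2 * i + 1]) for i, name in enumerate(self.names)}

    def candidate_to_vector(self, candidate: dict):
        return np.array([v for name in self.names for v in candidate[name]])

    def cost_vector(self, x) -> CostBreakdown:
        return self.cost(self.vector_to_candidate(x))


def cost_function(candidate: dict, trial, reference_moments,
                  config: CalibrationConfig = CalibrationConfig(),
                  base_params: dict | None = None,
                  geometry: MuscleGeometry | None = None,
                  curves: CurveSet = CurveSet()) -> CostBreakdown:
    """One-shot cost evaluation (builds a :class:`CalibrationProblem`)."""
    if base_params is None:
        base_params = musclemodel.default_params()
    if geometry is None:
        geometry = musclemodel.default_geometry()
    problem = CalibrationProblem(trial, reference_moments, base_params,
                                 geometry, config, curves)
    return problem.cost(candidate)


def _poll_directions(n, pair_stride=2):
    """Coordinate directions plus paired diagonals for each (l_opt, l_slack) pair.

    The diagonal directions let the search move along the l_opt / l_slack
    valley (the two lengths trade off against each other almost linearly).
    """
    dirs = []
    eye = np.eye(n)
    for i in range(n):
        dirs.append(eye[i])
        dirs.append(-eye[i])
    for i in range(0, n - 1, pair_stride):
        d = eye[i] - eye[i + 1]
        dirs.append(d)
        dirs.append(-d)
        s = eye[i] + eye[i + 1]
        dirs.append(s)
        dirs.append(-s)
    return np.array(dirs)


def pattern_search(objective, x0, config: CalibrationConfig = CalibrationConfig(),
                   bounds=None, extra_directions=None):
    """Generalized pattern search with expanding/contracting mesh.

    ``objective(x)`` must return a :class:`CostBreakdown`.  The search polls
    coordinate (and paired diagonal) directions scaled relative to ``x0``,
    expands the mesh after an improvement and halves it otherwise, keeps all
    iterates inside ``bounds_fraction`` of ``x0``, and stops once every
    penalty is zero and the improvement falls below ``improvement_tol`` with
    a refined mesh, or after ``max_iterations`` poll iterations.

    Returns (x_best, best CostBreakdown, iteration log).
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("x0 must be positive")
    if bounds is None:
        lo = config.bounds_fraction[0] * x0
        hi = config.bounds_fraction[1] * x0
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("x0 must lie within the bounds")

    x = x0.copy()
    best = objective(x)
    n_fail = 1 if best.total >= SENTINEL_COST else 0
    if n_fail and config.max_failures < 1:
        raise RuntimeError("objective failed at the starting point")
    mesh = config.mesh_init
    dirs = _poll_directions(x0.size)
    if extra_directions is not None:
        extra = np.atleast_2d(np.asarray(extra_directions, dtype=float))
        dirs = np.vstack([dirs, extra, -extra])
    order = np.arange(len(dirs))
    trace = [{"iteration": 0, "cost": best.total, "mesh": mesh}]

    for iteration in range(1, config.max_iterations + 1):
        improved = False
        improvement = 0.0
        for idx in order:
            cand = np.clip(x + mesh * dirs[idx] * x0, lo, hi)
            if np.allclose(cand, x):
                continue
            res = objective(cand)
            if res.total >= SENTINEL_COST:
                n_fail += 1
                if n_fail > config.max_failures:
                    raise RuntimeError(
                        f"objective failed {n_fail} times; aborting pattern search")
                continue
            if res.total < best.total - 1e-15:
                improvement = best.total - res.total
                x, best = cand, res
                improved = True
                # last successful direction is polled first next time
                order = np.concatenate(([idx], order[order != idx]))
                break
        if improved:
            mesh = min(mesh * 2.0, config.mesh_init)
        else:
            mesh *= 0.5
        trace.append({"iteration": iteration, "cost": best.total, "mesh": mesh,
                      "improvement": improvement})
        if (best.penalties_zero and improvement < config.improvement_tol
                and mesh < config.mesh_tol):
            break
    return x, best, trace


#: Functionally coupled muscle groups that share joints (and, for the
#: gastrocnemii, an EMG signal); they are re-polled jointly after the
#: per-muscle sweeps to escape cross-muscle compensation minima.
CALIBRATION_GROUPS = (
    ("soleus", "gastrocnemius_medialis", "gastrocnemius_lateralis"),
    ("vastus_medialis", "rectus_femoris"),
    ("biceps_femoris", "gluteus_maximus"),
    ("tibialis_anterior", "soleus"),
)


def _valley_direction(p: MuscleParams):
    """Tangent of the l_opt / l_slack compensation valley in the normalized
    coordinates the mesh steps in: a relative slack change of
    -cos(alpha) l_opt / l_slack offsets a relative l_opt change."""
    v = np.array([1.0, -np.cos(p.pennation_opt) * p.l_opt / p.l_slack])
    return v / np.abs(v).max()


def calibrate(trial, reference_moments, initial_params: dict,
              geometry: MuscleGeometry | None = None,
              config: CalibrationConfig = CalibrationConfig(),
              curves: CurveSet = CurveSet(), warmup_strides: int = 2,
              max_cycles: int = 8, groups=CALIBRATION_GROUPS):
    """Calibrate (l_opt, l_slack) for every muscle of one trial.

    The search runs muscle by muscle and then over small coupled muscle
    groups: each block's lengths get their own pattern search against the
    shared cost while the remaining muscles' states are held fixed (only the
    polled block is re-simulated), and the blocks are cycled until a full
    cycle no longer improves the cost.  Box constraints (50-150%) apply to
    each muscle's own starting values.  Block-wise polling keeps the search
    out of the long l_opt / l_slack compensation valleys that trap a joint
    search over all muscles at once; the group blocks resolve compensation
    between muscles that share a joint.

    Returns (calibrated params dict, final CostBreakdown, cycle log).
    """
    if geometry is None:
        geometry = musclemodel.default_geometry()
    problem = CalibrationProblem(trial, reference_moments, initial_params,
                                 geometry, config, curves, warmup_strides)
    # the stated improvement tolerance governs the outer cycle; the inner
    # block polls refine further so shallow directions (short-tendon slack
    # lengths) are not abandoned early
    block_config = replace(config, improvement_tol=config.improvement_tol * 1e-2)
    candidate = {name: (p.l_opt, p.l_slack) for name, p in initial_params.items()}
    states, _ = problem.simulate(candidate)
    params = problem.params_from_candidate(candidate)
    best = problem.cost_from_states(states, params)
    trace = [{"cycle": 0, "cost": best.total}]

    def run_block(block, grid_start=False):
        nonlocal best

        def block_objective(x):
            trial_states = dict(states)
            trial_params = dict(params)
            try:
                for i, n in enumerate(block):
                    trial_states[n] = problem.simulate_one(n, x[2 * i:2 * i + 2])
                    trial_params[n] = replace(problem.base_params[n],
                                              l_opt=float(x[2 * i]),
                                              l_slack=float(x[2 * i + 1]))
            except (RuntimeError, FloatingPointError) as exc:
                log.warning("simulation failed during calibration: %s", exc)
                return problem._sentinel()
            return problem.cost_from_states(trial_states, trial_params)

        x0 = np.concatenate([candidate[n] for n in block])
        x_init = np.concatenate([(initial_params[n].l_opt,
                                  initial_params[n].l_slack) for n in block])
        if grid_start and len(block) <= 2:
            # coarse scan of the box to start the poll in the right basin
            lo, hi = (config.bounds_fraction[0] * x_init,
                      config.bounds_fraction[1] * x_init)
            n_axis = 7 if len(block) == 1 else 5
            axes = [np.linspace(lo[k], hi[k], n_axis) for k in range(len(x0))]
            mesh_pts = np.stack([g.ravel() for g in np.meshgrid(*axes)], axis=-1)
            best_grid, best_x = block_objective(x0).total, x0
            for pt in mesh_pts:
                res = block_objective(pt)
                if res.total < best_grid:
                    best_grid, best_x = res.total, pt
            x0 = best_x
        extra = []
        for i, n in enumerate(block):
            d = np.zeros(2 * len(block))
            d[2 * i:2 * i + 2] = _valley_direction(initial_params[n])
            extra.append(d)
        x_best, bd, _ = pattern_search(
            block_objective, x0, block_config,
            bounds=(config.bounds_fraction[0] * x_init,
                    config.bounds_fraction[1] * x_init),
            extra_directions=extra)
        if bd.total < best.total - 1e-15:
            for i, n in enumerate(block):
                candidate[n] = (float(x_best[2 * i]), float(x_best[2 * i + 1]))
                states[n] = problem.simulate_one(n, x_best[2 * i:2 * i + 2])
                params[n] = replace(problem.base_params[n],
                                    l_opt=candidate[n][0],
                                    l_slack=candidate[n][1])
            best = bd

    group_blocks = [tuple(n for n in g if n in problem.names)
                    for g in (groups or ())]
    group_blocks = [g for g in group_blocks if len(g) >= 2]
    # sweep distal to proximal: the ankle muscles are pinned by the largest
    # and cleanest moment signal, the hip muscles (masked to the extension
    # window) are the least identified and adapt last
    joint_rank = {"ankle": 0, "knee": 1, "hip": 2}
    singles = sorted(problem.names,
                     key=lambda n: max(joint_rank[j]
                                       for j in geometry.joints_of(n)))
    for cycle in range(1, max_cycles + 1):
        cycle_start = best.total
        for name in singles:
            run_block((name,))
        for block in group_blocks:
            run_block(block)
        improvement = cycle_start - best.total
        trace.append({"cycle": cycle, "cost": best.total,
                      "improvement": improvement})
        if best.penalties_zero and improvement < config.improvement_tol:
            break
    return problem.params_from_candidate(candidate), best, trace
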