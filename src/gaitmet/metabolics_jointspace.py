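"""Joint-space metabolic-rate estimation from joint moments and velocities.

The joint-space model maps joint moments and joint angular velocities
directly to a metabolic-rate time profile, bypassing muscle states.  Per
joint and per sample it evaluates

* an activation-maintenance term proportional to the moment magnitude,
* a shortening-lengthening term from the moment-velocity interaction, and
* mechanical-work terms with separate positive- and negative-work
  efficiencies (eccentric work is metabolically cheaper, so the
  negative-work efficiency magnitude is larger).

All terms are nonnegative per sample and the limb profile is exactly
additive across joints; there is no basal term, so zero inputs give a zero
profile.  The packaged coefficient values are a named, versioned default
set; every identity the package tests holds for any admissible set.
Upper-body joints are structurally absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metabolics_muscle import MetabolicProfile

JOINTS = ("hip", "knee", "ankle")
SIDES = ("right", "left")

#: moment-direction groups per joint: (positive-moment group, negative-moment
#: group) in the extension / plantarflexion-positive sign convention.
DIRECTION_GROUPS = {
    "ankle": ("plantarflexors", "dorsiflexors"),
    "knee": ("knee_extensors", "knee_flexors"),
    "hip": ("hip_extensors", "hip_flexors"),
}


@dataclass(frozen=True)
class JointSpaceCoefficients:
    """Coefficient set of the joint-space equations (configuration).

    am_coeff : W/kg per (N m/kg) of moment magnitude
    sl_coeff : W/kg per (N m/kg)(rad/s) of moment-velocity interaction
    pos_efficiency : efficiency of positive (concentric) mechanical work
    neg_efficiency : efficiency magnitude of negative (eccentric) work
    moment_deadband : moments below this magnitude (N m/kg) are ignored
    """

    am_coeff: float = 0.55
    sl_coeff: float = 0.12
    pos_efficiency: float = 0.25
    neg_efficiency: float = 1.20
    moment_deadband: float = 0.0

    def __post_init__(self):
        if self.pos_efficiency <= 0 or self.neg_efficiency <= 0:
            raise ValueError("efficiencies must be positive")
        if self.neg_efficiency <= self.pos_efficiency:
            raise ValueError("negative-work efficiency magnitude must exceed positive-work")
        if self.am_coeff < 0 or self.sl_coeff < 0:
            raise ValueError("heat coefficients must be nonnegative")


@dataclass
class JointInputs:
    """Per-side, per-joint moment (N m/kg) and angular velocity (rad/s) series."""

    moments: dict        # side -> joint -> array
    angular_velocities: dict

    def __post_init__(self):
        n = None
        for side in self.moments:
            for joint, m in self.moments[side].items():
                w = self.angular_velocities[side][joint]
                if len(m) != len(w):
                    raise ValueError("moment and velocity series must be aligned")
                if n is None:
                    n = len(m)
                elif len(m) != n:
                    raise ValueError("all series must share one time base")
                if not (np.all(np.isfinite(m)) and np.all(np.isfinite(w))):
                    raise ValueError("non-finite values in joint inputs")
        self.n_samples = n

    def copy(self):
        return JointInputs(
            moments={s: {j: v.copy() for j, v in js.items()} for s, js in self.moments.items()},
            angular_velocities={s: {j: v.copy() for j, v in js.items()}
                                for s, js in self.angular_velocities.items()})

    @classmethod
    def unilateral(cls, moments: dict, angular_velocities: dict, side="right"):
        """Build bilateral inputs from one side's series, zeros on the other."""
        other = "left" if side == "right" else "right"
        zeros = {j: np.zeros_like(np.asarray(v, dtype=float))
                 for j, v in moments.items()}
        return cls(
            moments={side: {j: np.asarray(v, dtype=float) for j, v in moments.items()},
                     other: {j: z.copy() for j, z in zeros.items()}},
            angular_velocities={side: {j: np.asarray(v, dtype=float)
                                       for j, v in angular_velocities.items()},
                                other: {j: z.copy() for j, z in zeros.items()}})


def unilateral_mask(inputs: JointInputs, side: str) -> JointInputs:
    """Zero every channel that is not on ``side`` (idempotent)."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    out = inputs.copy()
    for s in out.moments:
        if s != side:
            for j in out.moments[s]:
                out.moments[s][j][:] = 0.0
                out.angular_velocities[s][j][:] = 0.0
    return out


def jointspace_rate(inputs: JointInputs,
                    coeffs: JointSpaceCoefficients = JointSpaceCoefficients(),
                    stride_grid=None) -> MetabolicProfile:
    """Metabolic-rate profile from joint inputs, W per kg body mass.

    Sources are keyed "<side>_<joint>"; the total is their exact sum.
    """
    n = inputs.n_samples
    grid = (np.linspace(0.0, 100.0, n) if stride_grid is None
            else np.asarray(stride_grid, dtype=float))
    if len(grid) != n:
        raise ValueError("stride grid must match the input length")
    sources, am_tot, sl_tot, w_tot = {}, np.zeros(n), np.zeros(n), np.zeros(n)
    for side in inputs.moments:
        for joint, m in inputs.moments[side].items():
            m = np.asarray(m, dtype=float)
            w = np.asarray(inputs.angular_velocities[side][joint], dtype=float)
            if coeffs.moment_deadband > 0:
                m = np.where(np.abs(m) < coeffs.moment_deadband, 0.0, m)
            am = coeffs.am_coeff * np.abs(m)
            sl = coeffs.sl_coeff * np.abs(m * w)
            power = m * w
            work = (np.clip(power, 0.0, None) / coeffs.pos_efficiency
                    + np.abs(np.clip(power, None, 0.0)) / coeffs.neg_efficiency)
            sources[f"{side}_{joint}"] = am + sl + work
            am_tot += am
            sl_tot += sl
            w_tot += work
    total = np.sum(list(sources.values()), axis=0)
    return MetabolicProfile(
        stride_grid=grid, sources=sources,
        components={"activation_maintenance": am_tot,
                    "shortening_lengthening": sl_tot,
                    "fiber_work": w_tot},
        total=total)


def estimate_profile(trial, coeffs: JointSpaceCoefficients = JointSpaceCoefficients(),
                     n_points: int = 201, side: str = "right"):
    """Full joint-space estimate for one trial.

    Joint angular velocities come from differentiating the joint angles;
    strides are segmented from the GRFs, each joint's moment and velocity is
    time-normalized and stride-averaged, the contralateral side is masked to
    zero, and the joint-space equations are evaluated on the stride grid.
    Returns (MetabolicProfile, masked JointInputs).
    """
    from . import signals

    fs = trial.sampling_rate
    events = signals.detect_strides(signals.filter_grf(trial.grf_vertical_ipsi, fs),
                                    signals.filter_grf(trial.grf_vertical_contra, fs),
                                    fs)
    hs = events.ipsi_heel_strikes
    grid = signals.stride_grid(n_points)

    def stride_mean(series):
        return np.mean([signals.time_normalize(series, hs[k], hs[k + 1], n_points)
                        for k in range(len(hs) - 1)], axis=0)

    moments = {j: stride_mean(trial.joint_moments[j]) for j in JOINTS}
    omegas = {j: stride_mean(np.gradient(trial.joint_angles[j]) * fs) for j in JOINTS}
    inputs = unilateral_mask(JointInputs.unilateral(moments, omegas, side), side)
    profile = jointspace_rate(inputs, coeffs, stride_grid=grid)
    return profile, inputs


def partition_by_moment_direction(profile: MetabolicProfile, inputs: JointInputs):
    """Attribute each joint's rate to a direction group by the moment's sign.

    Returns shares in percent of the limb stride average; the six groups
    partition the total, so shares sum to 100.
    """
    n = inputs.n_samples
    group_rates = {g: np.zeros(n) for pair in DIRECTION_GROUPS.values() for g in pair}
    for side in inputs.moments:
        for joint, m in inputs.moments[side].items():
            key = f"{side}_{joint}"
            if key not in profile.sources:
                raise ValueError(f"profile has no source {key}")
            rate = profile.sources[key]
            if len(rate) != n:
                raise ValueError("profile and inputs must be aligned")
            pos_group, neg_group = DIRECTION_GROUPS[joint]
            positive = np.asarray(m, dtype=float) >= 0.0
            group_rates[pos_group] += np.where(positive, rate, 0.0)
            group_rates[neg_group] += np.where(~positive, rate, 0.0)
    denom = profile.total.mean()
    if denom == 0:
        return {g: 0.0 for g in group_rates}
    return {g: 100.0 * v.mean() / denom for g, v in group_rates.items()}
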