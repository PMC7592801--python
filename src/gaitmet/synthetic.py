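"""Synthetic gait-trial generator.

Generates stride-locked, periodic walking data with the statistical structure
of a treadmill grade / shoe-inclination study: sagittal joint angles and
moments, bilateral vertical ground reaction forces with a double-bump stance
profile, EMG envelopes for seven recorded muscles (the lateral gastrocnemius
mirrors the medial one), stride-average gas-exchange values, and condition
effects in which uphill grade scales plantarflexor / hip-extensor drive and
positive leg work, downhill grade scales negative work, and shoe inclination
perturbs the ankle moment and the tibialis / plantarflexor drive.

Signal shapes are built from smooth periodic raised-cosine bumps; the exact
shapes are configuration (module-level template tables), not hard-coded
science.  Trial noise is multiplicative lognormal on per-stride amplitudes
plus a little additive white noise, which reproduces the variability that
motivates stride-average outlier screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import musclemodel
from .musclemodel import MUSCLES, MuscleGeometry

GRAVITY = 9.81

#: Muscles with a recorded EMG channel (the lateral gastrocnemius is mirrored).
RECORDED_MUSCLES = tuple(m for m in MUSCLES if m != "gastrocnemius_lateralis")

VALID_GRADES = (-6.0, 0.0, 6.0)
VALID_SHOES = (-7.0, -3.0, 0.0, 3.0, 7.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One walking condition: treadmill grade or shoe inclination (degrees)."""

    grade_deg: float = 0.0
    shoe_inclination_deg: float = 0.0
    speed: float = 1.0

    def __post_init__(self):
        if self.grade_deg not in VALID_GRADES:
            raise ValueError(f"grade_deg must be one of {VALID_GRADES}, got {self.grade_deg}")
        if self.shoe_inclination_deg not in VALID_SHOES:
            raise ValueError(
                f"shoe_inclination_deg must be one of {VALID_SHOES}, got {self.shoe_inclination_deg}"
            )
        if self.grade_deg != 0.0 and self.shoe_inclination_deg != 0.0:
            raise ValueError("grade_deg and shoe_inclination_deg cannot both be nonzero")

    @property
    def is_baseline(self):
        return self.grade_deg == 0.0 and self.shoe_inclination_deg == 0.0

    def label(self):
        if self.grade_deg:
            return f"grade{self.grade_deg:+.0f}"
        if self.shoe_inclination_deg:
            return f"shoe{self.shoe_inclination_deg:+.0f}"
        return "baseline"


#: The study design: three grades with level shoes plus four inclined-shoe
#: conditions on the level treadmill (the baseline belongs to both families).
STUDY_CONDITIONS = (
    ConditionSpec(grade_deg=-6.0),
    ConditionSpec(),
    ConditionSpec(grade_deg=6.0),
    ConditionSpec(shoe_inclination_deg=-7.0),
    ConditionSpec(shoe_inclination_deg=-3.0),
    ConditionSpec(shoe_inclination_deg=3.0),
    ConditionSpec(shoe_inclination_deg=7.0),
)


@dataclass(frozen=True)
class ParticipantSpec:
    """Anthropometrics and per-participant signal idiosyncrasies."""

    id: str
    body_mass: float = 79.9          # kg
    stride_period: float = 1.12      # s
    stance_fraction: float = 0.65
    template_scales: dict = field(default_factory=dict)
    mvc: dict = field(default_factory=lambda: {m: 1.0 for m in MUSCLES})

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.stride_period <= 0:
            raise ValueError("stride_period must be positive")
        if not 0.5 < self.stance_fraction < 0.7:
            raise ValueError("stance_fraction must lie in (0.5, 0.7)")


@dataclass
class GaitTrial:
    """One condition's synchronized time series plus metadata."""

    sampling_rate: float
    time: np.ndarray
    joint_angles: dict       # rad; hip/knee extension and ankle plantarflexion positive
    joint_moments: dict      # N m / kg, same sign convention
    grf_vertical_ipsi: np.ndarray    # N
    grf_vertical_contra: np.ndarray  # N
    emg_envelope: dict       # raw units (scaled by each muscle's MVC)
    condition: ConditionSpec
    participant: ParticipantSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time)
        series = [self.grf_vertical_ipsi, self.grf_vertical_contra,
                  *self.joint_angles.values(), *self.joint_moments.values(),
                  *self.emg_envelope.values()]
        for s in series:
            if len(s) != n:
                raise ValueError("all series must share one time base")
            if not np.all(np.isfinite(s)):
                raise ValueError("non-finite values in trial series")
        if self.grf_vertical_ipsi.min() < 0 or self.grf_vertical_contra.min() < 0:
            raise ValueError("GRFs must be nonnegative")


def _bump(phi, center, width):
    """Smooth periodic raised-cosine bump of unit peak on the stride circle."""
    d = (np.asarray(phi, dtype=float) - center + 0.5) % 1.0 - 0.5
    return np.where(np.abs(d) < width / 2.0, np.cos(np.pi * d / width) ** 2, 0.0)


# ---------------------------------------------------------------------------
# signal templates (configuration): lists of (amplitude, center, width) bumps
# plus an optional cosine term for the hip.  Angles in degrees, moments in
# N m/kg, EMG in fraction of MVC.
# ---------------------------------------------------------------------------

ANGLE_BUMPS = {
    "hip": [],                       # handled by the cosine below
    "knee": [(-15.0, 0.12, 0.30), (-55.0, 0.72, 0.45)],
    "ankle": [(-8.0, 0.40, 0.55), (18.0, 0.62, 0.25), (5.0, 0.04, 0.15),
              (-3.0, 0.85, 0.30)],
}
ANGLE_OFFSETS = {"hip": -5.0, "knee": -5.0, "ankle": 0.0}
HIP_COS_AMPLITUDE = -20.0            # deg; flexion at heel strike, extension at 50%

MOMENT_BUMPS = {
    "ankle": [(1.40, 0.40, 0.55), (-0.15, 0.03, 0.10)],
    "knee": [(0.45, 0.10, 0.18), (-0.25, 0.40, 0.35), (0.25, 0.60, 0.12),
             (-0.15, 0.90, 0.20)],
    "hip": [(0.70, 0.05, 0.25), (-0.60, 0.45, 0.35), (0.30, 0.95, 0.15)],
}

EMG_BUMPS = {
    "soleus": [(0.50, 0.40, 0.45)],
    "gastrocnemius_medialis": [(0.45, 0.38, 0.40)],
    "tibialis_anterior": [(0.30, 0.03, 0.12), (0.25, 0.80, 0.35)],
    "vastus_medialis": [(0.35, 0.10, 0.25), (0.10, 0.95, 0.12)],
    "rectus_femoris": [(0.20, 0.10, 0.25), (0.18, 0.68, 0.22)],
    "biceps_femoris": [(0.35, 0.97, 0.30), (0.15, 0.55, 0.20)],
    "gluteus_maximus": [(0.35, 0.05, 0.28)],
}
EMG_BASELINE = 0.02

#: Additive white-noise scale per signal family (multiplied by noise_sd).
ADDITIVE_NOISE = {"angle": 0.004, "moment": 0.01, "grf": 4.0, "emg": 0.004}


def _sum_bumps(phi, bumps):
    out = np.zeros_like(np.asarray(phi, dtype=float))
    for amp, center, width in bumps:
        out += amp * _bump(phi, center, width)
    return out


def _grf_shape(s):
    """Double-bump vertical GRF shape over normalized stance time s in [0, 1]."""
    s = np.asarray(s, dtype=float)
    return np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 0.75 * (1.0 + 0.4 * np.cos(2 * np.pi * s))


_GRF_SHAPE_MEAN = float(np.trapezoid(_grf_shape(np.linspace(0, 1, 4001)), np.linspace(0, 1, 4001)))


def _grf_template(phi, stance_fraction, body_mass):
    """Single-leg vertical GRF; the two-leg stride average equals body weight."""
    phi = np.asarray(phi, dtype=float)
    in_stance = phi < stance_fraction
    s = np.where(in_stance, phi / stance_fraction, 0.0)
    scale = body_mass * GRAVITY / (2.0 * stance_fraction * _GRF_SHAPE_MEAN)
    return np.where(in_stance, scale * _grf_shape(s), 0.0)


# ---------------------------------------------------------------------------
# condition effects (configuration)
# ---------------------------------------------------------------------------

def _condition_factors(condition: ConditionSpec):
    g = condition.grade_deg
    s = condition.shoe_inclination_deg
    up, down = max(g, 0.0), max(-g, 0.0)
    emg = {m: 1.0 for m in MUSCLES}
    for m in ("soleus", "gastrocnemius_medialis", "gastrocnemius_lateralis",
              "gluteus_maximus"):
        emg[m] = (1.0 + 0.06 * up + 0.015 * down) * (1.0 + 0.015 * max(s, 0.0))
    for m in ("vastus_medialis", "biceps_femoris", "rectus_femoris"):
        emg[m] = 1.0 + 0.04 * down + 0.02 * up
    emg["tibialis_anterior"] = 1.0 + 0.03 * abs(s) + 0.02 * down
    moments = {
        "ankle": (1.0 + 0.05 * g) * (1.0 + 0.012 * abs(s)),
        "knee": 1.0 + 0.05 * down,
        "hip": 1.0 + 0.04 * up + 0.02 * down,
    }
    ankle_angle_offset_deg = 0.6 * s
    return emg, moments, ankle_angle_offset_deg


def metabolic_scale(condition: ConditionSpec):
    """Net-metabolic-rate multiplier of a condition relative to baseline."""
    g = condition.grade_deg
    s = condition.shoe_inclination_deg
    factor = 1.0
    if g > 0:
        factor *= 1.0 + 0.185 * g
    elif g < 0:
        factor *= 1.0 + 0.060 * g
    if s < 0:
        factor *= 1.0 + 0.017 * abs(s)
    elif s > 0:
        factor *= 1.0 + 0.009 * s
    return factor


BASELINE_NET_RATE = 3.3   # W/kg, level walking at 1 m/s
STANDING_RATE = 1.4       # W/kg
RESPIRATORY_QUOTIENT = 0.85


def _stride_noise(rng, n_samples, samples_per_stride, noise_sd):
    """Smooth multiplicative per-stride amplitude factor series."""
    if noise_sd == 0.0:
        return np.ones(n_samples)
    n_strides = int(np.ceil(n_samples / samples_per_stride))
    factors = np.exp(rng.normal(0.0, noise_sd, n_strides))
    mids = (np.arange(n_strides) + 0.5) * samples_per_stride
    return np.interp(np.arange(n_samples), mids, factors)


def generate_trial(participant: ParticipantSpec, condition: ConditionSpec,
                   n_strides: int = 3, noise_sd: float = 0.0, seed: int = 0,
                   sampling_rate: float = 2000.0) -> GaitTrial:
    """Generate one synthetic gait trial.

    The output is exactly stride-periodic when ``noise_sd`` is zero; identical
    arguments produce bitwise-identical trials.
    """
    if n_strides < 2:
        raise ValueError("n_strides must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    fs = float(sampling_rate)
    spp = int(round(participant.stride_period * fs))
    n = n_strides * spp
    time = np.arange(n) / fs
    phi = (np.arange(n) % spp) / spp

    emg_fac, mom_fac, ankle_offset_deg = _condition_factors(condition)
    scales = participant.template_scales

    def noisy(series, key, family, positive=False, stance_only=None):
        amp = _stride_noise(rng, n, spp, noise_sd) * scales.get(key, 1.0)
        out = series * amp
        if noise_sd > 0:
            add = rng.normal(0.0, ADDITIVE_NOISE[family] * noise_sd, n)
            if stance_only is not None:
                add = np.where(stance_only, add, 0.0)
            out = out + add
        return np.maximum(out, 0.0) if positive else out

    joint_angles = {}
    for joint in ("hip", "knee", "ankle"):
        deg = ANGLE_OFFSETS[joint] + _sum_bumps(phi, ANGLE_BUMPS[joint])
        if joint == "hip":
            deg = deg + HIP_COS_AMPLITUDE * np.cos(2 * np.pi * phi)
        if joint == "ankle":
            deg = deg + ankle_offset_deg
        joint_angles[joint] = noisy(np.deg2rad(deg), f"angle_{joint}", "angle")

    joint_moments = {
        joint: noisy(mom_fac[joint] * _sum_bumps(phi, MOMENT_BUMPS[joint]),
                     f"moment_{joint}", "moment")
        for joint in ("hip", "knee", "ankle")
    }

    sf = participant.stance_fraction
    grf_i = _grf_template(phi, sf, participant.body_mass)
    phi_c = (phi + 0.5) % 1.0
    grf_c = _grf_template(phi_c, sf, participant.body_mass)
    grf_ipsi = noisy(grf_i, "grf", "grf", positive=True, stance_only=grf_i > 0)
    grf_contra = noisy(grf_c, "grf", "grf", positive=True, stance_only=grf_c > 0)

    emg = {}
    for muscle in RECORDED_MUSCLES:
        act = np.clip(
            noisy((EMG_BASELINE + _sum_bumps(phi, EMG_BUMPS[muscle])) * emg_fac[muscle],
                  f"emg_{muscle}", "emg", positive=True),
            0.0, 1.0)
        emg[muscle] = act * participant.mvc[muscle]
    # the lateral gastrocnemius channel mirrors the medial activation pattern
    gm_act = emg["gastrocnemius_medialis"] / participant.mvc["gastrocnemius_medialis"]
    emg["gastrocnemius_lateralis"] = (
        np.clip(gm_act * emg_fac["gastrocnemius_lateralis"] / emg_fac["gastrocnemius_medialis"],
                0.0, 1.0) * participant.mvc["gastrocnemius_lateralis"])

    net_rate = BASELINE_NET_RATE * metabolic_scale(condition)
    if noise_sd > 0:
        net_rate *= float(np.exp(rng.normal(0.0, 0.5 * noise_sd)))
    gross_w = (net_rate + STANDING_RATE) * participant.body_mass
    vo2 = gross_w / (16.58 + 4.51 * RESPIRATORY_QUOTIENT)
    meta = {
        "vo2_ml_s": vo2,
        "vco2_ml_s": RESPIRATORY_QUOTIENT * vo2,
        "standing_rate_w_kg": STANDING_RATE,
        "samples_per_stride": spp,
        "true_ipsi_heel_strikes": np.arange(n_strides + 1) * spp,
        "true_ipsi_toe_offs": np.arange(n_strides) * spp + int(round(sf * spp)),
        "seed": seed,
        "noise_sd": noise_sd,
    }
    return GaitTrial(
        sampling_rate=fs, time=time, joint_angles=joint_angles,
        joint_moments=joint_moments, grf_vertical_ipsi=grf_ipsi,
        grf_vertical_contra=grf_contra, emg_envelope=emg,
        condition=condition, participant=participant, meta=meta,
    )


#: Population distributions the cohort generator draws from
#: (mean, sd, lower clip, upper clip).
POPULATION = {
    "body_mass": (79.9, 13.8, 50.0, 120.0),
    "stride_period": (1.12, 0.07, 0.90, 1.40),
    "stance_fraction": (0.650, 0.012, 0.620, 0.680),
}


def sample_participant(rng, label: str) -> ParticipantSpec:
    draws = {}
    for key, (mu, sd, lo, hi) in POPULATION.items():
        draws[key] = float(np.clip(rng.normal(mu, sd), lo, hi))
    mvc = {m: float(rng.uniform(0.3, 0.9)) for m in MUSCLES}
    scale_keys = ([f"angle_{j}" for j in ("hip", "knee", "ankle")]
                  + [f"moment_{j}" for j in ("hip", "knee", "ankle")]
                  + ["grf"] + [f"emg_{m}" for m in RECORDED_MUSCLES])
    scales = {k: float(np.exp(rng.normal(0.0, 0.06))) for k in scale_keys}
    return ParticipantSpec(id=label, body_mass=draws["body_mass"],
                           stride_period=draws["stride_period"],
                           stance_fraction=draws["stance_fraction"],
                           template_scales=scales, mvc=mvc)


def generate_cohort(n_participants: int, conditions, seed: int = 0,
                    n_strides: int = 3, noise_sd: float = 0.05,
                    sampling_rate: float = 2000.0):
    """Generate a cohort: one trial per participant per condition."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    conditions = list(conditions)
    if not conditions:
        raise ValueError("condition list must not be empty")
    rng = np.random.default_rng(seed)
    participants = [sample_participant(rng, f"P{i + 1:02d}") for i in range(n_participants)]
    trials = []
    for p in participants:
        for cond in conditions:
            trial_seed = int(rng.integers(2**31))
            trials.append(generate_trial(p, cond, n_strides=n_strides,
                                         noise_sd=noise_sd, seed=trial_seed,
                                         sampling_rate=sampling_rate))
    return trials


def generate_truth_trial(true_params: dict, participant: ParticipantSpec,
                         seed: int = 0, geometry: MuscleGeometry | None = None,
                         condition: ConditionSpec | None = None,
                         n_strides: int = 2, sampling_rate: float = 2000.0,
                         warmup_strides: int = 2):
    """Build a trial whose joint moments are the net muscle-generated moments.

    The trial's EMG and kinematics are the standard synthetic templates; its
    moments are replaced by the moments the muscle simulation produces under
    ``true_params``, so a calibration run against these reference moments has
    a known optimum at ``true_params``.  Returns (trial, reference moments in
    N m/kg per joint).
    """
    for p in true_params.values():
        if not isinstance(p, musclemodel.MuscleParams):
            raise TypeError("true_params must map names to MuscleParams")
    if geometry is None:
        geometry = musclemodel.default_geometry()
    missing = set(true_params) - set(geometry.muscles)
    if missing:
        raise ValueError(f"muscles absent from geometry: {sorted(missing)}")
    cond = condition or ConditionSpec()
    trial = generate_trial(participant, cond, n_strides=n_strides, noise_sd=0.0,
                           seed=seed, sampling_rate=sampling_rate)
    _, _, moments_per_kg = musclemodel.simulate_trial(
        trial, true_params, geometry, warmup_strides=warmup_strides)
    trial.joint_moments = {j: m.copy() for j, m in moments_per_kg.items()}
    reference = {j: m.copy() for j, m in moments_per_kg.items()}
    return trial, reference


def positive_leg_work(trial: GaitTrial):
    """Stride-average positive mechanical work rate of the leg (W/kg)."""
    fs = trial.sampling_rate
    total = 0.0
    for joint, moment in trial.joint_moments.items():
        omega = np.gradient(trial.joint_angles[joint]) * fs
        total += np.maximum(moment * omega, 0.0).mean()
    return total
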