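"""Muscle-level metabolic rate from simulated muscle states.

The per-muscle metabolic rate is partitioned, in the Umberger tradition, into
an activation-maintenance heat rate, a shortening-lengthening heat rate and
the mechanical work rate of the contractile fibers (negative work included,
not zeroed), all expressed per kilogram of muscle mass and then summed over
muscles per kilogram of body mass.  The per-muscle total is clamped at zero
from below at every sample (negative mechanical work cannot synthesize ATP).
Outputs are net rates: resting muscle metabolism is not modeled, matching a
net-of-standing measurement convention.

The numeric heat-rate coefficients are a named, versioned configuration set
(:class:`EnergeticsCoefficients`); every identity the package tests —
component additivity, the aerobic-factor scaling, nonnegativity after
clamping, zero drive giving zero rate — holds for any admissible
coefficient set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import musclemodel
from .musclemodel import CurveSet, MuscleParams

#: Table-4-style functional grouping of the modeled muscles.  The rectus
#: femoris is counted with the knee extensors so the groups partition the
#: whole muscle set.
MUSCLE_GROUPS = {
    "plantarflexors": ("soleus", "gastrocnemius_medialis", "gastrocnemius_lateralis"),
    "knee_extensors": ("vastus_medialis", "rectus_femoris"),
    "hip_extensors": ("gluteus_maximus",),
    "dorsiflexors": ("tibialis_anterior",),
    "knee_flexors": ("biceps_femoris",),
}


@dataclass(frozen=True)
class EnergeticsCoefficients:
    """Physical constants and heat-rate coefficients (configuration).

    density : muscle density, kg/m^3
    specific_tension : maximum isometric stress, N/m^2
    aerobic_factor : scaling for primarily aerobic effort
    am_base_slow / am_base_fast : activation-maintenance heat rate of pure
        slow / fast muscle at full drive, W per kg muscle
    am_exponent / shortening_exponent : activation scaling exponents
    slow_vmax_fraction : slow-fiber maximum shortening velocity as a fraction
        of the muscle's v_max
    shortening_coeff_scale : alpha_S(slow) = scale * am_base_slow / v_max(slow)
    lengthening_multiple : alpha_L = multiple * alpha_S(slow)
    recruitment_model : "orderly" (slow fibers recruited first)
    recruitment_exponent : shape of the orderly recruitment curve
    """

    density: float = 1059.7
    specific_tension: float = 600000.0
    aerobic_factor: float = 1.5
    am_base_slow: float = 25.0
    am_base_fast: float = 153.0
    am_exponent: float = 0.6
    shortening_exponent: float = 2.0
    slow_vmax_fraction: float = 0.4
    shortening_coeff_scale: float = 4.0
    lengthening_multiple: float = 4.0
    recruitment_model: str = "orderly"
    recruitment_exponent: float = 1.0

    def __post_init__(self):
        if min(self.density, self.specific_tension, self.aerobic_factor) <= 0:
            raise ValueError("density, specific_tension and aerobic_factor must be positive")


@dataclass
class MetabolicProfile:
    """Time-normalized metabolic-rate profile with a component decomposition.

    stride_grid : percent of stride, 0-100
    sources : per-source rate series, W per kg body mass (muscles or joints)
    components : activation_maintenance / shortening_lengthening / fiber_work
    total : sum over sources
    normalization : "absolute" or "percent of baseline stride average"
    """

    stride_grid: np.ndarray
    sources: dict
    components: dict
    total: np.ndarray
    groups: dict = field(default_factory=dict)
    normalization: str = "absolute"

    def stride_average(self):
        return float(self.total.mean())

    def scaled(self, baseline_average: float):
        """Express the profile in percent of a baseline stride average."""
        if baseline_average == 0:
            raise ValueError("baseline average must be nonzero")
        f = 100.0 / baseline_average
        return MetabolicProfile(
            stride_grid=self.stride_grid,
            sources={k: v * f for k, v in self.sources.items()},
            components={k: v * f for k, v in self.components.items()},
            total=self.total * f,
            groups={k: v * f for k, v in self.groups.items()},
            normalization="percent of baseline stride average")


def muscle_mass(params: MuscleParams, coeffs: EnergeticsCoefficients = EnergeticsCoefficients()):
    """Muscle mass from maximum force, optimal fiber length and density (kg)."""
    return params.f_max / coeffs.specific_tension * params.l_opt * coeffs.density


def recruitment_fractions(activation, slow_twitch_ratio,
                          model: str = "orderly", exponent: float = 1.0):
    """Effective (slow, fast) fiber fractions under orderly recruitment.

    Slow fibers are recruited first: at zero activation the active pool is
    entirely slow, and at full activation the fractions equal the anatomical
    ratio.  The interpolation shape is configuration.
    """
    if model != "orderly":
        raise ValueError(f"unknown recruitment model {model!r}")
    a = np.asarray(activation, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1.0 + 1e-12):
        raise ValueError("activation must lie in [0, 1]")
    a = np.clip(a, 0.0, 1.0)
    slow = slow_twitch_ratio + (1.0 - slow_twitch_ratio) * (1.0 - a) ** exponent
    return slow, 1.0 - slow


def _drive(activation, excitation):
    """Umberger-style drive: u when rising, (u + a)/2 otherwise."""
    a = np.asarray(activation, dtype=float)
    u = np.asarray(excitation, dtype=float)
    return np.where(u > a, u, 0.5 * (u + a))


def heat_rates(activation, excitation, l_fiber, v_fiber, params: MuscleParams,
               coeffs: EnergeticsCoefficients = EnergeticsCoefficients(),
               curves: CurveSet = CurveSet()):
    """Activation-maintenance and shortening-lengthening heat rates.

    Both are in W per kg muscle mass, nonnegative, and scaled by the aerobic
    factor.  v_fiber follows the trajectory convention (m/s, lengthening
    positive).
    """
    a = np.asarray(activation, dtype=float)
    u = np.asarray(excitation, dtype=float)
    l_f = np.asarray(l_fiber, dtype=float)
    v_f = np.asarray(v_fiber, dtype=float)
    if np.any(l_f <= 0):
        raise ValueError("fiber length must be positive")
    A = _drive(a, u)
    slow, fast = recruitment_fractions(a, params.slow_twitch_ratio,
                                       coeffs.recruitment_model,
                                       coeffs.recruitment_exponent)
    lnorm = l_f / params.l_opt
    fl = musclemodel.active_force_length(lnorm, params.width, curves)
    # above optimal length both heat rates scale with the force-length value
    length_scale = np.where(lnorm > 1.0, fl, 1.0)

    am_base = coeffs.am_base_slow * slow + coeffs.am_base_fast * fast
    h_am = am_base * A**coeffs.am_exponent * length_scale * coeffs.aerobic_factor

    vmax_slow = coeffs.slow_vmax_fraction * params.v_max
    alpha_slow = coeffs.shortening_coeff_scale * coeffs.am_base_slow / vmax_slow
    alpha_fast = coeffs.am_base_fast / params.v_max
    alpha_len = coeffs.lengthening_multiple * alpha_slow

    vnorm = v_f / params.l_opt  # optimal fiber lengths per second
    shortening = np.clip(-vnorm, 0.0, None)
    lengthening = np.clip(vnorm, 0.0, None)
    h_short = ((alpha_slow * slow + alpha_fast * fast) * shortening
               * A**coeffs.shortening_exponent)
    h_len = alpha_len * lengthening * A
    h_sl = (h_short + h_len) * length_scale * coeffs.aerobic_factor
    return h_am, h_sl


def fiber_work_rate(f_ce, v_shortening, muscle_mass_kg):
    """Signed mechanical power of the contractile element, W per kg muscle.

    ``v_shortening`` is positive while the fiber shortens, so positive work
    is positive power; lengthening (negative) work is kept, not zeroed.
    """
    if muscle_mass_kg <= 0:
        raise ValueError("muscle mass must be positive")
    return np.asarray(f_ce, dtype=float) * np.asarray(v_shortening, dtype=float) / muscle_mass_kg


def total_muscle_rate(h_am, h_sl, w_fiber, muscle_mass_kg, body_mass_kg):
    """Per-muscle rate in W per kg body mass, clamped at zero per sample."""
    per_muscle = np.asarray(h_am) + np.asarray(h_sl) + np.asarray(w_fiber)
    return np.clip(per_muscle, 0.0, None) * muscle_mass_kg / body_mass_kg


def muscle_rate_components(states: dict, params: dict, body_mass,
                           coeffs: EnergeticsCoefficients = EnergeticsCoefficients(),
                           curves: CurveSet = CurveSet(), excitations: dict | None = None):
    """Per-muscle clamped total and components, W per kg body mass.

    Returns (totals dict, components dict of dicts).  Component series are
    reported on the body-mass scale before clamping, so their per-muscle sum
    equals the unclamped total.
    """
    totals, comps = {}, {}
    for name, traj in states.items():
        p = params[name]
        m_kg = muscle_mass(p, coeffs)
        exc = traj.activation if excitations is None else excitations[name]
        h_am, h_sl = heat_rates(traj.activation, exc, traj.l_fiber,
                                traj.v_fiber, p, coeffs, curves)
        w = fiber_work_rate(traj.f_ce, -traj.v_fiber, m_kg)
        totals[name] = total_muscle_rate(h_am, h_sl, w, m_kg, body_mass)
        scale = m_kg / body_mass
        comps[name] = {
            "activation_maintenance": h_am * scale,
            "shortening_lengthening": h_sl * scale,
            "fiber_work": w * scale,
        }
    return totals, comps


def limb_profile(per_muscle_rates: dict, stride_grid,
                 per_muscle_components: dict | None = None) -> MetabolicProfile:
    """Sum per-muscle rates into a limb profile with group decompositions."""
    grid = np.asarray(stride_grid, dtype=float)
    lengths = {len(v) for v in per_muscle_rates.values()}
    if lengths != {len(grid)}:
        raise ValueError("per-muscle rates must be on the stride grid")
    total = np.sum(list(per_muscle_rates.values()), axis=0)
    groups = {}
    for group, members in MUSCLE_GROUPS.items():
        present = [m for m in members if m in per_muscle_rates]
        if present:
            groups[group] = np.sum([per_muscle_rates[m] for m in present], axis=0)
    components = {}
    if per_muscle_components:
        for key in ("activation_maintenance", "shortening_lengthening", "fiber_work"):
            components[key] = np.sum(
                [c[key] for c in per_muscle_components.values()], axis=0)
    return MetabolicProfile(stride_grid=grid, sources=dict(per_muscle_rates),
                            components=components, total=total, groups=groups)


def estimate_profile(trial, params: dict | None = None, geometry=None,
                     coeffs: EnergeticsCoefficients = EnergeticsCoefficients(),
                     curves: CurveSet = CurveSet(), n_points: int = 201,
                     warmup_strides: int = 2) -> MetabolicProfile:
    """Full musculoskeletal estimate for one trial.

    Runs the EMG-driven muscle simulation, evaluates the energetics per
    muscle, segments strides from the GRFs and averages the time-normalized
    per-muscle rates over all complete strides.
    """
    from . import signals

    if params is None:
        params = musclemodel.default_params()
    if geometry is None:
        geometry = musclemodel.default_geometry()
    fs = trial.sampling_rate
    states, _, _ = musclemodel.simulate_trial(trial, params, geometry,
                                              curves=curves,
                                              warmup_strides=warmup_strides)
    excitations = {
        name: signals.normalize_emg(trial.emg_envelope[name],
                                    trial.participant.mvc[name])
        for name in params
    }
    totals, comps = muscle_rate_components(states, params,
                                           trial.participant.body_mass,
                                           coeffs, curves, excitations)
    events = signals.detect_strides(signals.filter_grf(trial.grf_vertical_ipsi, fs),
                                    signals.filter_grf(trial.grf_vertical_contra, fs),
                                    fs)
    hs = events.ipsi_heel_strikes
    grid = signals.stride_grid(n_points)

    def stride_mean(series):
        return np.mean([signals.time_normalize(series, hs[k], hs[k + 1], n_points)
                        for k in range(len(hs) - 1)], axis=0)

    per_muscle = {name: stride_mean(totals[name]) for name in totals}
    per_comps = {name: {key: stride_mean(c[key]) for key in c}
                 for name, c in comps.items()}
    return limb_profile(per_muscle, grid, per_comps)


def group_shares(profile: MetabolicProfile):
    """Stride-average share of each muscle group, percent of the limb total."""
    denom = profile.total.mean()
    if denom == 0:
        raise ValueError("limb profile has zero stride average")
    return {g: 100.0 * v.mean() / denom for g, v in profile.groups.items()}
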