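"""Numerical core of the muscle-tendon integrator.

The fiber-length ODE is integrated with a fixed-step classical Runge-Kutta
scheme.  At every derivative evaluation the fiber velocity is obtained in
closed form from the damped tendon-fiber force equilibrium: the Hill
force-velocity hyperbola plus a linear damping term is inverted analytically
(a quadratic per branch), so no iterative root finding is needed inside the
integration loop.

Two implementations are provided: a numba-compiled scalar-loop kernel (used
when numba is importable) and a vectorized numpy fallback with identical
semantics.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


_STRAIN_LIN = 0.10  # tendon curve continues linearly above this strain
_V_CAP = 5.0        # |fiber velocity| cap in units of v_max


@njit(cache=True)
def _tendon_force(strain, shape, c1):
    if strain <= 0.0:
        return 0.0
    if strain > _STRAIN_LIN:
        f_lin = c1 * (np.exp(shape * _STRAIN_LIN) - 1.0)
        slope = c1 * shape * np.exp(shape * _STRAIN_LIN)
        return f_lin + slope * (strain - _STRAIN_LIN)
    return c1 * (np.exp(shape * strain) - 1.0)


@njit(cache=True)
def _active_fl(lnorm, width, fl_shape):
    z = (lnorm - 1.0) / (fl_shape * width)
    return np.exp(-z * z)


@njit(cache=True)
def _passive_fl(lnorm, pe_shape, pe_strain):
    if lnorm <= 1.0:
        return 0.0
    return (np.exp(pe_shape * (lnorm - 1.0) / pe_strain) - 1.0) / (np.exp(pe_shape) - 1.0)


@njit(cache=True)
def _inverse_fv_damped(load, act_fl, af, plateau, ecc_k, beta):
    """Solve  act_fl*fv(v) + beta*v = load  for normalized fiber velocity v.

    v < 0 is shortening.  Both hyperbolic branches give a quadratic in v whose
    physical root is returned; the combined left-hand side is strictly
    increasing in v (beta > 0), so the solution is unique.
    """
    if load >= act_fl:
        # lengthening branch: fv = plateau - (plateau-1)/(1 + ecc_k*v)
        b = act_fl * plateau * ecc_k + beta - load * ecc_k
        c = act_fl - load  # <= 0
        disc = b * b - 4.0 * beta * ecc_k * c
        return (-b + np.sqrt(disc)) / (2.0 * beta * ecc_k)
    # shortening branch: fv = (1-u)/(1+u/af), v = -u
    inv_af = 1.0 / af
    a_q = beta * inv_af
    b_q = act_fl + beta + load * inv_af
    c_q = -(act_fl - load)  # < 0
    disc = b_q * b_q - 4.0 * a_q * c_q
    u = (-b_q + np.sqrt(disc)) / (2.0 * a_q)
    return -u


@njit(cache=True)
def _fiber_velocity(l_f, a, l_mt, l_opt, l_slack, h, v_max, width,
                    fl_shape, af, plateau, ecc_k, beta,
                    t_shape, t_c1, pe_shape, pe_strain):
    if l_f < 0.2 * l_opt:
        l_f = 0.2 * l_opt
    if l_f > 2.2 * l_opt:
        l_f = 2.2 * l_opt
    sin_a = h / l_f
    if sin_a > 0.985:
        sin_a = 0.985
    if sin_a < 0.0:
        sin_a = 0.0
    cos_a = np.sqrt(1.0 - sin_a * sin_a)
    l_t = l_mt - l_f * cos_a
    f_t = _tendon_force((l_t - l_slack) / l_slack, t_shape, t_c1)
    lnorm = l_f / l_opt
    load = f_t / cos_a - _passive_fl(lnorm, pe_shape, pe_strain)
    act_fl = a * _active_fl(lnorm, width, fl_shape)
    vn = _inverse_fv_damped(load, act_fl, af, plateau, ecc_k, beta)
    if vn > _V_CAP:
        vn = _V_CAP
    if vn < -_V_CAP:
        vn = -_V_CAP
    return vn * v_max * l_opt


@njit(cache=True)
def _n_substeps(l_opt, l_slack, v_max, dt, t_shape, t_c1, beta):
    """Substeps per sample so the fastest fiber eigenvalue stays RK4-stable.

    The dominant rate is tendon stiffness divided by the damped
    force-velocity slope: lambda ~ v_max l_opt t_shape (f + c1) / (l_slack
    beta).  Short-tendon muscles (e.g. a gluteus with a 5 cm tendon) are
    stiff and get many substeps; long-tendon muscles get one or two.
    """
    f_cap = 1.2
    lam = v_max * l_opt * t_shape * (f_cap + t_c1) / (l_slack * beta)
    n = int(np.ceil(dt * lam / 2.0))  # keep lambda * dt_sub inside RK4 stability
    if n < 1:
        n = 1
    return n


@njit(cache=True)
def integrate_fibers_numba(act, l_mt, l_f0, l_opt, l_slack, h, v_max, width,
                           dt, fl_shape, af, plateau, ecc_k, beta,
                           t_shape, t_c1, pe_shape, pe_strain):
    """RK4-integrate fiber lengths for M muscles over N samples.

    act, l_mt: (M, N); returns l_fiber (M, N).  Inputs are interpolated
    linearly onto the per-muscle substep grid.
    """
    m, n = act.shape
    out = np.empty((m, n))
    for j in range(m):
        lo, ls, hh, vm, w = l_opt[j], l_slack[j], h[j], v_max[j], width[j]
        lf = l_f0[j]
        out[j, 0] = lf
        lf_min = 0.2 * lo
        lf_max = 2.2 * lo
        n_sub = _n_substeps(lo, ls, vm, dt, t_shape, t_c1, beta)
        ds = dt / n_sub
        diverged = False
        for i in range(n - 1):
            a0 = act[j, i]
            da = (act[j, i + 1] - a0) / n_sub
            m0 = l_mt[j, i]
            dm = (l_mt[j, i + 1] - m0) / n_sub
            for s in range(n_sub):
                as0 = a0 + da * s
                as1 = a0 + da * (s + 1)
                asm = a0 + da * (s + 0.5)
                ms0 = m0 + dm * s
                ms1 = m0 + dm * (s + 1)
                msm = m0 + dm * (s + 0.5)
                k1 = _fiber_velocity(lf, as0, ms0, lo, ls, hh, vm, w, fl_shape,
                                     af, plateau, ecc_k, beta, t_shape, t_c1,
                                     pe_shape, pe_strain)
                k2 = _fiber_velocity(lf + 0.5 * ds * k1, asm, msm, lo, ls, hh,
                                     vm, w, fl_shape, af, plateau, ecc_k, beta,
                                     t_shape, t_c1, pe_shape, pe_strain)
                k3 = _fiber_velocity(lf + 0.5 * ds * k2, asm, msm, lo, ls, hh,
                                     vm, w, fl_shape, af, plateau, ecc_k, beta,
                                     t_shape, t_c1, pe_shape, pe_strain)
                k4 = _fiber_velocity(lf + ds * k3, as1, ms1, lo, ls, hh, vm, w,
                                     fl_shape, af, plateau, ecc_k, beta,
                                     t_shape, t_c1, pe_shape, pe_strain)
                lf = lf + ds / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                if lf < lf_min:
                    lf = lf_min
                if lf > lf_max:
                    lf = lf_max
            if not np.isfinite(lf):
                # signal failure with a negative sentinel the caller checks
                for t in range(i + 1, n):
                    out[j, t] = -1.0
                diverged = True
                break
            out[j, i + 1] = lf
        if diverged:
            continue
    return out


def tendon_force_np(strain, shape, c1):
    s = np.asarray(strain, dtype=float)
    f_exp = c1 * np.expm1(shape * np.clip(s, 0.0, _STRAIN_LIN))
    f_lin = c1 * np.expm1(shape * _STRAIN_LIN)
    slope = c1 * shape * np.exp(shape * _STRAIN_LIN)
    return np.where(s > _STRAIN_LIN, f_lin + slope * (s - _STRAIN_LIN),
                    np.where(s > 0.0, f_exp, 0.0))


def _fiber_velocity_np(l_f, a, l_mt, p, c):
    """Vectorized derivative over M muscles (numpy fallback)."""
    l_f = np.clip(l_f, 0.2 * p["l_opt"], 2.2 * p["l_opt"])
    sin_a = np.clip(p["h"] / l_f, 0.0, 0.985)
    cos_a = np.sqrt(1.0 - sin_a**2)
    strain = (l_mt - l_f * cos_a - p["l_slack"]) / p["l_slack"]
    f_t = tendon_force_np(strain, c["t_shape"], c["t_c1"])
    lnorm = l_f / p["l_opt"]
    f_pe = np.where(
        lnorm > 1.0,
        np.expm1(c["pe_shape"] * np.maximum(lnorm - 1.0, 0.0) / c["pe_strain"]) / np.expm1(c["pe_shape"]),
        0.0,
    )
    load = f_t / cos_a - f_pe
    z = (lnorm - 1.0) / (c["fl_shape"] * p["width"])
    act_fl = a * np.exp(-(z**2))
    beta, af, plateau, k = c["beta"], c["af"], c["plateau"], c["ecc_k"]
    # lengthening branch
    b_e = act_fl * plateau * k + beta - load * k
    v_e = (-b_e + np.sqrt(b_e**2 - 4.0 * beta * k * (act_fl - load))) / (2.0 * beta * k)
    # shortening branch
    a_q = beta / af
    b_q = act_fl + beta + load / af
    u = (-b_q + np.sqrt(np.maximum(b_q**2 + 4.0 * a_q * (act_fl - load), 0.0))) / (2.0 * a_q)
    vn = np.clip(np.where(load >= act_fl, v_e, -u), -_V_CAP, _V_CAP)
    return vn * p["v_max"] * p["l_opt"]


def integrate_fibers_numpy(act, l_mt, l_f0, l_opt, l_slack, h, v_max, width,
                           dt, fl_shape, af, plateau, ecc_k, beta,
                           t_shape, t_c1, pe_shape, pe_strain):
    p = {"l_opt": l_opt, "l_slack": l_slack, "h": h, "v_max": v_max, "width": width}
    c = {"fl_shape": fl_shape, "af": af, "plateau": plateau, "ecc_k": ecc_k,
         "beta": beta, "t_shape": t_shape, "t_c1": t_c1, "pe_shape": pe_shape,
         "pe_strain": pe_strain}
    m, n = act.shape
    out = np.empty((m, n))
    lf = l_f0.astype(float).copy()
    out[:, 0] = lf
    lo_min, lo_max = 0.2 * l_opt, 2.2 * l_opt
    f_cap = 1.2
    lam = v_max * l_opt * t_shape * (f_cap + t_c1) / (l_slack * beta)
    n_sub = max(1, int(np.ceil(dt * lam.max() / 2.0)))
    ds = dt / n_sub
    for i in range(n - 1):
        a0 = act[:, i]
        da = (act[:, i + 1] - a0) / n_sub
        m0 = l_mt[:, i]
        dm = (l_mt[:, i + 1] - m0) / n_sub
        for s in range(n_sub):
            as0, asm, as1 = a0 + da * s, a0 + da * (s + 0.5), a0 + da * (s + 1)
            ms0, msm, ms1 = m0 + dm * s, m0 + dm * (s + 0.5), m0 + dm * (s + 1)
            k1 = _fiber_velocity_np(lf, as0, ms0, p, c)
            k2 = _fiber_velocity_np(lf + 0.5 * ds * k1, asm, msm, p, c)
            k3 = _fiber_velocity_np(lf + 0.5 * ds * k2, asm, msm, p, c)
            k4 = _fiber_velocity_np(lf + ds * k3, as1, ms1, p, c)
            lf = np.clip(lf + ds / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), lo_min, lo_max)
        lf = np.where(np.isfinite(lf), lf, -1.0)
        out[:, i + 1] = lf
    return out


integrate_fibers = integrate_fibers_numba if _HAVE_NUMBA else integrate_fibers_numpy
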