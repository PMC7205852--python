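"""JIT-compiled numerical core: constitutive laws, ODE right-hand side and a
Dormand-Prince 5(4) adaptive integrator.

Everything here works on packed float64 vectors (see
``parameters.PARAM_ORDER``) so that numba can compile the whole cycle
integration into one native call; the same functions run as plain Python
when numba is unavailable or ``NUMBA_DISABLE_JIT`` is set.

State vector layout (length 7):
``[v_a, v_v, v_s, p_ic, q_v, q_s, v_comp]``.

Integrator status codes: 0 ok, 1 invariant-violating / non-finite state,
2 step size underflow, 3 step budget exhausted.
"""

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# Packed parameter indices; order must match parameters.PARAM_ORDER.
IE_A0 = 0
IR_AV0 = 1
IR_V0 = 2
IE_C0 = 3
IE_S = 4
IL_CS = 5
IR_CS = 6
IRHO_L = 7
IP_0 = 8
IB_LS = 9
IA_RS = 10
IL_V = 11
ITAU_REG = 12
IK_EA = 13
IN_EA = 14
IM_EA = 15
IN_RAV = 16
IM_RAV = 17
IE_V1 = 18
IE_V2 = 19
IM_EV1 = 20
IM_EV2 = 21
IM_RV = 22
IK_EC = 23
IV_AN = 24
IV_VN = 25
IV_SN = 26
IP_OUT = 27
IG_COMP = 28
IEPS_Q = 29
IEPS_P = 30
IC_GEO = 31
IC_COLLAPSE = 32
IRV_CAP = 33

NSTATE = 7


@njit(cache=True)
def arterial_pv_(v_a, P):
    """Arterial transmural pressure p_a - p_ic at volume v_a."""
    dv = v_a - P[IV_AN]
    x = abs(dv) / P[IV_AN]
    if x > 10.0:  # keep the high-order stiffening term finite
        x = 10.0
    stiff = (1.0 + P[IK_EA] * x ** P[IN_EA]) ** P[IM_EA]
    return P[IE_A0] * dv * stiff


@njit(cache=True)
def arteriovenous_resistance_(v_a, P):
    """Arteriovenous resistance; falls with arterial volume, rises on collapse."""
    base = P[IR_AV0] * (P[IV_AN] / v_a) ** P[IM_RAV]
    z = P[IN_RAV] * (v_a - 0.5 * P[IV_AN]) / P[IV_AN]
    if z > 700.0:
        z = 700.0
    collapse = P[IC_COLLAPSE] / (1.0 + np.exp(z))
    return base * (1.0 + collapse)


@njit(cache=True)
def venous_pv_(v_v, P):
    """Venous transmural pressure: split power law about the unstressed volume."""
    dv = v_v - P[IV_VN]
    if dv >= 0.0:
        return P[IE_V1] * dv ** P[IM_EV1]
    return -P[IE_V2] * (-dv) ** P[IM_EV2]


@njit(cache=True)
def venous_resistance_of_volume_(v_v, P):
    """Venous outflow resistance as a function of venous volume.

    Compression (v_v below the unstressed volume) narrows the lumen and
    raises the resistance, ``R_v0 * (V_vn/v_v)**m_Rv``; capped at
    ``r_v_cap * R_v0`` for deep collapse.
    """
    vmin = 1e-3 * P[IV_VN]
    if v_v < vmin:
        v_v = vmin
    r = P[IR_V0] * (P[IV_VN] / v_v) ** P[IM_RV]
    hi = P[IRV_CAP] * P[IR_V0]
    if r > hi:
        r = hi
    return r


@njit(cache=True)
def invert_venous_pv_(x, P):
    """Venous volume at transmural pressure x (closed-form inverse)."""
    if x >= 0.0:
        return P[IV_VN] + (x / P[IE_V1]) ** (1.0 / P[IM_EV1])
    return P[IV_VN] - (-x / P[IE_V2]) ** (1.0 / P[IM_EV2])


@njit(cache=True)
def venous_outflow_resistance_(p_v, p_ic, P):
    """Starling-type venous resistance from the venous-ICP pressure gap.

    The dependence on ``p_v - p_ic`` is indirect: the transmural pressure
    fixes the venous volume through the pressure-volume law, and the
    resistance rises as the compressed lumen shrinks.
    """
    v_v = invert_venous_pv_(p_v - p_ic, P)
    return venous_resistance_of_volume_(v_v, P)


@njit(cache=True)
def csf_switch_(q_s, P):
    """C1 smoothstep direction factor: 0 for inflow, 1 for outflow."""
    eps = P[IEPS_Q]
    if q_s <= -eps:
        return 0.0
    if q_s >= eps:
        return 1.0
    t = (q_s + eps) / (2.0 * eps)
    return t * t * (3.0 - 2.0 * t)


@njit(cache=True)
def craniospinal_elastance_(p_ic, P):
    """Pressure-dependent CSF-space elastance, floored at 0.1*e_c0."""
    e = P[IE_C0] * (1.0 + P[IK_EC] * (p_ic - P[IP_0]) / P[IP_0])
    floor = 0.1 * P[IE_C0]
    if e < floor:
        e = floor
    return e


@njit(cache=True)
def eval_fourier_(t, period, a0, ac, bs):
    """Evaluate a truncated Fourier series (mean a0, harmonics ac/bs)."""
    w = 2.0 * np.pi / period
    q = a0
    for k in range(ac.shape[0]):
        ang = (k + 1) * w * t
        q += ac[k] * np.cos(ang) + bs[k] * np.sin(ang)
    return q


@njit(cache=True)
def rhs_(t, y, P, period, a0, ac, bs, dy):
    """Fill dy with the state derivative; return 0 on success, 1 on bad state."""
    v_a = y[0]
    v_v = y[1]
    v_s = y[2]
    p_ic = y[3]
    q_v = y[4]
    q_s = y[5]
    v_comp = y[6]
    if not (v_a > 1e-9 and v_v > 1e-9 and v_s > 1e-9):
        return 1
    if not (np.isfinite(p_ic) and np.isfinite(q_v) and np.isfinite(q_s)):
        return 1

    p_a = p_ic + arterial_pv_(v_a, P)
    p_v = p_ic + venous_pv_(v_v, P)
    q_av = (p_a - p_v) / arteriovenous_resistance_(v_a, P)
    r_v = venous_resistance_of_volume_(v_v, P)
    p_s = P[IP_0] + P[IE_S] * (v_s - P[IV_SN])
    s = csf_switch_(q_s, P)
    r_eff = P[IR_CS] * (1.0 + P[IA_RS] * s)
    l_eff = P[IL_CS] * (1.0 + P[IB_LS] * s)
    q_a = eval_fourier_(t, period, a0, ac, bs)
    dvcomp = (P[IG_COMP] * (p_ic - P[IP_0]) - v_comp) / P[ITAU_REG]

    dy[0] = q_a - q_av
    dy[1] = q_av - q_v
    dy[2] = q_s
    dy[3] = craniospinal_elastance_(p_ic, P) * (q_a - q_v - q_s - dvcomp)
    dy[4] = ((p_v - P[IP_OUT]) - r_v * q_v) / P[IL_V]
    dy[5] = (
        (p_ic - p_s)
        - r_eff * q_s
        - P[IRHO_L] * P[IC_GEO] * q_s * abs(q_s)
    ) / l_eff
    dy[6] = dvcomp
    return 0


# Dormand-Prince 5(4) coefficients.
_C2 = 1.0 / 5.0
_C3 = 3.0 / 10.0
_C4 = 4.0 / 5.0
_C5 = 8.0 / 9.0

_A21 = 1.0 / 5.0
_A31 = 3.0 / 40.0
_A32 = 9.0 / 40.0
_A41 = 44.0 / 45.0
_A42 = -56.0 / 15.0
_A43 = 32.0 / 9.0
_A51 = 19372.0 / 6561.0
_A52 = -25360.0 / 2187.0
_A53 = 64448.0 / 6561.0
_A54 = -212.0 / 729.0
_A61 = 9017.0 / 3168.0
_A62 = -355.0 / 33.0
_A63 = 46732.0 / 5247.0
_A64 = 49.0 / 176.0
_A65 = -5103.0 / 18656.0
_B1 = 35.0 / 384.0
_B3 = 500.0 / 1113.0
_B4 = 125.0 / 192.0
_B5 = -2187.0 / 6784.0
_B6 = 11.0 / 84.0
# error weights (5th minus 4th order)
_E1 = 35.0 / 384.0 - 5179.0 / 57600.0
_E3 = 500.0 / 1113.0 - 7571.0 / 16695.0
_E4 = 125.0 / 192.0 - 393.0 / 640.0
_E5 = -2187.0 / 6784.0 + 92097.0 / 339200.0
_E6 = 11.0 / 84.0 - 187.0 / 2100.0
_E7 = -1.0 / 40.0


@njit(cache=True)
def integrate_times_(y0, times, P, period, a0, ac, bs, rtol, atol, max_steps):
    """Integrate the model over ``times``, returning the state at each point.

    Returns ``(Y, status, n_steps, n_rejected, t_last)``.
    """
    n = times.shape[0]
    Y = np.empty((n, NSTATE))
    for j in range(NSTATE):
        Y[0, j] = y0[j]
    y = y0.copy()
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    k5 = np.empty(NSTATE)
    k6 = np.empty(NSTATE)
    k7 = np.empty(NSTATE)
    ytmp = np.empty(NSTATE)
    ynew = np.empty(NSTATE)

    t = times[0]
    h = 1e-3
    nsteps = 0
    nrej = 0
    for i in range(1, n):
        tend = times[i]
        while t < tend - 1e-12:
            if h > tend - t:
                h = tend - t
            if h < 1e-12:
                return Y, 2, nsteps, nrej, t
            nsteps += 1
            if nsteps > max_steps:
                return Y, 3, nsteps, nrej, t

            bad = rhs_(t, y, P, period, a0, ac, bs, k1)
            if bad == 0:
                for j in range(NSTATE):
                    ytmp[j] = y[j] + h * _A21 * k1[j]
                bad = rhs_(t + _C2 * h, ytmp, P, period, a0, ac, bs, k2)
            if bad == 0:
                for j in range(NSTATE):
                    ytmp[j] = y[j] + h * (_A31 * k1[j] + _A32 * k2[j])
                bad = rhs_(t + _C3 * h, ytmp, P, period, a0, ac, bs, k3)
            if bad == 0:
                for j in range(NSTATE):
                    ytmp[j] = y[j] + h * (_A41 * k1[j] + _A42 * k2[j] + _A43 * k3[j])
                bad = rhs_(t + _C4 * h, ytmp, P, period, a0, ac, bs, k4)
            if bad == 0:
                for j in range(NSTATE):
                    ytmp[j] = y[j] + h * (
                        _A51 * k1[j] + _A52 * k2[j] + _A53 * k3[j] + _A54 * k4[j]
                    )
                bad = rhs_(t + _C5 * h, ytmp, P, period, a0, ac, bs, k5)
            if bad == 0:
                for j in range(NSTATE):
                    ytmp[j] = y[j] + h * (
                        _A61 * k1[j]
                        + _A62 * k2[j]
                        + _A63 * k3[j]
                        + _A64 * k4[j]
                        + _A65 * k5[j]
                    )
                bad = rhs_(t + h, ytmp, P, period, a0, ac, bs, k6)
            if bad == 0:
                for j in range(NSTATE):
                    ynew[j] = y[j] + h * (
                        _B1 * k1[j]
                        + _B3 * k3[j]
                        + _B4 * k4[j]
                        + _B5 * k5[j]
                        + _B6 * k6[j]
                    )
                bad = rhs_(t + h, ynew, P, period, a0, ac, bs, k7)

            if bad != 0:
                # a stage left the physical domain: retry with a smaller step
                nrej += 1
                h *= 0.25
                if h < 1e-12:
                    return Y, 1, nsteps, nrej, t
                continue

            errnorm = 0.0
            for j in range(NSTATE):
                e = h * (
                    _E1 * k1[j]
                    + _E3 * k3[j]
                    + _E4 * k4[j]
                    + _E5 * k5[j]
                    + _E6 * k6[j]
                    + _E7 * k7[j]
                )
                ay = abs(y[j])
                an = abs(ynew[j])
                sc = atol + rtol * (ay if ay > an else an)
                r = e / sc
                errnorm += r * r
            errnorm = np.sqrt(errnorm / NSTATE)

            if errnorm <= 1.0:
                t = t + h
                for j in range(NSTATE):
                    y[j] = ynew[j]
                if not np.isfinite(y[0]):
                    return Y, 1, nsteps, nrej, t
            else:
                nrej += 1

            if errnorm < 1e-30:
                fac = 5.0
            else:
                fac = 0.9 * errnorm ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            h *= fac
        for j in range(NSTATE):
            Y[i, j] = y[j]
    return Y, 0, nsteps, nrej, t
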