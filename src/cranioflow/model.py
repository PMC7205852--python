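"""Constitutive laws, state container and ODE right-hand side of the
craniospinal circuit model.

The model tracks seven states: arterial blood volume ``v_a``, venous blood
volume ``v_v``, spinal CSF volume ``v_s``, intracranial pressure ``p_ic``
(a state through the elastance ODE), inertial venous outflow ``q_v``,
inertial foramen-magnum CSF flow ``q_s`` (positive out of the cranium) and
the compensatory brain-displacement volume ``v_comp``.  Pressures follow by
construction: ``p_a = p_ic + arterial_pv(v_a)``, ``p_v = p_ic +
venous_pv(v_v)``, ``p_s = p_0 + e_s*(v_s - V_sn)``.

The cranium is treated as a closed, incompressible container
(Monro-Kellie): the ICP equation is driven by the instantaneous volume
imbalance ``q_a - q_v - q_s - dv_comp/dt`` scaled by the pressure-dependent
craniospinal elastance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _kernel as K
from .errors import DomainError, EquilibriumError
from .parameters import ModelParameters

__all__ = [
    "ModelState",
    "arterial_pv",
    "arteriovenous_resistance",
    "venous_pv",
    "venous_outflow_resistance",
    "csf_channel_coeffs",
    "craniospinal_elastance",
    "compensatory_rate",
    "rhs",
    "equilibrium_state",
]


@dataclass
class ModelState:
    """Instantaneous model state (units: ml, ml/s, mmHg)."""

    v_a: float
    v_v: float
    v_s: float
    p_ic: float
    q_v: float
    q_s: float
    v_comp: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.v_a, self.v_v, self.v_s, self.p_ic, self.q_v, self.q_s, self.v_comp],
            dtype=float,
        )

    @classmethod
    def from_array(cls, y) -> "ModelState":
        y = np.asarray(y, dtype=float)
        return cls(*y.tolist())

    def validate(self) -> None:
        if not (self.v_a > 0 and self.v_v > 0 and self.v_s > 0):
            raise DomainError(
                f"volumes must be strictly positive: v_a={self.v_a}, "
                f"v_v={self.v_v}, v_s={self.v_s}"
            )
        if not np.all(np.isfinite(self.to_array())):
            raise DomainError("state contains non-finite values")


def _packed(params: ModelParameters) -> np.ndarray:
    if isinstance(params, ModelParameters):
        return params.to_array()
    return np.asarray(params, dtype=float)


# ---------------------------------------------------------------------------
# constitutive laws (scalar public API over the compiled kernels)
# ---------------------------------------------------------------------------


def arterial_pv(v_a: float, params: ModelParameters) -> float:
    """Arterial transmural pressure ``p_a - p_ic`` (mmHg) at volume ``v_a``.

    Zero at the unstressed volume ``V_an`` and strictly increasing; the
    bracket ``(1 + k_ea*|dv/V_an|**n_ea)**m_ea`` stiffens the wall at large
    distension.
    """
    if v_a <= 0:
        raise DomainError(f"v_a must be > 0, got {v_a}")
    return float(K.arterial_pv_(float(v_a), _packed(params)))


def arteriovenous_resistance(v_a: float, params: ModelParameters) -> float:
    """Arteriovenous flow resistance (mmHg*s/ml) at arterial volume ``v_a``.

    ``R_av0*(V_an/v_a)**m_Rav`` (Poiseuille-like, R ~ 1/A**2 for m_Rav=2)
    times a logistic collapse factor of steepness ``n_Rav`` centred at
    ``0.5*V_an``; negligible at and above the unstressed volume.
    """
    if v_a <= 0:
        raise DomainError(f"v_a must be > 0, got {v_a}")
    return float(K.arteriovenous_resistance_(float(v_a), _packed(params)))


def venous_pv(v_v: float, params: ModelParameters) -> float:
    """Venous transmural pressure (mmHg): split power law about ``V_vn``.

    Distension branch ``e_v1*dv**m_ev1`` for ``v_v > V_vn``; collapse branch
    ``-e_v2*(-dv)**m_ev2`` below; continuous and monotone increasing.
    """
    if v_v <= 0:
        raise DomainError(f"v_v must be > 0, got {v_v}")
    return float(K.venous_pv_(float(v_v), _packed(params)))


def venous_outflow_resistance(p_v: float, p_ic: float, params: ModelParameters) -> float:
    """Starling-type venous outflow resistance (mmHg*s/ml).

    Indirectly dependent on the venous-pressure/ICP difference: the
    transmural pressure ``p_v - p_ic`` sets the venous volume through the
    pressure-volume law, and resistance rises as the compressed lumen
    narrows, ``R_v0 * (V_vn/v_v)**m_Rv``.  Equals ``R_v0`` when transmural
    compression is absent (``p_v = p_ic``), grows without bound as ICP
    rises above venous pressure and squeezes the veins (capped at
    ``r_v_cap * R_v0``), and is constant for ``m_Rv = 0``.
    """
    return float(K.venous_outflow_resistance_(float(p_v), float(p_ic), _packed(params)))


def csf_channel_coeffs(q_s: float, params: ModelParameters) -> tuple[float, float]:
    """Direction-dependent foramen-magnum (R_eff, L_eff).

    Outflow (``q_s > 0``) sees ``R_cs*(1+a_Rs)`` and ``L_cs*(1+b_Ls)``;
    inflow sees the baseline values.  The switch is a C1 smoothstep of
    half-width ``eps_q`` so the right-hand side stays continuous.
    """
    P = _packed(params)
    s = float(K.csf_switch_(float(q_s), P))
    idx_rcs, idx_ars = K.IR_CS, K.IA_RS
    r_eff = P[idx_rcs] * (1.0 + P[idx_ars] * s)
    l_eff = P[K.IL_CS] * (1.0 + P[K.IB_LS] * s)
    return float(r_eff), float(l_eff)


def craniospinal_elastance(p_ic: float, params: ModelParameters) -> float:
    """CSF-space elastance (mmHg/ml): ``e_c0*(1 + k_ec*(p_ic-p_0)/p_0)``,
    floored at ``0.1*e_c0`` (stiffening pressure-volume curve)."""
    if not np.isfinite(p_ic):
        raise DomainError(f"p_ic must be finite, got {p_ic}")
    return float(K.craniospinal_elastance_(float(p_ic), _packed(params)))


def compensatory_rate(p_ic: float, v_comp: float, params: ModelParameters) -> float:
    """Rate of compensatory brain displacement (ml/s): first-order
    relaxation of ``v_comp`` toward ``G_comp*(p_ic - p_0)`` with time
    constant ``tau_reg``."""
    return float(
        (params.G_comp * (p_ic - params.p_0) - v_comp) / params.tau_reg
    )


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def rhs(t: float, state, params: ModelParameters, inflow) -> np.ndarray:
    """State derivative at time ``t`` under the arterial-inflow forcing.

    Parameters
    ----------
    state : ModelState or array-like of length 7
    inflow : PeriodicWaveform (or any object with ``period``, ``mean`` and
        Fourier coefficient arrays ``ac``/``bs``).

    Returns
    -------
    ndarray, shape (7,)
        ``d/dt [v_a, v_v, v_s, p_ic, q_v, q_s, v_comp]``.
    """
    if isinstance(state, ModelState):
        state.validate()
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
        ModelState.from_array(y).validate()
    P = _packed(params)
    period, a0, ac, bs = _fourier_of(inflow)
    dy = np.empty(K.NSTATE)
    bad = K.rhs_(float(t), y, P, period, a0, ac, bs, dy)
    if bad:
        raise DomainError("state violates model invariants inside rhs")
    return dy


def _fourier_of(inflow):
    """Extract (period, a0, ac, bs) from a waveform object."""
    period = float(inflow.period)
    a0 = float(inflow.mean)
    ac = np.asarray(getattr(inflow, "ac"), dtype=float)
    bs = np.asarray(getattr(inflow, "bs"), dtype=float)
    return period, a0, ac, bs


# ---------------------------------------------------------------------------
# constant-inflow equilibrium
# ---------------------------------------------------------------------------


def _invert_venous_pv(x: float, params: ModelParameters) -> float:
    """Venous volume at transmural pressure x (closed-form inverse)."""
    if x >= 0:
        return params.V_vn + (x / params.e_v1) ** (1.0 / params.m_ev1)
    return params.V_vn - (-x / params.e_v2) ** (1.0 / params.m_ev2)


def equilibrium_state(
    params: ModelParameters,
    mean_inflow: float,
    p_ic: float | None = None,
) -> ModelState:
    """Steady state under constant inflow ``mean_inflow`` (ml/s).

    The model conserves a pressure-volume invariant under constant forcing
    (it has no CSF production/absorption), so constant-inflow equilibria
    form a one-parameter family indexed by ICP; by convention the
    equilibrium is anchored at ``p_ic = p_0`` unless an explicit ``p_ic``
    is given.  At equilibrium ``q_v = mean_inflow`` and ``q_s = 0``.

    Raises
    ------
    EquilibriumError
        If a bracketing root cannot be found (with diagnostics).
    """
    if mean_inflow < 0:
        raise DomainError(f"mean_inflow must be >= 0, got {mean_inflow}")
    q = float(mean_inflow)
    pic = params.p_0 if p_ic is None else float(p_ic)
    P = params.to_array()

    # venous volume: (p_v - p_out) - R_v(v_v)*q = 0 with p_v = p_ic +
    # venous_pv(v_v); monotone increasing in v_v, hence a unique root
    if q < 1e-14:
        v_v = _invert_venous_pv(params.p_out - pic, params)
        if v_v <= 0:
            raise EquilibriumError(
                f"no positive venous volume at p_v={params.p_out} (p_ic={pic})"
            )
    else:

        def g(v_v):
            r_v = K.venous_resistance_of_volume_(v_v, P)
            return (pic + K.venous_pv_(v_v, P) - params.p_out) - r_v * q

        lo = 1e-2 * params.V_vn
        hi = _invert_venous_pv(
            abs(params.p_out - pic) + params.R_v0 * q + 10.0, params
        )
        if g(lo) > 0 or g(hi) < 0:
            raise EquilibriumError(
                f"venous equilibrium not bracketed: g({lo:.3g})={g(lo):.3g}, "
                f"g({hi:.3g})={g(hi):.3g} for q={q}"
            )
        v_v = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)

    p_v_eq = pic + K.venous_pv_(v_v, P)

    # arterial volume: (p_a - p_v) - R_av(v_a)*q = 0
    def f(v_a):
        return (
            K.arterial_pv_(v_a, P)
            - (p_v_eq - pic)
            - K.arteriovenous_resistance_(v_a, P) * q
        )

    v_grid = params.V_an * np.logspace(-2, 1.3, 500)
    fv = np.array([f(v) for v in v_grid])
    sign = np.sign(fv)
    flips = np.nonzero((sign[:-1] < 0) & (sign[1:] >= 0))[0]
    if len(flips) == 0:
        raise EquilibriumError(
            "arterial equilibrium not bracketed: "
            f"f in [{fv.min():.3g}, {fv.max():.3g}] for q={q}"
        )
    i = flips[-1]
    v_a = brentq(f, v_grid[i], v_grid[i + 1], xtol=1e-13, rtol=8.9e-16)

    v_s = params.V_sn + (pic - params.p_0) / params.e_s
    v_comp = params.G_comp * (pic - params.p_0)
    state = ModelState(
        v_a=v_a, v_v=v_v, v_s=v_s, p_ic=pic, q_v=q, q_s=0.0, v_comp=v_comp
    )
    state.validate()
    return state
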