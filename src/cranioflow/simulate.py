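"""Periodic steady-state simulation of the craniospinal circuit.

The model is forced with a cardiac-period-periodic arterial inflow and
integrated cycle by cycle from the constant-inflow equilibrium until two
consecutive cycles are indistinguishable (sup-norm on ICP and on the
flows over a fixed phase grid).  The converged cycle is the model's
prediction of the ICP pulse waveform, venous outflow and foramen-magnum
CSF flow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel as K
from .errors import ConvergenceError, IntegrationError
from .model import ModelState, _fourier_of, equilibrium_state
from .parameters import ModelParameters

__all__ = [
    "Trajectory",
    "CycleOutputs",
    "integrate_cycles",
    "run_to_steady_state",
    "conservation_residual",
]

#: Output phase resolution: number of intervals per cardiac cycle.
POINTS_PER_CYCLE = 200

_STATUS_MSG = {
    1: "state left the physical domain",
    2: "step size underflow",
    3: "step budget exhausted",
}


@dataclass
class Trajectory:
    """A resolved multi-cycle integration on a fixed per-cycle phase grid."""

    t: np.ndarray             # time grid, s
    y: np.ndarray             # states, shape (len(t), 7)
    q_a: np.ndarray           # inflow samples, ml/s
    stats: dict = field(default_factory=dict)

    @property
    def icp(self) -> np.ndarray:
        return self.y[:, 3]


@dataclass
class CycleOutputs:
    """One steady-state cardiac cycle of model outputs on a phase grid."""

    phase: np.ndarray         # s, 0 .. period inclusive
    icp: np.ndarray           # mmHg
    q_a: np.ndarray           # ml/s, arterial inflow
    q_v: np.ndarray           # ml/s, venous outflow
    q_s: np.ndarray           # ml/s, foramen-magnum CSF flow (positive out)
    v_a: np.ndarray           # ml
    v_v: np.ndarray           # ml
    v_s: np.ndarray           # ml
    v_comp: np.ndarray        # ml
    period: float             # s
    n_cycles_to_steady: int
    solver_stats: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        """Write the cycle as CSV plus a JSON sidecar with metadata."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_s": self.phase,
                "icp_mmHg": self.icp,
                "qa_ml_s": self.q_a,
                "qv_ml_s": self.q_v,
                "qs_ml_s": self.q_s,
                "va_ml": self.v_a,
                "vv_ml": self.v_v,
                "vs_ml": self.v_s,
                "vcomp_ml": self.v_comp,
            }
        )
        path = Path(path)
        df.to_csv(path, index=False)
        sidecar = {
            "period_s": self.period,
            "n_cycles_to_steady": self.n_cycles_to_steady,
            "solver_stats": {
                k: (int(v) if isinstance(v, (int, np.integer)) else v)
                for k, v in self.solver_stats.items()
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @property
    def pulse_amplitude(self) -> float:
        """Peak-to-trough ICP excursion over the cycle, mmHg."""
        return float(self.icp.max() - self.icp.min())


def _integrate_grid(y0, times, P, period, a0, ac, bs, rtol, atol, max_steps):
    """Kernel integration with a scipy LSODA fallback for stiff episodes."""
    Y, status, nsteps, nrej, t_last = K.integrate_times_(
        y0, times, P, period, a0, ac, bs, rtol, atol, max_steps
    )
    if status == 0:
        return Y, {"n_steps": int(nsteps), "n_rejected": int(nrej), "method": "dp45"}
    if status == 1:
        raise IntegrationError(
            f"integration failed at t={t_last:.6g}: {_STATUS_MSG[status]}",
            last_time=float(t_last),
            last_state=Y[max(int(np.searchsorted(times, t_last)) - 1, 0)].copy(),
        )
    # stiff fallback
    from scipy.integrate import solve_ivp

    def f(t, y):
        dy = np.empty(K.NSTATE)
        bad = K.rhs_(t, y, P, period, a0, ac, bs, dy)
        if bad:
            return np.full(K.NSTATE, np.nan)
        return dy

    sol = solve_ivp(
        f,
        (times[0], times[-1]),
        np.asarray(y0, dtype=float),
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"stiff-fallback integration failed: {sol.message}",
            last_time=float(sol.t[-1]) if len(sol.t) else float(times[0]),
            last_state=sol.y[:, -1].copy() if sol.y.size else np.asarray(y0),
        )
    return sol.y.T.copy(), {
        "n_steps": int(nsteps),
        "n_rejected": int(nrej),
        "method": "lsoda-fallback",
    }


def integrate_cycles(
    params: ModelParameters,
    inflow,
    n_cycles: int,
    *,
    y0=None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    points_per_cycle: int = POINTS_PER_CYCLE,
    max_steps_per_cycle: int = 200_000,
) -> Trajectory:
    """Integrate ``n_cycles`` cardiac periods from the constant-inflow
    equilibrium (or from ``y0``), resampled to a fixed per-cycle phase grid.

    The output grid has ``n_cycles * points_per_cycle + 1`` samples.
    """
    if n_cycles < 0:
        raise ValueError(f"n_cycles must be >= 0, got {n_cycles}")
    period, a0, ac, bs = _fourier_of(inflow)
    if y0 is None:
        y0 = equilibrium_state(params, a0).to_array()
    elif isinstance(y0, ModelState):
        y0 = y0.to_array()
    else:
        y0 = np.asarray(y0, dtype=float)
    P = params.to_array()

    times = np.linspace(0.0, n_cycles * period, n_cycles * points_per_cycle + 1)
    if n_cycles == 0:
        q_a = np.array([K.eval_fourier_(0.0, period, a0, ac, bs)])
        return Trajectory(t=times, y=y0[None, :].copy(), q_a=q_a, stats={"n_steps": 0})

    Y, stats = _integrate_grid(
        y0, times, P, period, a0, ac, bs, rtol, atol, max_steps_per_cycle * n_cycles
    )
    q_a = np.array([K.eval_fourier_(t, period, a0, ac, bs) for t in times])
    return Trajectory(t=times, y=Y, q_a=q_a, stats=stats)


def run_to_steady_state(
    params: ModelParameters,
    inflow,
    *,
    tol: float = 0.01,
    flow_tol: float = 0.01,
    vol_tol: float = 1e-4,
    max_cycles: int = 200,
    y0=None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    points_per_cycle: int = POINTS_PER_CYCLE,
) -> tuple[CycleOutputs, int]:
    """Iterate single cardiac cycles until a periodic steady state.

    Convergence requires the sup-norm cycle-to-cycle difference on the
    phase grid to fall below ``tol`` (mmHg) for ICP, below ``flow_tol``
    (ml/s) for the venous and CSF flows, and below ``vol_tol`` (ml) for
    the volume states.  The volume tolerance default is the volume
    equivalent of the ICP tolerance at the craniospinal elastance scale
    (0.01 mmHg / ~100 mmHg/ml); without it the slow compensatory
    displacement can still be drifting when the ICP trace has settled.

    Returns
    -------
    (CycleOutputs, int)
        The converged cycle and the number of cycles simulated.

    Raises
    ------
    ConvergenceError
        If ``max_cycles`` is reached; carries the residual history.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if max_cycles < 1:
        raise ValueError(f"max_cycles must be >= 1, got {max_cycles}")
    period, a0, ac, bs = _fourier_of(inflow)
    if y0 is None:
        y = equilibrium_state(params, a0).to_array()
    elif isinstance(y0, ModelState):
        y = y0.to_array()
    else:
        y = np.asarray(y0, dtype=float).copy()
    P = params.to_array()

    phase = np.linspace(0.0, period, points_per_cycle + 1)
    q_a = np.array([K.eval_fourier_(t, period, a0, ac, bs) for t in phase])
    prev = None
    history: list[float] = []
    tot_stats = {"n_steps": 0, "n_rejected": 0, "method": "dp45"}

    for cycle in range(1, max_cycles + 1):
        # the forcing is periodic: integrate each cycle on [0, T]
        Y, stats = _integrate_grid(
            y, phase, P, period, a0, ac, bs, rtol, atol, 200_000
        )
        tot_stats["n_steps"] += stats["n_steps"]
        tot_stats["n_rejected"] += stats["n_rejected"]
        if stats["method"] != "dp45":
            tot_stats["method"] = stats["method"]
        y = Y[-1].copy()
        if prev is not None:
            d_icp = float(np.max(np.abs(Y[:, 3] - prev[:, 3])))
            d_flow = float(
                max(
                    np.max(np.abs(Y[:, 4] - prev[:, 4])),
                    np.max(np.abs(Y[:, 5] - prev[:, 5])),
                )
            )
            d_vol = float(
                np.max(np.abs(Y[:, [0, 1, 2, 6]] - prev[:, [0, 1, 2, 6]]))
            )
            history.append(d_icp)
            if d_icp < tol and d_flow < flow_tol and d_vol < vol_tol:
                out = CycleOutputs(
                    phase=phase.copy(),
                    icp=Y[:, 3].copy(),
                    q_a=q_a.copy(),
                    q_v=Y[:, 4].copy(),
                    q_s=Y[:, 5].copy(),
                    v_a=Y[:, 0].copy(),
                    v_v=Y[:, 1].copy(),
                    v_s=Y[:, 2].copy(),
                    v_comp=Y[:, 6].copy(),
                    period=period,
                    n_cycles_to_steady=cycle,
                    solver_stats=tot_stats,
                )
                return out, cycle
        prev = Y

    raise ConvergenceError(
        f"no periodic steady state after {max_cycles} cycles "
        f"(last ICP residual {history[-1]:.3g} mmHg, tol {tol})",
        residual_history=history,
    )


def conservation_residual(cycle: CycleOutputs) -> float:
    """Net cranial volume bookkeeping error over one cycle (ml).

    Integrates the ICP drive term ``q_a - q_v - q_s - dv_comp/dt`` over the
    cycle and subtracts the net change of stored blood volume
    ``v_a + v_v``; at a true periodic steady state both vanish, so the
    residual is ~0 (up to quadrature error).
    """
    if len(cycle.phase) == 0:
        raise ValueError("cycle arrays are empty")
    dvcomp = cycle.v_comp[-1] - cycle.v_comp[0]
    net_drive = (
        np.trapezoid(cycle.q_a - cycle.q_v - cycle.q_s, cycle.phase) - dvcomp
    )
    stored = (cycle.v_a[-1] + cycle.v_v[-1]) - (cycle.v_a[0] + cycle.v_v[0])
    return float(net_drive - stored)
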