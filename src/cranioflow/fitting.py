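"""Goodness-of-fit, parameter-sensitivity screening and SCE-UA calibration.

The model is calibrated against a measured mean ICP cycle by maximizing
the coefficient of determination R^2 between the measured curve and the
simulated periodic-steady-state ICP on a common phase grid.  The global
search is the Shuffled Complex Evolution algorithm (SCE-UA: a population
is partitioned into complexes, each evolved by competitive downhill
simplex steps, then shuffled), which is robust for small numbers of free
parameters of a nonlinear ODE model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConvergenceError,
    CranioflowError,
    DomainError,
    EquilibriumError,
    FitError,
    IntegrationError,
)
from .parameters import FITTED_NAMES, ModelParameters
from .simulate import POINTS_PER_CYCLE, run_to_steady_state

__all__ = [
    "r_squared",
    "FitResult",
    "SensitivityTable",
    "sensitivity_scan",
    "sce_fit",
]

#: Parameters searched in linear space (dimensionless exponents, may be 0).
_LINEAR_SPACE = frozenset({"n_ea", "m_ea", "n_Rav", "m_Rav", "m_ev1", "m_ev2",
                           "m_Rv", "k_ea", "k_ec", "a_Rs", "b_Ls", "rho_l"})
_EXPONENT_BOUND = (0.0, 50.0)
_FAIL_OBJECTIVE = 1e6


def r_squared(measured, simulated) -> float:
    """Coefficient of determination 1 - SSE/SST of ``simulated`` against
    ``measured`` on a common grid.

    SST is taken about the measured mean; the value is <= 1 and may be
    negative for fits worse than the mean.  A constant measured curve
    (SST = 0) is an error.
    """
    m = np.asarray(measured, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if m.shape != s.shape:
        raise DomainError(f"curve shapes differ: {m.shape} vs {s.shape}")
    sst = float(np.sum((m - m.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("measured curve is constant (SST = 0); R^2 undefined")
    sse = float(np.sum((m - s) ** 2))
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# sensitivity screening
# ---------------------------------------------------------------------------


@dataclass
class SensitivityTable:
    """One-at-a-time sensitivity screen around a parameter set.

    ``table`` has one row per perturbed parameter with the relative
    effects of a +/- ``rel_step`` perturbation on mean ICP and ICP pulse
    amplitude, the R^2 of the perturbed against the unperturbed cycle
    (reported as the effect ``1 - R^2``), the rank by overall effect and
    an ``insensitive`` flag (all effects below 1%).
    """

    table: pd.DataFrame
    rel_step: float

    def to_csv(self, path) -> None:
        self.table.to_csv(Path(path), index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"rel_step": self.rel_step,
                 "rows": self.table.to_dict(orient="records")},
                indent=2,
            )
            + "\n"
        )

    @property
    def insensitive_names(self) -> list[str]:
        t = self.table
        return list(t.loc[t["insensitive"], "parameter"])


#: Effects below this threshold on every statistic flag a parameter insensitive.
INSENSITIVITY_THRESHOLD = 0.01


def sensitivity_scan(
    params: ModelParameters,
    inflow,
    rel_step: float = 0.2,
    *,
    names=None,
    tol: float = 0.01,
    max_cycles: int = 200,
) -> SensitivityTable:
    """Screen each fitted parameter by one-at-a-time +/- perturbation.

    Every perturbed set is re-run to its periodic steady state; the
    recorded effects are relative changes of mean ICP and pulse
    amplitude (the larger of the + and - effect) and ``1 - R^2`` of the
    perturbed ICP cycle against the base cycle.  A perturbation that
    fails to converge is flagged, not fatal.
    """
    if not 0.0 < rel_step < 1.0:
        raise DomainError(f"rel_step must be in (0, 1), got {rel_step}")
    names = list(names) if names is not None else list(FITTED_NAMES)
    base_cycle, _ = run_to_steady_state(params, inflow, tol=tol, max_cycles=max_cycles)
    base_mean = float(base_cycle.icp.mean())
    base_amp = float(base_cycle.pulse_amplitude)

    rows = []
    for name in names:
        value = getattr(params, name)
        eff_mean = eff_amp = eff_r2 = 0.0
        failed = False
        for sign in (+1.0, -1.0):
            new = value * (1.0 + sign * rel_step)
            try:
                pert = params.replace(**{name: new})
                cyc, _ = run_to_steady_state(
                    pert, inflow, tol=tol, max_cycles=max_cycles
                )
            except CranioflowError:
                failed = True
                continue
            eff_mean = max(eff_mean, abs(cyc.icp.mean() - base_mean) / abs(base_mean))
            eff_amp = max(eff_amp, abs(cyc.pulse_amplitude - base_amp) / base_amp)
            eff_r2 = max(eff_r2, 1.0 - r_squared(base_cycle.icp, cyc.icp))
        rows.append(
            {
                "parameter": name,
                "effect_mean_icp": eff_mean,
                "effect_pulse_amplitude": eff_amp,
                "effect_one_minus_r2": eff_r2,
                "failed": failed,
                "insensitive": (not failed)
                and max(eff_mean, eff_amp, eff_r2) < INSENSITIVITY_THRESHOLD,
            }
        )
    df = pd.DataFrame(rows)
    overall = df[["effect_mean_icp", "effect_pulse_amplitude",
                  "effect_one_minus_r2"]].max(axis=1)
    df["rank"] = overall.rank(ascending=False, method="first").astype(int)
    df = df.sort_values("rank", ignore_index=True)
    return SensitivityTable(table=df, rel_step=rel_step)


# ---------------------------------------------------------------------------
# SCE-UA
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of an SCE-UA calibration."""

    params: ModelParameters
    free_names: list
    r_squared: float
    n_evaluations: int
    converged: bool
    seed: int
    residual: np.ndarray          # measured - simulated on the phase grid
    bounds: dict
    objective_trace: list = field(default_factory=list)
    bound_touched: list = field(default_factory=list)
    n_shuffles: int = 0

    def to_json(self, path) -> None:
        payload = {
            "free_names": list(self.free_names),
            "fitted": {n: getattr(self.params, n) for n in self.free_names},
            "r_squared": self.r_squared,
            "n_evaluations": self.n_evaluations,
            "n_shuffles": self.n_shuffles,
            "converged": self.converged,
            "seed": self.seed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "bound_touched": list(self.bound_touched),
            "objective_trace": [float(v) for v in self.objective_trace],
            "params": self.params.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _default_bounds(name: str, reference: ModelParameters) -> tuple[float, float]:
    if name in {"n_ea", "m_ea", "n_Rav", "m_Rav", "m_ev1", "m_ev2", "m_Rv"}:
        return _EXPONENT_BOUND
    ref = getattr(reference, name)
    if ref <= 0:  # non-negative coefficients that default to ~0
        return (0.0, 1.0)
    return (0.1 * ref, 10.0 * ref)


class _Space:
    """Maps free parameters to the unit hypercube (log10 for scale
    parameters, linear for exponents and coefficients that may be 0)."""

    def __init__(self, names, bounds):
        self.names = list(names)
        self.lo = np.empty(len(self.names))
        self.hi = np.empty(len(self.names))
        self.logscale = np.zeros(len(self.names), dtype=bool)
        for i, n in enumerate(self.names):
            lo, hi = bounds[n]
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise DomainError(f"invalid bounds for {n}: {(lo, hi)}")
            use_log = n not in _LINEAR_SPACE and lo > 0
            self.logscale[i] = use_log
            self.lo[i] = np.log10(lo) if use_log else lo
            self.hi[i] = np.log10(hi) if use_log else hi

    @property
    def dim(self):
        return len(self.names)

    def to_unit(self, values):
        v = np.asarray(values, dtype=float).copy()
        v[self.logscale] = np.log10(v[self.logscale])
        return (v - self.lo) / (self.hi - self.lo)

    def from_unit(self, x):
        v = self.lo + np.clip(x, 0.0, 1.0) * (self.hi - self.lo)
        v = np.where(self.logscale, 10.0 ** v, v)
        return v


def _sce_minimize(
    func,
    x0,
    dim,
    rng,
    n_complexes=4,
    max_loops=30,
    stall_loops=5,
    rel_tol=1e-4,
    abs_tol=1e-10,
    max_evals=None,
):
    """SCE-UA global minimization on the unit hypercube.

    Stops on the shuffling-loop budget, on relative stall of the best
    objective over ``stall_loops`` loops, on population collapse, or on
    an absolute objective floor ``abs_tol`` (for objectives whose perfect
    value is 0, e.g. 1 - R^2 on noiseless data).

    Returns ``(x_best, f_best, n_evals, trace, n_loops, converged)``.
    """
    m = 2 * dim + 1                 # points per complex
    q = dim + 1                     # simplex size
    s = n_complexes * m             # population
    if max_evals is None:
        max_evals = 100 * s * max_loops

    X = rng.random((s, dim))
    if x0 is not None:
        X[0] = np.clip(x0, 0.0, 1.0)
    F = np.array([func(x) for x in X])
    n_evals = s
    order = np.argsort(F)
    X, F = X[order], F[order]
    trace = [float(F[0])]
    weights = (m - np.arange(m)) / (m * (m + 1) / 2.0)  # triangular

    converged = False
    loop = 0
    for loop in range(1, max_loops + 1):
        for c in range(n_complexes):
            idx = np.arange(c, s, n_complexes)  # systematic partition
            cx, cf = X[idx].copy(), F[idx].copy()
            for _ in range(m):  # CCE inner evolutions
                chosen = rng.choice(m, size=q, replace=False, p=weights)
                chosen.sort()
                worst = chosen[-1]
                others = chosen[:-1]
                g = cx[others].mean(axis=0)
                r = 2.0 * g - cx[worst]
                if np.any(r < 0.0) or np.any(r > 1.0):
                    r = rng.random(dim)
                fr = func(r)
                n_evals += 1
                if fr < cf[worst]:
                    cx[worst], cf[worst] = r, fr
                else:
                    cc = 0.5 * (g + cx[worst])
                    fc = func(cc)
                    n_evals += 1
                    if fc < cf[worst]:
                        cx[worst], cf[worst] = cc, fc
                    else:
                        z = rng.random(dim)
                        cx[worst], cf[worst] = z, func(z)
                        n_evals += 1
                order = np.argsort(cf)
                cx, cf = cx[order], cf[order]
            X[idx], F[idx] = cx, cf
        order = np.argsort(F)
        X, F = X[order], F[order]
        trace.append(float(F[0]))
        if trace[-1] < abs_tol:
            converged = True
            break
        if len(trace) > stall_loops:
            past = trace[-stall_loops - 1]
            if abs(past - trace[-1]) < rel_tol * max(abs(past), 1e-12):
                converged = True
                break
        if np.max(np.ptp(X, axis=0)) < 1e-8:
            converged = True
            break
        if n_evals >= max_evals:
            break
    return X[0], float(F[0]), n_evals, trace, loop, converged


def _target_on_phase_grid(measured_icp, points_per_cycle):
    """Resample a measured ICP cycle to the simulator's open phase grid."""
    from .dataio import SampledCurve, resample_periodic

    if isinstance(measured_icp, SampledCurve):
        if measured_icp.period is None:
            raise DomainError("measured ICP cycle must be marked periodic")
        res = resample_periodic(measured_icp, points_per_cycle)
        return res.values, float(measured_icp.period)
    arr = np.asarray(measured_icp, dtype=float)
    if len(arr) != points_per_cycle:
        raise DomainError(
            f"raw measured array must have {points_per_cycle} samples; "
            "pass a SampledCurve with a period for resampling"
        )
    return arr, None


def sce_fit(
    measured_icp,
    inflow,
    free_names,
    *,
    params: ModelParameters | None = None,
    bounds: dict | None = None,
    seed: int = 0,
    n_complexes: int = 4,
    max_loops: int = 30,
    stall_loops: int = 5,
    rel_tol: float = 1e-4,
    tol: float = 0.01,
    vol_tol: float = 1e-3,
    max_cycles: int = 200,
    max_evals: int | None = None,
) -> FitResult:
    """Calibrate free parameters against a measured ICP cycle with SCE-UA.

    Parameters
    ----------
    measured_icp : SampledCurve (periodic, mmHg) or array on the
        simulator phase grid.
    inflow : PeriodicWaveform forcing (must share the measured period).
    free_names : names of the parameters to calibrate (subset of the
        fitted parameter set); an empty set simply scores the initial
        parameters.
    params : starting/fixed parameter set (default: population mean).
    bounds : per-name (lo, hi); defaults to [0.1x, 10x] of the mean
        preset (exponents [0, 50]).
    seed : RNG seed; runs are fully reproducible given the seed.

    Each objective evaluation runs the model to its periodic steady
    state and scores 1 - R^2; failed simulations score a large penalty.

    Raises
    ------
    FitError
        If every objective evaluation failed.
    """
    params = params if params is not None else ModelParameters()
    free_names = list(free_names)
    unknown = set(free_names) - set(FITTED_NAMES)
    if unknown:
        raise DomainError(f"not fitted parameters: {sorted(unknown)}")

    target, period = _target_on_phase_grid(measured_icp, POINTS_PER_CYCLE)
    if period is not None and abs(period - inflow.period) > 1e-9 * inflow.period:
        raise DomainError(
            f"measured cycle period {period} != inflow period {inflow.period}"
        )

    reference = ModelParameters()
    all_bounds = {n: _default_bounds(n, reference) for n in free_names}
    if bounds:
        all_bounds.update({k: tuple(v) for k, v in bounds.items() if k in all_bounds})

    def simulate_icp(p):
        # the ICP-shape objective does not need the tight volume
        # periodicity of the reported cycle, so fits use a looser vol_tol
        cyc, _ = run_to_steady_state(
            p, inflow, tol=tol, vol_tol=vol_tol, max_cycles=max_cycles
        )
        return cyc.icp[:-1]  # open grid

    def score(p):
        return 1.0 - r_squared(target, simulate_icp(p))

    if not free_names:
        r2 = 1.0 - score(params)
        return FitResult(
            params=params,
            free_names=[],
            r_squared=r2,
            n_evaluations=1,
            converged=True,
            seed=seed,
            residual=target - simulate_icp(params),
            bounds={},
        )

    space = _Space(free_names, all_bounds)
    n_ok = 0

    def objective(x):
        nonlocal n_ok
        values = space.from_unit(x)
        try:
            p = params.replace(**dict(zip(free_names, values)))
            f = score(p)
        except (ConvergenceError, EquilibriumError, IntegrationError,
                DomainError):
            return _FAIL_OBJECTIVE
        n_ok += 1
        return f

    rng = np.random.default_rng(seed)
    x_best, f_best, n_evals, trace, n_loops, converged = _sce_minimize(
        objective,
        space.to_unit([getattr(params, n) for n in free_names]),
        space.dim,
        rng,
        n_complexes=n_complexes,
        max_loops=max_loops,
        stall_loops=stall_loops,
        rel_tol=rel_tol,
        max_evals=max_evals,
    )
    if n_ok == 0:
        raise FitError("every objective evaluation failed to converge")

    best_values = space.from_unit(x_best)
    fitted = params.replace(**dict(zip(free_names, best_values)))
    sim = simulate_icp(fitted)
    r2 = r_squared(target, sim)

    touched = []
    for i, n in enumerate(free_names):
        lo, hi = all_bounds[n]
        span = hi - lo
        if best_values[i] <= lo + 1e-3 * span or best_values[i] >= hi - 1e-3 * span:
            touched.append(n)

    return FitResult(
        params=fitted,
        free_names=free_names,
        r_squared=r2,
        n_evaluations=n_evals,
        converged=converged,
        seed=seed,
        residual=target - sim,
        bounds=all_bounds,
        objective_trace=trace,
        bound_touched=touched,
        n_shuffles=n_loops,
    )
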