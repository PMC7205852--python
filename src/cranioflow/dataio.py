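"""Curve file I/O and preprocessing.

Curves are two-column CSV files (``time_s,value``) holding either flow
(ml/s) or pressure (mmHg) samples.  Preprocessing mirrors what is done to
clinical data before model fitting: scaling measured jugular outflow so
its cycle integral matches the arterial inflow (jugular veins do not
carry all cranial venous outflow), averaging the beat-to-beat ICP curves
recorded over one respiratory cycle into a single mean cycle, and
resampling sparse periodic PC-MRI curves onto the simulator's phase grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CurveFormatError

__all__ = [
    "SampledCurve",
    "read_curve",
    "write_curve",
    "scale_venous_outflow",
    "mean_respiratory_cycle_icp",
    "resample_periodic",
    "detect_respiratory_boundaries",
]

_UNITS = ("ml/s", "mmHg")


@dataclass
class SampledCurve:
    """A time-stamped sampled signal with a units tag.

    ``period`` marks the curve as one period of a periodic signal; it is
    required by :func:`resample_periodic`.
    """

    t: np.ndarray
    values: np.ndarray
    units: str
    period: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.values.shape:
            raise CurveFormatError(
                f"time and value arrays must be 1-D and equal length, "
                f"got {self.t.shape} and {self.values.shape}"
            )
        if len(self.t) == 0:
            raise CurveFormatError("curve is empty")
        if np.any(np.diff(self.t) <= 0):
            raise CurveFormatError("time stamps must be strictly increasing")
        if self.units not in _UNITS:
            raise CurveFormatError(
                f"units must be one of {_UNITS}, got {self.units!r}"
            )

    def __len__(self) -> int:
        return len(self.t)

    def cycle_integral(self) -> float:
        """Trapezoidal integral over the stored samples.

        For a curve marked periodic whose grid omits the endpoint, the
        wrap-around segment is included.
        """
        area = float(np.trapezoid(self.values, self.t))
        if self.period is not None and self.t[-1] - self.t[0] < self.period:
            # close the cycle: wrap last sample to first
            dt = self.period - (self.t[-1] - self.t[0])
            area += 0.5 * (self.values[-1] + self.values[0]) * dt
        return area

    def copy(self, **changes) -> "SampledCurve":
        kw = dict(t=self.t.copy(), values=self.values.copy(),
                  units=self.units, period=self.period)
        kw.update(changes)
        return SampledCurve(**kw)


def read_curve(path, expected_units: str) -> SampledCurve:
    """Read a two-column CSV (``time_s,value``) into a SampledCurve.

    Raises :class:`CurveFormatError` on missing columns, non-monotone
    time stamps, an empty table, or a units tag not in {ml/s, mmHg}.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CurveFormatError(f"{path}: file is empty") from None
    if not {"time_s", "value"}.issubset(df.columns):
        raise CurveFormatError(
            f"{path}: expected columns 'time_s,value', got {list(df.columns)}"
        )
    if len(df) == 0:
        raise CurveFormatError(f"{path}: no data rows")
    period = df.attrs.get("period") if hasattr(df, "attrs") else None
    try:
        return SampledCurve(
            t=df["time_s"].to_numpy(float),
            values=df["value"].to_numpy(float),
            units=expected_units,
            period=period,
        )
    except CurveFormatError as e:
        raise CurveFormatError(f"{path}: {e}") from None


def write_curve(curve: SampledCurve, path) -> None:
    """Write a curve as ``time_s,value`` CSV at full float precision."""
    df = pd.DataFrame({"time_s": curve.t, "value": curve.values})
    df.to_csv(Path(path), index=False, float_format="%.17g")


def scale_venous_outflow(
    venous: SampledCurve, arterial: SampledCurve
) -> tuple[SampledCurve, float]:
    """Scale venous outflow so its cycle integral equals the arterial one.

    Jugular-vein flow misses other venous drainage routes, so the measured
    venous curve is multiplied by ``(arterial cycle integral)/(venous
    cycle integral)``.

    Returns the scaled curve and the factor.
    """
    ia = arterial.cycle_integral()
    iv = venous.cycle_integral()
    if iv == 0.0:
        raise CurveFormatError("venous cycle integral is zero; cannot scale")
    factor = ia / iv
    return venous.copy(values=venous.values * factor), float(factor)


def mean_respiratory_cycle_icp(
    icp: SampledCurve, boundaries, n_phase: int | None = None
) -> SampledCurve:
    """Average the cardiac-cycle ICP segments recorded over one
    respiratory cycle into a single mean ICP cycle.

    ``boundaries`` are the cardiac cycle onset times (>= 2, within the
    series); each segment is resampled to a common phase grid by linear
    interpolation and the segments are averaged pointwise.  The result's
    period is the mean segment duration.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.ndim != 1 or len(b) < 2:
        raise CurveFormatError("need at least two cycle boundaries")
    if np.any(np.diff(b) <= 0):
        raise CurveFormatError("boundaries must be strictly increasing")
    if b[0] < icp.t[0] - 1e-12 or b[-1] > icp.t[-1] + 1e-12:
        raise CurveFormatError(
            f"boundaries [{b[0]}, {b[-1]}] outside series "
            f"[{icp.t[0]}, {icp.t[-1]}]"
        )
    durations = np.diff(b)
    period = float(durations.mean())
    if n_phase is None:
        dt = float(np.median(np.diff(icp.t)))
        n_phase = max(int(round(period / dt)), 8)
    phase = np.linspace(0.0, 1.0, n_phase, endpoint=False)
    segs = np.empty((len(durations), n_phase))
    for i, (t0, t1) in enumerate(zip(b[:-1], b[1:])):
        segs[i] = np.interp(t0 + phase * (t1 - t0), icp.t, icp.values)
    return SampledCurve(
        t=phase * period, values=segs.mean(axis=0), units=icp.units, period=period
    )


def resample_periodic(
    curve: SampledCurve, n_out: int, method: str = "fourier"
) -> SampledCurve:
    """Resample one period of a periodic curve onto ``n_out`` uniform
    phase points (endpoint excluded).

    ``method="fourier"`` (default) uses trigonometric interpolation,
    which reproduces band-limited signals exactly and preserves the cycle
    integral of a uniform grid to round-off; ``method="spline"`` uses a
    periodic cubic spline.
    """
    from .waveforms import PeriodicWaveform

    if curve.period is None:
        raise CurveFormatError("curve is not marked periodic (period is None)")
    if n_out < 2:
        raise CurveFormatError(f"n_out must be >= 2, got {n_out}")
    T = float(curve.period)
    t0 = curve.t[0]
    t_out = np.arange(n_out) * (T / n_out)

    t_rel = curve.t - t0
    uniform = np.allclose(
        t_rel, np.arange(len(curve)) * (T / len(curve)), atol=1e-9 * T
    )
    if method == "fourier":
        if uniform:
            vals = curve.values
        else:
            # regularize first with a periodic spline on a dense grid
            vals = _periodic_spline_eval(
                t_rel, curve.values, T, np.arange(4 * len(curve)) * (T / (4 * len(curve)))
            )
        wave = PeriodicWaveform.from_samples(vals, T)
        out = wave(t_out)
    elif method == "spline":
        out = _periodic_spline_eval(t_rel, curve.values, T, t_out)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SampledCurve(t=t0 + t_out, values=out, units=curve.units, period=T)


def _periodic_spline_eval(t, values, period, t_new):
    from scipy.interpolate import CubicSpline

    tt = np.concatenate([t, [t[0] + period]])
    vv = np.concatenate([values, [values[0]]])
    cs = CubicSpline(tt, vv, bc_type="periodic")
    return cs((np.asarray(t_new) - t[0]) % period + t[0])


def detect_respiratory_boundaries(
    icp: SampledCurve, heart_rate_hint: float = 60.0
) -> np.ndarray:
    """Heuristic cardiac-cycle onset detector (helper, not a core contract).

    Onsets are placed at the troughs preceding each systolic ICP upstroke,
    found as local minima separated by at least half the expected cardiac
    period.
    """
    from scipy.signal import find_peaks

    expected = 60.0 / heart_rate_hint
    dt = float(np.median(np.diff(icp.t)))
    dist = max(int(0.5 * expected / dt), 1)
    trough_idx, _ = find_peaks(-icp.values, distance=dist)
    return icp.t[trough_idx]
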