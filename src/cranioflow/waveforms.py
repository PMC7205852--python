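"""Synthetic arterial inflow waveforms, PC-MRI-like sampling and complete
forward-model "virtual patients".

No clinical curves are distributed with the package, so every downstream
stage (preprocessing, fitting, morphology) is exercised on synthetic data:
a parametric pulsatile inflow with a systolic peak and dicrotic-notch
second peak, sparse noisy flow sampling emulating phase-contrast MRI
(30-35 points per cardiac cycle), and "measured" ICP / venous / CSF curves
generated by the forward model plus additive noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel as K
from .errors import DomainError
from .parameters import ModelParameters

__all__ = [
    "PeriodicWaveform",
    "synth_arterial_inflow",
    "pcmri_sample",
    "VirtualPatient",
    "make_virtual_patient",
    "count_local_maxima",
]


@dataclass
class PeriodicWaveform:
    """A cardiac-period-periodic flow function as a truncated Fourier series.

    ``q(t) = mean + sum_k ac[k]*cos(2*pi*(k+1)*t/period)
                  + bs[k]*sin(2*pi*(k+1)*t/period)``

    The representation is exactly periodic and its time average over one
    period is exactly ``mean``.
    """

    period: float                     # s
    mean: float                       # ml/s
    ac: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bs: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        if self.period <= 0:
            raise DomainError(f"period must be > 0, got {self.period}")
        self.ac = np.asarray(self.ac, dtype=float)
        self.bs = np.asarray(self.bs, dtype=float)
        if self.ac.shape != self.bs.shape:
            raise DomainError("ac and bs must have the same length")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi / self.period
        k = np.arange(1, len(self.ac) + 1)
        ang = np.multiply.outer(t, k) * w
        out = self.mean + np.cos(ang) @ self.ac + np.sin(ang) @ self.bs
        return out if out.shape else float(out)

    def sample(self, n: int) -> np.ndarray:
        """Values at ``n`` uniform phase points over one period (no endpoint)."""
        return self(np.arange(n) * (self.period / n))

    @classmethod
    def from_samples(cls, values, period: float) -> "PeriodicWaveform":
        """Fit the full trigonometric interpolant of uniform phase samples."""
        values = np.asarray(values, dtype=float)
        n = len(values)
        c = np.fft.rfft(values) / n
        mean = float(c[0].real)
        nh = len(c) - 1
        ac = np.empty(nh)
        bs = np.empty(nh)
        for k in range(1, nh + 1):
            fac = 1.0 if (n % 2 == 0 and k == n // 2) else 2.0
            ac[k - 1] = fac * c[k].real
            bs[k - 1] = -fac * c[k].imag
        return cls(period=float(period), mean=mean, ac=ac, bs=bs)

    @classmethod
    def constant(cls, value: float, period: float = 1.0) -> "PeriodicWaveform":
        return cls(period=period, mean=float(value))


def count_local_maxima(wave: PeriodicWaveform, n: int = 2048,
                       prominence_frac: float = 0.005) -> int:
    """Count local maxima per period, ignoring ripples below
    ``prominence_frac`` of the peak-to-trough amplitude."""
    from scipy.signal import find_peaks

    v = wave.sample(n)
    amp = v.max() - v.min()
    if amp <= 0:
        return 0
    # wrap so periodic-boundary maxima are seen
    vv = np.concatenate([v, v, v])
    peaks, _ = find_peaks(vv, prominence=prominence_frac * amp)
    return int(np.sum((peaks >= n) & (peaks < 2 * n)))


def _periodized_gaussian(phi, center, sigma, sigma_right=None):
    """Gaussian bump on the circle (phases in [0, 1)); optionally skewed
    with a different width on the falling side."""
    sr = sigma if sigma_right is None else sigma_right
    out = np.zeros_like(phi)
    for shift in (-1.0, 0.0, 1.0):
        d = phi - center + shift
        s = np.where(d < 0, sigma, sr)
        out += np.exp(-0.5 * (d / s) ** 2)
    return out


def synth_arterial_inflow(
    heart_rate: float = 60.0,
    mean_flow: float = 646.0,
    pulsatility: float = 1.0,
    notch_depth: float = 0.3,
    notch_phase: float = 0.45,
    *,
    n_harmonics: int = 6,
) -> PeriodicWaveform:
    """Synthesise a pulsatile cerebral arterial inflow waveform.

    Parameters
    ----------
    heart_rate : bpm.
    mean_flow : ml/min (cycle-averaged cerebral blood flow).
    pulsatility : (peak - mean)/mean of the underlying shape; 0 gives a
        constant flow.
    notch_depth : relative height of the dicrotic second peak (0 disables
        it; values >~0.05 produce a distinct second local maximum, first
        peak higher than the second for depth < 1).
    notch_phase : phase (cycle fraction) of the second peak.

    The waveform is a systolic Gaussian bump plus a dicrotic-notch bump,
    truncated to ``n_harmonics`` Fourier harmonics; the time average equals
    ``mean_flow/60`` ml/s exactly and the flow is verified non-negative.
    """
    if heart_rate <= 0:
        raise DomainError(f"heart_rate must be > 0, got {heart_rate}")
    if mean_flow <= 0:
        raise DomainError(f"mean_flow must be > 0, got {mean_flow}")
    if pulsatility < 0:
        raise DomainError(f"pulsatility must be >= 0, got {pulsatility}")
    if not 0 <= notch_depth < 1:
        raise DomainError(f"notch_depth must be in [0, 1), got {notch_depth}")
    if not 0 < notch_phase < 1:
        raise DomainError(f"notch_phase must be in (0, 1), got {notch_phase}")

    period = 60.0 / heart_rate
    qbar = mean_flow / 60.0  # ml/s
    n_dense = 1024
    phi = np.arange(n_dense) / n_dense
    s = _periodized_gaussian(phi, 0.15, 0.09)
    if notch_depth > 0:
        s = s + notch_depth * _periodized_gaussian(phi, notch_phase, 0.10)
    s_hat = (s - s.mean()) / max(s.max() - s.mean(), 1e-300)
    values = qbar * (1.0 + pulsatility * s_hat)

    full = PeriodicWaveform.from_samples(values, period)
    wave = PeriodicWaveform(
        period=period,
        mean=full.mean,
        ac=full.ac[:n_harmonics],
        bs=full.bs[:n_harmonics],
    )
    if wave.sample(2048).min() < 0:
        raise DomainError(
            "parameter combination produces negative flow "
            f"(pulsatility={pulsatility}, notch_depth={notch_depth})"
        )
    return wave


def pcmri_sample(
    waveform: PeriodicWaveform,
    n_points: int = 32,
    noise_sd: float = 0.0,
    seed: int | None = 0,
):
    """Sample a flow waveform the way phase-contrast MRI reports it.

    Uniform phase samples over one period (typically 30-35 points) plus
    independent additive Gaussian noise of standard deviation ``noise_sd``
    (ml/s).  Returns a :class:`cranioflow.dataio.SampledCurve`.
    """
    from .dataio import SampledCurve

    if n_points < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * (waveform.period / n_points)
    v = waveform(t)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n_points)
    return SampledCurve(t=t, values=np.asarray(v), units="ml/s", period=waveform.period)


@dataclass
class VirtualPatient:
    """A fully synthetic subject: ground-truth parameters, the inflow
    forcing, and forward-model 'measured' curves with known noise."""

    params: ModelParameters          # ground truth
    inflow: PeriodicWaveform
    icp: "object"                    # SampledCurve, 125 Hz, mmHg
    venous: "object"                 # SampledCurve, sparse, ml/s
    csf: "object"                    # SampledCurve, sparse, ml/s
    noise: dict
    seed: int
    cycle: "object" = None           # the noiseless steady-state CycleOutputs

    def save(self, directory) -> None:
        from .dataio import write_curve

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.params.to_json(d / "params.json")
        inflow_curve = pcmri_sample(self.inflow, n_points=256, noise_sd=0.0)
        write_curve(inflow_curve, d / "inflow.csv")
        write_curve(self.icp, d / "icp.csv")
        write_curve(self.venous, d / "venous.csv")
        write_curve(self.csf, d / "csf.csv")
        (d / "meta.json").write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "noise": self.noise,
                    "period_s": self.inflow.period,
                    "mean_inflow_ml_s": self.inflow.mean,
                },
                indent=2,
            )
            + "\n"
        )


def make_virtual_patient(
    params: ModelParameters,
    inflow: PeriodicWaveform | dict | None = None,
    noise: dict | None = None,
    seed: int = 0,
    *,
    n_flow_points: int = 32,
    icp_rate_hz: float = 125.0,
    tol: float = 0.01,
    max_cycles: int = 200,
) -> VirtualPatient:
    """Generate a virtual patient by running the forward model to its
    periodic steady state and sampling its outputs like the clinic would:
    ICP at 125 Hz, flows at ``n_flow_points`` PC-MRI phase points.

    ``noise`` keys: ``icp_sd`` (mmHg, default 0.5) and ``flow_frac``
    (fraction of the peak flow, default 0.05).  Pass
    ``noise={"icp_sd": 0, "flow_frac": 0}`` for a noiseless patient, whose
    measured curves equal the model outputs exactly on their grids.
    """
    from .dataio import SampledCurve
    from .simulate import run_to_steady_state

    if inflow is None:
        inflow = synth_arterial_inflow()
    elif isinstance(inflow, dict):
        inflow = synth_arterial_inflow(**inflow)
    noise = dict(noise or {})
    icp_sd = float(noise.setdefault("icp_sd", 0.5))
    flow_frac = float(noise.setdefault("flow_frac", 0.05))

    cycle, _ = run_to_steady_state(params, inflow, tol=tol, max_cycles=max_cycles)
    rng = np.random.default_rng(seed)
    period = cycle.period

    t_icp = np.arange(0.0, period, 1.0 / icp_rate_hz)
    icp_v = _periodic_interp(cycle.phase, cycle.icp, t_icp, period)
    if icp_sd > 0:
        icp_v = icp_v + rng.normal(0.0, icp_sd, size=len(icp_v))
    icp = SampledCurve(t=t_icp, values=icp_v, units="mmHg", period=period)

    t_flow = np.arange(n_flow_points) * (period / n_flow_points)
    curves = {}
    for name, vals in (("venous", cycle.q_v), ("csf", cycle.q_s)):
        v = _periodic_interp(cycle.phase, vals, t_flow, period)
        if flow_frac > 0:
            sd = flow_frac * float(np.max(np.abs(vals)))
            v = v + rng.normal(0.0, sd, size=len(v))
        curves[name] = SampledCurve(t=t_flow, values=v, units="ml/s", period=period)

    return VirtualPatient(
        params=params,
        inflow=inflow,
        icp=icp,
        venous=curves["venous"],
        csf=curves["csf"],
        noise={"icp_sd": icp_sd, "flow_frac": flow_frac},
        seed=seed,
        cycle=cycle,
    )


def _periodic_interp(phase, values, t_new, period):
    """Trigonometric interpolation of a closed cycle (phase[0]..phase[-1]=T)."""
    wave = PeriodicWaveform.from_samples(np.asarray(values)[:-1], period)
    return wave(np.asarray(t_new) % period)
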