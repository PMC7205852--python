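"""ICP pulse morphology: P1/P2 peak detection and shape statistics.

Within one cardiac cycle the ICP pulse normally shows several peaks; the
first two in phase order are labelled P1 and P2.  Their relative
amplitude carries clinical meaning (a dominant P2 suggests reduced
craniospinal compliance), so the detector reports amplitudes measured
above the cycle minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import DomainError

__all__ = ["PeakSet", "detect_icp_peaks", "p2_p1_ratio"]

#: Peaks with prominence below this fraction of the pulse amplitude are noise.
PROMINENCE_FRACTION = 0.02


@dataclass
class PeakSet:
    """Ordered local maxima of one ICP cycle.

    ``phases`` are within one period, strictly increasing; ``amplitudes``
    are heights above the cycle minimum.  The first two peaks are P1 and
    P2.  ``empty_warning`` flags a cycle with no detectable maximum.
    """

    phases: np.ndarray
    amplitudes: np.ndarray
    period: float
    empty_warning: bool = False

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.phases) != len(self.amplitudes):
            raise DomainError("phases and amplitudes must have equal length")
        if len(self.phases) > 1 and np.any(np.diff(self.phases) <= 0):
            raise DomainError("peak phases must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise DomainError("peak amplitudes must be >= 0")

    def __len__(self) -> int:
        return len(self.phases)

    @property
    def p1(self) -> tuple[float, float]:
        if len(self) < 1:
            raise DomainError("no peaks detected")
        return float(self.phases[0]), float(self.amplitudes[0])

    @property
    def p2(self) -> tuple[float, float]:
        if len(self) < 2:
            raise DomainError("fewer than two peaks detected")
        return float(self.phases[1]), float(self.amplitudes[1])

    def to_dict(self) -> dict:
        return {
            "phases_s": self.phases.tolist(),
            "amplitudes_mmHg": self.amplitudes.tolist(),
            "period_s": self.period,
            "empty_warning": self.empty_warning,
        }


def _smooth_periodic(values: np.ndarray, width: int = 3) -> np.ndarray:
    """Periodic moving average (default 3 points)."""
    kernel = np.ones(width) / width
    n = len(values)
    ext = np.concatenate([values[-(width // 2):], values, values[: width // 2]])
    return np.convolve(ext, kernel, mode="valid")[:n]


def detect_icp_peaks(phase, icp, period: float | None = None) -> PeakSet:
    """Detect local ICP maxima within one cardiac cycle.

    Parameters
    ----------
    phase : array of phase times over one period (a closed cycle whose
        last sample repeats the first is handled).
    icp : ICP samples, mmHg.
    period : cycle length; defaults to the phase span.

    The cycle is lightly smoothed (3-point periodic moving average),
    maxima are located with periodic wrap-around, and peaks with
    prominence below 2% of the pulse amplitude are discarded.  A
    monotone or constant cycle yields an empty PeakSet with
    ``empty_warning`` set.
    """
    phase = np.asarray(phase, dtype=float)
    icp = np.asarray(icp, dtype=float)
    if len(phase) < 16:
        raise DomainError(f"need >= 16 samples per cycle, got {len(phase)}")
    if period is None:
        period = float(phase[-1] - phase[0])
    # drop a duplicated endpoint (closed cycle)
    if np.isclose((phase[-1] - phase[0]), period) and np.isclose(
        icp[0], icp[-1], atol=1e-6 * max(1.0, np.ptp(icp))
    ):
        phase, icp = phase[:-1], icp[:-1]

    sm = _smooth_periodic(icp)
    amp = float(sm.max() - sm.min())
    if amp <= 0:
        return PeakSet(np.empty(0), np.empty(0), period, empty_warning=True)

    n = len(sm)
    tripled = np.concatenate([sm, sm, sm])
    idx, _ = find_peaks(tripled, prominence=PROMINENCE_FRACTION * amp)
    idx = idx[(idx >= n) & (idx < 2 * n)] - n
    if len(idx) == 0:
        return PeakSet(np.empty(0), np.empty(0), period, empty_warning=True)
    idx = np.sort(idx)
    base = float(sm.min())
    return PeakSet(
        phases=phase[idx] - phase[0],
        amplitudes=sm[idx] - base,
        period=period,
    )


def p2_p1_ratio(peaks: PeakSet) -> float:
    """Amplitude ratio P2/P1 (heights above the cycle minimum).

    Raises :class:`DomainError` when fewer than two peaks were found.
    """
    if len(peaks) < 2:
        raise DomainError(
            f"P2:P1 ratio needs >= 2 peaks, found {len(peaks)}"
        )
    (_, a1), (_, a2) = peaks.p1, peaks.p2
    return float(a2 / a1)
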