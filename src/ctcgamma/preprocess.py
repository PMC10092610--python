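"""Band definitions, zero-phase band filtering and stimulus-locked epoching.

The canonical band set is delta 1-4 Hz, theta 5-9 Hz, sigma 10-16 Hz,
beta 17-29 Hz and gamma 30-80 Hz.  The two analysis windows are the 500 ms
immediately before each stimulus (baseline) and the 200-700 ms post-stimulus
window (late); both span 500 ms so their spectra share the same 2 Hz grid.

Time-to-sample convention: samples are 0-based, windows are half-open
``[start, end)``, and a time t maps to sample ``round(t * fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy import signal

__all__ = [
    "Band",
    "CANONICAL_BANDS",
    "BASELINE_WINDOW",
    "LATE_WINDOW",
    "bandpass",
    "EpochSet",
    "extract_epochs",
]

#: Baseline window relative to stimulus onset, seconds.
BASELINE_WINDOW: Tuple[float, float] = (-0.5, 0.0)
#: Late post-stimulus window relative to stimulus onset, seconds.
LATE_WINDOW: Tuple[float, float] = (0.2, 0.7)


@dataclass(frozen=True)
class Band:
    """A frequency band [low, high] in Hz with 0 < low < high."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequencies inside the band, endpoints inclusive."""
        return (freqs >= self.low) & (freqs <= self.high)


CANONICAL_BANDS: dict[str, Band] = {
    "delta": Band("delta", 1.0, 4.0),
    "theta": Band("theta", 5.0, 9.0),
    "sigma": Band("sigma", 10.0, 16.0),
    "beta": Band("beta", 17.0, 29.0),
    "gamma": Band("gamma", 30.0, 80.0),
}


def _butter_sos(band: Band, sampling_rate: float, order: int = 4) -> np.ndarray:
    nyquist = sampling_rate / 2.0
    if band.high >= nyquist:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz is at or above the "
            f"Nyquist frequency {nyquist} Hz"
        )
    return signal.butter(
        order, [band.low, band.high], btype="bandpass", fs=sampling_rate, output="sos"
    )


def bandpass(
    x: np.ndarray,
    band: Band,
    sampling_rate: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass filter (Butterworth, forward-backward).

    A 4th-order Butterworth is applied with :func:`scipy.signal.sosfiltfilt`,
    so the effective magnitude response is 8th order and the phase delay is
    zero — the 200-700 ms window boundaries are latency-critical, so no
    group delay can be tolerated.  Output length equals input length.

    Raises
    ------
    ValueError
        If the band reaches the Nyquist frequency or the series is shorter
        than the filter warm-up (padding) length.
    """
    x = np.asarray(x, dtype=float)
    sos = _butter_sos(band, sampling_rate, order=order)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"series of length {x.shape[-1]} is shorter than the filter "
            f"warm-up length {padlen}"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


@dataclass
class EpochSet:
    """Stimulus-locked trials for one channel, window and condition.

    ``trials`` is a (n_trials, n_samples) matrix; row order follows stimulus
    onset order.  ``window`` is (start, end) in seconds relative to onset.
    """

    channel: str
    condition: str
    trials: np.ndarray
    window_label: str
    window: Tuple[float, float]
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[1]

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))


def extract_epochs(
    recording,
    train,
    channel: str,
    window: Tuple[float, float],
    window_label: str | None = None,
) -> EpochSet:
    """Extract one epoch per stimulus onset from a continuous recording.

    The slice for an onset at time ``t`` is the half-open sample range
    ``[round((t + start) * fs), round((t + start) * fs) + n)`` with
    ``n = round((end - start) * fs)``, so both 500 ms windows always yield
    identical sample counts.  Any onset whose window leaves the recording
    rejects the whole call — trials are never silently dropped.
    """
    fs = recording.sampling_rate
    data = recording.channel_data(channel)
    start, end = window
    if not end > start:
        raise ValueError(f"window end must exceed start, got {window}")
    n = int(round((end - start) * fs))
    rows = np.empty((len(train.onsets), n), dtype=float)
    for i, onset in enumerate(train.onsets):
        s0 = int(round((onset + start) * fs))
        if s0 < 0 or s0 + n > data.shape[0]:
            raise ValueError(
                f"onset {onset} s with window {window} falls outside the "
                f"recording ({data.shape[0]} samples at {fs} Hz); "
                "rejecting the whole run"
            )
        rows[i] = data[s0 : s0 + n]
    if window_label is None:
        window_label = "baseline" if end <= 0 else "late"
    return EpochSet(
        channel=channel,
        condition=recording.condition_label,
        trials=rows,
        window_label=window_label,
        window=(start, end),
        sampling_rate=fs,
    )
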