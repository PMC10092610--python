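"""Hamming periodograms, band power, normalised power and the evoked/induced
power decomposition.

Spectral settings: each 500 ms epoch is analysed as a single Hamming-tapered
segment (no overlap, no averaging), giving exactly 2 Hz frequency resolution
at any sampling rate.  Spectra are one-sided with power doubled at every bin
except DC and Nyquist, scaled so that the sum over bins equals the energy
(sum of squares) of the windowed signal — Parseval's identity holds exactly.

Band power sums bins with ``low <= f <= high`` (both edges inclusive).  On
the 2 Hz grid the canonical odd-Hz band boundaries (1-4, 5-9, 10-16, 17-29,
30-80 Hz) never collide, so no bin is shared between adjacent bands except
the even band edges themselves, which belong to exactly one band each.

Per-trial quantities for trial i (baseline power P_b[i], late-window power
P_e[i]) combine into the average normalised power

    P_v = mean_i( P_e[i] / P_b[i] ),

the mean of per-trial ratios, *not* the ratio of means.  Induced power is

    induced[i] = total[i] - evoked - baseline[i]          ("methods")
    induced[i] = total[i] - baseline[i]                   ("figure3")

where ``evoked`` is the band power of the spectrum of the time-domain trial
average of the same late epochs.  The two definitions coexist in the source
material; "methods" is the default and the variant is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import windows

from .preprocess import Band, EpochSet

__all__ = [
    "BandSpectrum",
    "epoch_spectrum",
    "band_power",
    "build_power_table",
    "normalized_power",
    "baseline_ratio",
    "induced_band_power",
]

EPOCH_DURATION_S = 0.5  # fixed 500 ms epochs => 2 Hz bins


@dataclass
class BandSpectrum:
    """One-sided power spectrum on a 2 Hz grid (units^2 per bin)."""

    frequencies: np.ndarray
    power: np.ndarray
    window_label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have the same shape")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be nonnegative")


def epoch_spectrum(
    epoch: np.ndarray,
    sampling_rate: float,
    demean: bool = True,
    window_label: str | None = None,
) -> BandSpectrum:
    """Single-segment Hamming periodogram of one 500 ms epoch.

    ``demean`` subtracts the epoch mean before tapering (default on) to stop
    DC leakage through the Hamming window's sidelobes.

    Raises
    ------
    ValueError
        If the epoch does not span 500 ms at the given sampling rate.
    """
    x = np.asarray(epoch, dtype=float)
    n = x.shape[0]
    if n != int(round(EPOCH_DURATION_S * sampling_rate)):
        raise ValueError(
            f"epoch must span {EPOCH_DURATION_S * 1e3:.0f} ms "
            f"({int(round(EPOCH_DURATION_S * sampling_rate))} samples at "
            f"{sampling_rate} Hz), got {n} samples"
        )
    if demean:
        x = x - x.mean()
    w = windows.hamming(n, sym=False)
    xw = x * w
    spec = np.fft.rfft(xw)
    power = np.abs(spec) ** 2 / n
    scale = np.full(power.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power *= scale
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return BandSpectrum(frequencies=freqs, power=power, window_label=window_label)


def band_power(spectrum: BandSpectrum, band: Band) -> float:
    """Sum of spectral power over bins with low <= f <= high (inclusive)."""
    mask = band.contains(spectrum.frequencies)
    if not mask.any():
        raise ValueError(
            f"no spectral bins inside band {band.name!r} [{band.low}, {band.high}] Hz"
        )
    return float(spectrum.power[mask].sum())


def _trial_band_powers(epochs: EpochSet, band: Band, demean: bool = True) -> np.ndarray:
    return np.array(
        [
            band_power(epoch_spectrum(tr, epochs.sampling_rate, demean=demean), band)
            for tr in epochs.trials
        ]
    )


def build_power_table(
    baseline: EpochSet,
    late: EpochSet,
    bands: Sequence[Band],
    demean: bool = True,
) -> pd.DataFrame:
    """Per-trial baseline (P_b) and late-window (P_e) band powers.

    Returns a long-format table with one row per (trial, band); columns are
    ``trial`` (1-based), ``band``, ``channel``, ``condition``, ``P_b``,
    ``P_e``.
    """
    if baseline.n_trials != late.n_trials:
        raise ValueError("baseline and late epoch sets must have equal trial counts")
    rows = []
    for band in bands:
        pb = _trial_band_powers(baseline, band, demean=demean)
        pe = _trial_band_powers(late, band, demean=demean)
        for i in range(len(pb)):
            rows.append(
                dict(
                    trial=i + 1,
                    band=band.name,
                    channel=late.channel,
                    condition=late.condition,
                    P_b=pb[i],
                    P_e=pe[i],
                )
            )
    return pd.DataFrame(rows)


def _select_band(table: pd.DataFrame, band: str | Band | None) -> pd.DataFrame:
    if band is None:
        return table
    name = band.name if isinstance(band, Band) else band
    sub = table[table["band"] == name]
    if sub.empty:
        raise ValueError(f"power table contains no rows for band {name!r}")
    return sub


def normalized_power(table: pd.DataFrame, band: str | Band | None = None) -> float:
    """Average normalised power: the mean over trials of P_e[i]/P_b[i]."""
    sub = _select_band(table, band)
    pb = sub["P_b"].to_numpy(dtype=float)
    pe = sub["P_e"].to_numpy(dtype=float)
    if np.any(pb <= 0):
        raise ValueError("normalised power undefined: some baseline powers are <= 0")
    return float(np.mean(pe / pb))


def baseline_ratio(
    ketamine_table: pd.DataFrame,
    saline_table: pd.DataFrame,
    band: str | Band,
) -> float:
    """Mean over paired trials of ketamine/saline baseline band power."""
    kt = _select_band(ketamine_table, band).sort_values("trial")
    st = _select_band(saline_table, band).sort_values("trial")
    if len(kt) != len(st) or not np.array_equal(
        kt["trial"].to_numpy(), st["trial"].to_numpy()
    ):
        raise ValueError("tables are not trial-paired")
    pb_s = st["P_b"].to_numpy(dtype=float)
    pb_k = kt["P_b"].to_numpy(dtype=float)
    if np.any(pb_s <= 0):
        raise ValueError("baseline ratio undefined: some saline baseline powers are <= 0")
    return float(np.mean(pb_k / pb_s))


def induced_band_power(
    late: EpochSet,
    baseline: EpochSet,
    band: Band,
    definition: Literal["methods", "figure3"] = "methods",
    demean: bool = True,
) -> pd.DataFrame:
    """Per-trial induced band power and %-change relative to baseline.

    ``definition="methods"`` subtracts both the evoked band power (spectrum
    of the time-domain average of the same late epochs) and the per-trial
    baseline band power from the per-trial total; ``"figure3"`` omits the
    evoked term.  The %-change is ``100 * induced / P_b`` (NaN where the
    baseline power is zero).

    Returns a DataFrame with columns ``trial``, ``total``, ``evoked``,
    ``baseline``, ``induced``, ``pct_change``.
    """
    if late.n_trials != baseline.n_trials:
        raise ValueError("late and baseline epoch sets must be trial-paired")
    if late.n_trials < 2:
        raise ValueError("need at least 2 trials to separate an evoked component")
    if definition not in ("methods", "figure3"):
        raise ValueError(f"unknown induced-power definition {definition!r}")
    fs = late.sampling_rate
    total = _trial_band_powers(late, band, demean=demean)
    base = _trial_band_powers(baseline, band, demean=demean)
    evoked = band_power(
        epoch_spectrum(late.trials.mean(axis=0), fs, demean=demean), band
    )
    induced = total - base - (evoked if definition == "methods" else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(base > 0, 100.0 * induced / base, np.nan)
    return pd.DataFrame(
        dict(
            trial=np.arange(1, len(total) + 1),
            total=total,
            evoked=evoked,
            baseline=base,
            induced=induced,
            pct_change=pct,
        )
    )
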