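"""Sample entropy and band-limited multiscale entropy (MSE).

Sample entropy of a series x[0..N-1] with embedding length m and tolerance r
is ``-ln(A/B)`` where B counts unordered pairs of distinct m-length templates
whose Chebyshev (max-norm) distance is <= r and A counts the same for
(m+1)-length templates.  Following the standard formulation only the first
N-m templates enter both counts, so every m-template has an (m+1)-point
extension; self-matches are excluded.  When A or B is zero the entropy is
undefined and flagged as such rather than silently returned as NaN-with-no-
context.

MSE first coarse-grains the series at scale factor tau by averaging
non-overlapping blocks of tau points (y_j = mean(x[(j-1)*tau .. j*tau-1]),
length floor(N/tau); tau = 1 is the identity), then computes sample entropy
at each scale.  For band-limited MSE the raw epoch is band-pass filtered
first and the tolerance r is fixed once as ``r_frac`` times the SD of the
filtered (scale-1) series, held constant across scales; recomputing r per
scale is available behind a flag.

Defaults m=2, r = 0.2 x SD, scales 1-20 follow the conventions of the
literature this analysis style descends from; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .preprocess import Band, EpochSet, bandpass

__all__ = [
    "SampleEntropyResult",
    "sample_entropy",
    "coarse_grain",
    "MSECurve",
    "mse_curve",
    "mse_trial_curves",
    "mse_compare",
]


class SampleEntropyResult(NamedTuple):
    """Sample entropy with its raw template-match counts."""

    value: float  # NaN when undefined
    a_count: int  # (m+1)-template matches
    b_count: int  # m-template matches
    defined: bool


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping blocks of ``tau`` points.

    Output length is floor(N / tau); trailing samples that do not fill a
    block are discarded.  ``tau = 1`` returns the input unchanged.
    """
    if int(tau) != tau or tau < 1:
        raise ValueError(f"scale factor tau must be a positive integer, got {tau}")
    tau = int(tau)
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.shape[0] < tau:
        raise ValueError(f"series of length {x.shape[0]} is shorter than tau={tau}")
    if tau == 1:
        return x.copy()
    n_blocks = x.shape[0] // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def sample_entropy(series: np.ndarray, m: int = 2, r: float = 0.2) -> SampleEntropyResult:
    """Sample entropy -ln(A/B) with exact integer template-match counts.

    ``r`` is an *absolute* tolerance in signal units (callers scale it from
    the series SD).  The implementation thresholds the pairwise distance
    matrix once and extends matches by logical AND of diagonally shifted
    slices, which reproduces brute-force template counting exactly in
    O(N^2) time and memory.
    """
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if int(m) != m or m < 1:
        raise ValueError("embedding length m must be a positive integer")
    m = int(m)
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n <= m + 1:
        raise ValueError(f"series of length {n} is too short for m={m}")

    within = np.abs(x[:, None] - x[None, :]) <= r
    L = n - m  # number of templates considered for both m and m+1
    match = within[:L, :L].copy()
    for k in range(1, m):
        match &= within[k : k + L, k : k + L]
    b = (int(match.sum()) - L) // 2  # remove self-matches, count pairs once
    match &= within[m : m + L, m : m + L]
    a = (int(match.sum()) - L) // 2
    if a > 0 and b > 0:
        return SampleEntropyResult(float(-np.log(a / b)), a, b, True)
    return SampleEntropyResult(float("nan"), a, b, False)


@dataclass
class MSECurve:
    """Sample entropy versus scale factor for one series."""

    scales: np.ndarray
    values: np.ndarray  # NaN at undefined scales
    defined: np.ndarray  # boolean mask
    m: int
    r: float
    r_frac: float
    band: str | None = None
    metadata: dict = field(default_factory=dict)

    def mean(self) -> float:
        """Mean entropy across defined scales (NaN if none defined)."""
        if not self.defined.any():
            return float("nan")
        return float(np.nanmean(self.values[self.defined]))


def mse_curve(
    epoch: np.ndarray,
    band: Band | None,
    sampling_rate: float,
    scales: Sequence[int] = tuple(range(1, 21)),
    m: int = 2,
    r_frac: float = 0.2,
    prefilter: bool = True,
    r_per_scale: bool = False,
) -> MSECurve:
    """Band-limited multiscale entropy of one raw epoch.

    The epoch is band-pass filtered (unless ``prefilter`` is False, for
    callers that filtered the continuous signal already or pass ``band=None``
    for broadband MSE), r is set from the filtered series, and sample
    entropy is evaluated on each coarse-grained series.  Scales whose
    coarse-grained series is too short for m, or where no template matches
    survive, are flagged undefined rather than imputed.  A zero-variance
    epoch yields an all-undefined curve.
    """
    x = np.asarray(epoch, dtype=float)
    if prefilter and band is not None:
        x = bandpass(x, band, sampling_rate)
    scales_arr = np.asarray(list(scales), dtype=int)
    sd = float(x.std())
    values = np.full(scales_arr.shape, np.nan)
    defined = np.zeros(scales_arr.shape, dtype=bool)
    band_name = band.name if band is not None else None
    if sd == 0.0:
        return MSECurve(scales_arr, values, defined, m, float("nan"), r_frac, band_name,
                        metadata={"flag": "zero-variance epoch"})
    r = r_frac * sd
    for i, tau in enumerate(scales_arr):
        y = coarse_grain(x, int(tau))
        if y.shape[0] <= m + 1:
            continue
        r_tau = r_frac * float(y.std()) if r_per_scale else r
        if r_tau <= 0:
            continue
        res = sample_entropy(y, m=m, r=r_tau)
        if res.defined:
            values[i] = res.value
            defined[i] = True
    return MSECurve(scales_arr, values, defined, m, r, r_frac, band_name)


def mse_trial_curves(
    epochs: EpochSet,
    band: Band | None,
    scales: Sequence[int] = tuple(range(1, 21)),
    m: int = 2,
    r_frac: float = 0.2,
    prefilter: bool = True,
) -> np.ndarray:
    """Per-trial MSE values as a (n_trials, n_scales) matrix (NaN = undefined).

    MSE is computed per trial and averaged downstream across trials, never on
    concatenated trials.
    """
    out = np.full((epochs.n_trials, len(list(scales))), np.nan)
    for i, tr in enumerate(epochs.trials):
        curve = mse_curve(
            tr, band, epochs.sampling_rate, scales=scales, m=m, r_frac=r_frac,
            prefilter=prefilter,
        )
        out[i] = curve.values
    return out


def mse_compare(curves_a: np.ndarray, curves_b: np.ndarray, scales: Sequence[int] | None = None):
    """Paired comparison of two trial-paired MSE matrices (b minus a).

    Returns a dict with per-scale paired-t results, the paired t on each
    trial's mean across scales (the headline statistic, df = n_trials - 1),
    and the number of trials excluded per scale because the entropy was
    undefined in either condition.
    """
    from . import stats as _stats

    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("MSE matrices must be trial-paired with equal shapes")
    n_scales = a.shape[1]
    scales = list(scales) if scales is not None else list(range(1, n_scales + 1))
    per_scale = []
    excluded = []
    for s in range(n_scales):
        ok = np.isfinite(a[:, s]) & np.isfinite(b[:, s])
        excluded.append(int((~ok).sum()))
        if ok.sum() >= 2:
            per_scale.append(_stats.paired_t(b[ok, s], a[ok, s]))
        else:
            per_scale.append(None)
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    ok = np.isfinite(mean_a) & np.isfinite(mean_b)
    mean_test = _stats.paired_t(mean_b[ok], mean_a[ok])
    return {
        "scales": scales,
        "per_scale": per_scale,
        "mean": mean_test,
        "excluded_per_scale": excluded,
        "mean_a": float(np.mean(mean_a[ok])) if ok.any() else float("nan"),
        "mean_b": float(np.mean(mean_b[ok])) if ok.any() else float("nan"),
    }
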