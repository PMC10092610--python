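"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's algorithms: template matching is done
pair-by-pair over explicit sliding windows, and coherence is estimated with a
hand-rolled FFT-based Welch cross-spectrum.
"""

import numpy as np


def naive_sampen_counts(x, m, r):
    """Brute-force template-match counts (B for length m, A for m+1).

    Considers the first N-m templates for both lengths, Chebyshev distance,
    self-matches excluded, unordered pairs counted once.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    L = n - m
    win_m = np.lib.stride_tricks.sliding_window_view(x, m)[:L]
    win_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:L]
    a = b = 0
    for i in range(L - 1):
        d_m = np.abs(win_m[i + 1 :] - win_m[i]).max(axis=1)
        d_m1 = np.abs(win_m1[i + 1 :] - win_m1[i]).max(axis=1)
        b += int((d_m <= r).sum())
        a += int((d_m1 <= r).sum())
    return a, b


def welch_coherence_oracle(x, y, nperseg, noverlap):
    """Hand-rolled Hamming-Welch magnitude-squared coherence (per-segment
    mean removal, matching the constant detrend of the tested estimator)."""
    step = nperseg - noverlap
    win = np.hamming(nperseg)  # symmetric window; bias oracle is insensitive
    sxx = syy = sxy = 0.0
    n_seg = 0
    for start in range(0, len(x) - nperseg + 1, step):
        xs = x[start : start + nperseg]
        ys = y[start : start + nperseg]
        fx = np.fft.rfft((xs - xs.mean()) * win)
        fy = np.fft.rfft((ys - ys.mean()) * win)
        sxx = sxx + np.abs(fx) ** 2
        syy = syy + np.abs(fy) ** 2
        sxy = sxy + fx * np.conj(fy)
        n_seg += 1
    assert n_seg >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    freqs = np.fft.rfftfreq(nperseg)
    return freqs, np.nan_to_num(coh)
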