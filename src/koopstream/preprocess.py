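"""Preprocessing of bandpassed LFP into pipeline input.

The order is fixed: 3-s sliding standardization, 10-ms boxcar smoothing,
then decimation to 200 Hz by keeping every n-th sample.  Windows are
centered and truncated at the record boundary (standalone inputs carry no
pre/post-stimulus padding, and fabricating samples would bias the edges).
A 10-ms window at 1000 Hz covers an even number of samples, so the centered
window is widened to the nearest odd count (11 samples, +-5 ms).
"""

from __future__ import annotations

import numpy as np

from .datatypes import KoopstreamError, Recording

__all__ = ["sliding_standardize", "smooth_boxcar", "decimate_to",
           "preprocess"]


def _window_sums(x: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving sums with boundary truncation.

    Returns (sums, counts) where ``sums[k]`` is the sum of ``x`` over indices
    ``[k-half, k+half]`` clipped to the array, per column.
    """
    n = x.shape[0]
    cs = np.concatenate([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    k = np.arange(n)
    lo = np.clip(k - half, 0, n)
    hi = np.clip(k + half + 1, 0, n)
    sums = cs[hi] - cs[lo]
    counts = (hi - lo).astype(float)
    return sums, counts[:, None]


def sliding_standardize(rec: Recording, window_s: float = 3.0) -> Recording:
    """Standard-normalize each channel within a centered sliding window.

    ``out[k, c] = (in[k, c] - mu_k_c) / sigma_k_c`` with the mean and
    (population) SD taken over the ``window_s`` window centered at sample k,
    truncated to available samples near the edges.  A window longer than the
    record degenerates to a single global standardization.
    """
    half = int(round(window_s * rec.rate / 2))
    if 2 * half + 1 <= 1:
        raise KoopstreamError("standardization window must cover > 1 sample")
    x = rec.values
    sums, counts = _window_sums(x, half)
    sq_sums, _ = _window_sums(x ** 2, half)
    mu = sums / counts
    var = sq_sums / counts - mu ** 2
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    bad = sd <= 0
    if bad.any():
        k, c = np.argwhere(bad)[0]
        raise KoopstreamError(
            f"zero within-window SD at channel {c}, t={k / rec.rate:.3f} s")
    return Recording(values=(x - mu) / sd, rate=rec.rate, t0=rec.t0)


def smooth_boxcar(rec: Recording, window_ms: float = 10.0) -> Recording:
    """Centered moving average over ``window_ms``; edges truncated.

    The window is widened to an odd sample count so it stays centered
    (10 ms at 1000 Hz -> 11 samples).
    """
    half = int(round(rec.rate * window_ms / 1000.0 / 2))
    if half < 0:
        raise KoopstreamError("smoothing window must be non-negative")
    if half == 0:
        return Recording(values=rec.values.copy(), rate=rec.rate, t0=rec.t0)
    sums, counts = _window_sums(rec.values, half)
    return Recording(values=sums / counts, rate=rec.rate, t0=rec.t0)


def decimate_to(rec: Recording, target_rate: float = 200.0) -> Recording:
    """Keep every (rate/target_rate)-th sample, starting at index 0.

    No additional filtering is applied; smoothing precedes decimation in the
    fixed pipeline order.
    """
    ratio = rec.rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise KoopstreamError(
            f"rate {rec.rate} not an integer multiple of target {target_rate}")
    stride = int(round(ratio))
    return Recording(values=rec.values[::stride].copy(),
                     rate=target_rate, t0=rec.t0)


def preprocess(rec: Recording, std_window_s: float = 3.0,
               smooth_ms: float = 10.0,
               target_rate: float = 200.0) -> Recording:
    """Full order-fixed preprocessing: standardize, smooth, decimate."""
    out = sliding_standardize(rec, std_window_s)
    out = smooth_boxcar(out, smooth_ms)
    return decimate_to(out, target_rate)
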