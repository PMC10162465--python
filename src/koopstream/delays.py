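"""Exponentially weighted time-delay coordinates.

Each retained sample k >= s is mapped to the row
``[y_k, e^{-a} y_{k-1}, ..., e^{-s a} y_{k-s}]`` (lag blocks newest to
oldest, each block holding all channels).  The decay a > 0 trades temporal
history against regularity of the embedded coordinates; a = 0 reproduces
classical delay coordinates.  The first s samples lack sufficient history
and are dropped.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DelayMatrix, KoopstreamError, Recording

__all__ = ["build_delay_coordinates"]


def build_delay_coordinates(rec: Recording, s: int = 799,
                            alpha: float = 0.001) -> DelayMatrix:
    """Build the (n_samples - s) x (n_channels * (s+1)) delay matrix."""
    n, nc = rec.values.shape
    if s < 0:
        raise KoopstreamError("s must be non-negative")
    if s >= n:
        raise KoopstreamError(
            f"insufficient history: s={s} but only {n} samples")
    n_rows = n - s
    weights = np.exp(-alpha * np.arange(s + 1))
    out = np.empty((n_rows, nc * (s + 1)))
    for lag in range(s + 1):
        block = rec.values[s - lag:n - lag]
        out[:, lag * nc:(lag + 1) * nc] = weights[lag] * block
    return DelayMatrix(values=out, s=s, alpha=alpha, dt=1.0 / rec.rate,
                       start_index=s, n_channels=nc, t0=rec.t0)
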