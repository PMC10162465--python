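"""Instantaneous phase and the perceptual-switch predictor.

The instantaneous phase of an eigenfunction relative to a reference
frequency f is ``phi_f(t) = angle(exp(i(2 pi f t - theta(t))))`` with theta
the four-quadrant angle of the eigenfunction.  Trailing circular means over
one triplet (0.6 s) and two triplets (1.2 s) feed the nonlinear predictor
``p = sin^2((short - long)/2)``, which maps antipodal phase differences to
one and congruent differences to zero.  Threshold crossings above the
predictor's mean + 1 SD mark predicted switches; each opens a window
``[t* - 1.2, t* + RT]`` followed by an ``RT + 1.2`` s refractory period.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import KoopstreamError, SwitchPrediction

__all__ = ["instantaneous_phase", "windowed_circular_mean",
           "switch_predictor", "predict_switches", "align_predictions",
           "chi_square_order_test", "build_switch_prediction"]


def instantaneous_phase(eigfun: np.ndarray, f: float,
                        times: np.ndarray,
                        zero_tol: float = 1e-12) -> np.ndarray:
    """Phase of a complex eigenfunction relative to frequency ``f`` (Hz),
    wrapped into (-pi, pi].  Samples with near-zero magnitude are NaN."""
    if f <= 0:
        raise KoopstreamError("reference frequency must be positive")
    eigfun = np.asarray(eigfun, complex)
    times = np.asarray(times, float)
    theta = np.angle(eigfun)
    phi = np.angle(np.exp(1j * (2 * np.pi * f * times - theta)))
    phi = np.where(np.abs(eigfun) < zero_tol, np.nan, phi)
    return phi


def windowed_circular_mean(phase: np.ndarray, times: np.ndarray,
                           window_s: float,
                           resultant_tol: float = 1e-12) -> np.ndarray:
    """Angle of the mean resultant vector over the trailing window
    ``[t_k - window_s, t_k]``.

    Samples whose window extends before the series start, or whose
    resultant length is (numerically) zero, are NaN.
    """
    phase = np.asarray(phase, float)
    times = np.asarray(times, float)
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    win_n = int(round(window_s / dt)) + 1   # inclusive trailing window
    n = len(phase)
    valid = ~np.isnan(phase)
    c = np.where(valid, np.cos(phase), 0.0)
    s = np.where(valid, np.sin(phase), 0.0)
    cs_c = np.concatenate([[0.0], np.cumsum(c)])
    cs_s = np.concatenate([[0.0], np.cumsum(s)])
    k = np.arange(n)
    lo = np.maximum(k - win_n + 1, 0)
    sum_c = cs_c[k + 1] - cs_c[lo]
    sum_s = cs_s[k + 1] - cs_s[lo]
    out = np.arctan2(sum_s, sum_c)
    resultant = np.hypot(sum_c, sum_s)
    degenerate = resultant < resultant_tol
    if degenerate.any():
        warnings.warn("zero resultant length in circular mean; "
                      "samples masked", RuntimeWarning, stacklevel=2)
        out[degenerate] = np.nan
    out[k < win_n - 1] = np.nan   # incomplete window
    return out


def switch_predictor(mean_short: np.ndarray,
                     mean_long: np.ndarray) -> np.ndarray:
    """Nonlinear phase-difference predictor ``sin^2((short - long)/2)``."""
    diff = np.asarray(mean_short, float) - np.asarray(mean_long, float)
    return np.sin(diff / 2.0) ** 2


def predict_switches(predictor: np.ndarray, times: np.ndarray,
                     rt: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold the predictor and emit non-overlapping prediction windows.

    The threshold is mean + 1 SD over unmasked samples; crossings are
    strict.  Each marked time ``t*`` opens the window ``[t* - 1.2,
    t* + rt]``; crossings within ``rt + 1.2`` s of the previous mark fall
    in its refractory period and are ignored.

    Returns (predicted_times, windows, threshold).
    """
    predictor = np.asarray(predictor, float)
    times = np.asarray(times, float)
    valid = ~np.isnan(predictor)
    if not valid.any():
        raise KoopstreamError("empty predictor")
    mu = predictor[valid].mean()
    sd = predictor[valid].std()
    thr = mu + sd
    above = valid & (predictor > thr)
    marked = []
    refractory_until = -np.inf
    for k in np.flatnonzero(above):
        if times[k] < refractory_until:
            continue
        marked.append(times[k])
        refractory_until = times[k] + rt + 1.2
    marked = np.asarray(marked)
    windows = np.column_stack([marked - 1.2, marked + rt]) if len(marked) \
        else np.empty((0, 2))
    return marked, windows, float(thr)


def align_predictions(predicted_times: np.ndarray, windows: np.ndarray,
                      button_times: np.ndarray) -> pd.DataFrame:
    """Match button presses to prediction windows (greedy, earliest first).

    A press matches the window containing it; matched pairs are classified
    ``bp`` when the press precedes the marked time t*, else ``pb``.
    Unmatched windows are false positives; unmatched presses are misses.
    """
    predicted_times = np.asarray(predicted_times, float)
    button_times = np.sort(np.asarray(button_times, float))
    taken = np.zeros(len(predicted_times), dtype=bool)
    rows = []
    for press in button_times:
        inside = np.flatnonzero((windows[:, 0] <= press)
                                & (press <= windows[:, 1]) & ~taken) \
            if len(windows) else np.array([], int)
        if len(inside):
            w = inside[0]
            taken[w] = True
            cls = "bp" if press < predicted_times[w] else "pb"
            rows.append(dict(press_time=press, window=w,
                             predicted_time=predicted_times[w], outcome=cls))
        else:
            rows.append(dict(press_time=press, window=-1,
                             predicted_time=np.nan, outcome="miss"))
    for w in np.flatnonzero(~taken):
        rows.append(dict(press_time=np.nan, window=w,
                         predicted_time=predicted_times[w],
                         outcome="false_positive"))
    table = pd.DataFrame(
        rows, columns=["press_time", "window", "predicted_time", "outcome"])
    return table


def chi_square_order_test(bp: int, pb: int) -> tuple[float, float]:
    """Goodness-of-fit of the bp/pb split against equal expected counts.

    One degree of freedom; returns (statistic, p).
    """
    if bp + pb <= 0:
        raise KoopstreamError("no bp/pb events to test")
    expected = (bp + pb) / 2.0
    stat = (bp - expected) ** 2 / expected + (pb - expected) ** 2 / expected
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def build_switch_prediction(eigfun: np.ndarray, f: float,
                            times: np.ndarray, rt: float,
                            button_times: np.ndarray | None = None
                            ) -> SwitchPrediction:
    """Full predictor chain for one oscillatory eigenfunction."""
    phase = instantaneous_phase(eigfun, f, times)
    short = windowed_circular_mean(phase, times, 0.6)
    long = windowed_circular_mean(phase, times, 1.2)
    pred = switch_predictor(short, long)
    pred[np.isnan(short) | np.isnan(long)] = np.nan
    marked, windows, thr = predict_switches(pred, times, rt)
    out = SwitchPrediction(times=np.asarray(times, float), phase=phase,
                           mean_phase_short=short, mean_phase_long=long,
                           predictor=pred, threshold=thr,
                           predicted_times=marked, windows=windows,
                           frequency=f, reaction_time=rt)
    if button_times is not None:
        table = align_predictions(marked, windows, button_times)
        out.matches = table
        out.bp = int((table["outcome"] == "bp").sum())
        out.pb = int((table["outcome"] == "pb").sum())
    return out
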