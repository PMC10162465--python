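"""Core containers passed between pipeline stages.

Every stage of the feature-extraction pipeline consumes and produces one of
the dataclasses below.  They are deliberately thin: plain NumPy arrays with
the minimal metadata (sampling rate, time origin, hyperparameters) needed to
keep downstream bookkeeping honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ONE_STREAM = "one_stream"
TWO_STREAM = "two_stream"
NEUTRAL = "neutral"

#: integer codes used in per-triplet / per-sample label arrays
LABEL_CODES = {ONE_STREAM: 0, TWO_STREAM: 1, NEUTRAL: -1}


class KoopstreamError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass
class Recording:
    """A multichannel time series with a uniform sampling rate.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_channels)
        Signal matrix; rows are time samples.
    rate : float
        Sampling rate in Hz.
    t0 : float
        Time (seconds) of the first sample.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise KoopstreamError("values must be a (time x channel) matrix")
        if not np.isfinite(self.values).all():
            raise KoopstreamError("recording contains non-finite samples")
        if not self.rate > 0:
            raise KoopstreamError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class PerceptTimeline:
    """Behavioral ground truth / report for one stimulus block.

    ``switch_times`` are the perceptual switch instants; the subject's button
    press trails each switch by ``reaction_time``.  ``percept_sequence`` has
    one label per epoch (one more entry than ``switch_times``) and alternates
    between the one-stream and two-stream percepts.
    """

    switch_times: np.ndarray
    percept_sequence: list
    reaction_time: float
    block_duration: float
    triplet_duration: float = 0.6

    def __post_init__(self) -> None:
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        self.percept_sequence = list(self.percept_sequence)
        if len(self.percept_sequence) != len(self.switch_times) + 1:
            raise KoopstreamError(
                "need one percept label per epoch (len(switches)+1)")
        if np.any(np.diff(self.switch_times) <= 0):
            raise KoopstreamError("switch times must be strictly increasing")
        if len(self.switch_times) and (
                self.switch_times[0] <= 0
                or self.switch_times[-1] >= self.block_duration):
            raise KoopstreamError("switch times must lie inside the block")
        for a, b in zip(self.percept_sequence, self.percept_sequence[1:]):
            if a == b or {a, b} - {ONE_STREAM, TWO_STREAM}:
                raise KoopstreamError("percepts must alternate between "
                                      f"{ONE_STREAM!r} and {TWO_STREAM!r}")

    @property
    def button_times(self) -> np.ndarray:
        """Press times: switches delayed by the subject's reaction time."""
        bt = self.switch_times + self.reaction_time
        return bt[bt < self.block_duration]

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """Latent percept code (0 = one-stream, 1 = two-stream) at ``times``."""
        times = np.asarray(times, dtype=float)
        epoch = np.searchsorted(self.switch_times, times, side="right")
        codes = np.array([LABEL_CODES[p] for p in self.percept_sequence])
        return codes[epoch]

    def label_at(self, times: np.ndarray) -> np.ndarray:
        codes = self.state_at(times)
        return np.where(codes == 1, TWO_STREAM, ONE_STREAM)


@dataclass
class DelayMatrix:
    """Exponentially weighted delay coordinates.

    Row ``i`` corresponds to original sample index ``start_index + i`` and
    concatenates the current observation with ``s`` weighted past ones,
    newest to oldest: ``[y_k, e^{-a} y_{k-1}, ..., e^{-s a} y_{k-s}]``.
    """

    values: np.ndarray
    s: int
    alpha: float
    dt: float
    start_index: int
    n_channels: int
    t0: float = 0.0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + (self.start_index + np.arange(self.n_rows)) * self.dt

    @property
    def span(self) -> float:
        """Temporal history contained in a single row, seconds."""
        return (self.s + 1) * self.dt


@dataclass
class DiffusionBasis:
    """Leading eigenpairs of the kernel Markov matrix over delay coordinates.

    ``eigvecs[:, j]`` is the time series psi_j evaluated at the embedded
    sample times; ``eigvals`` are sorted in descending order with the Perron
    eigenvalue 1 (constant eigenvector) first.
    """

    eigvals: np.ndarray
    eigvecs: np.ndarray
    epsilon: float
    kmin: int
    knn: int
    dt: float = 0.0
    start_index: int = 0
    t0: float = 0.0

    @property
    def n_eigs(self) -> int:
        return len(self.eigvals)

    @property
    def times(self) -> np.ndarray:
        n = self.eigvecs.shape[0]
        return self.t0 + (self.start_index + np.arange(n)) * self.dt


@dataclass
class KoopmanDecomposition:
    """Koopman eigenvalues, eigenfunction time series, and spatial modes.

    ``discrete_eigvals`` are eigenvalues of the finite eDMD matrix;
    ``exp_eigvals`` their continuous-time counterparts ln(lambda)/dt, whose
    real part is a decay rate (1/s) and whose imaginary part / 2pi is a
    frequency in Hz.  ``eigfuns[:, j]`` samples eigenfunction phi_j at the
    embedded times; ``modes[j, c]`` is the coefficient of phi_j in the
    reconstruction of channel c.
    """

    discrete_eigvals: np.ndarray
    exp_eigvals: np.ndarray
    eigfuns: np.ndarray
    dt: float
    dictionary_size: int
    times: np.ndarray
    modes: np.ndarray | None = None

    @property
    def n_eigs(self) -> int:
        return len(self.discrete_eigvals)

    @property
    def frequencies(self) -> np.ndarray:
        """Oscillation frequency of each eigenfunction, Hz."""
        return self.exp_eigvals.imag / (2 * np.pi)

    @property
    def decay_rates(self) -> np.ndarray:
        return self.exp_eigvals.real


@dataclass
class BranchAssignment:
    """Organization of the Koopman spectrum into stimulus- and
    perception-encoding branches.

    J1 holds, per triplet-rate harmonic, the conjugate pair of eigenvalues
    decaying most slowly (plus the near-zero constant eigenvalue); J2 holds
    the faster-decaying pair at the same harmonic plus the slow purely real
    eigenfunction phi_star.
    """

    J1: list
    J2: list
    harmonic_of: dict
    f_triplet: float
    phi_star_index: int | None = None
    omega_star: float | None = None
    multiple_real_candidates: bool = False

    def __post_init__(self) -> None:
        if set(self.J1) & set(self.J2):
            raise KoopstreamError("J1 and J2 must be disjoint")


@dataclass
class TripletLabels:
    """Per-triplet percept labels with the RT-derived neutral zone.

    ``labels`` uses integer codes: 0 one-stream, 1 two-stream, -1 neutral.
    """

    labels: np.ndarray
    triplet_duration: float
    n_neutral: int
    reaction_time: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_triplets(self) -> int:
        return len(self.labels)

    def sample_labels(self, times: np.ndarray) -> np.ndarray:
        """Map sample times to the label of the triplet containing them."""
        idx = np.floor(np.asarray(times) / self.triplet_duration).astype(int)
        idx = np.clip(idx, 0, self.n_triplets - 1)
        return self.labels[idx]


@dataclass
class SwitchPrediction:
    """Output of the instantaneous-phase switch predictor."""

    times: np.ndarray
    phase: np.ndarray
    mean_phase_short: np.ndarray
    mean_phase_long: np.ndarray
    predictor: np.ndarray
    threshold: float
    predicted_times: np.ndarray
    windows: np.ndarray          # (n_windows, 2) [start, end]
    frequency: float
    reaction_time: float
    matches: "object | None" = None   # pandas DataFrame, filled by alignment
    bp: int | None = None
    pb: int | None = None
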