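"""Surrogate bistable-streaming data generator.

Emulates the statistical structure of local field potentials recorded during
an auditory triplet-streaming task: oscillatory components at integer
multiples of the triplet presentation rate (1.67 Hz for 600-ms triplets), a
slow two-state latent percept process that shifts the *phase* of those
components, a multiplicative slow drift, additive Gaussian noise, and button
presses trailing each perceptual switch by the subject's reaction time.

The percept is encoded in phase rather than amplitude because the
discriminating signal the downstream pipeline is built to find is a phase
shift of triplet-locked oscillators between the two percepts.  Dwell times
follow a truncated log-normal, the standard phenomenological model for
irregular percept durations in bistable perception; the truncation floor
(reaction time plus two triplets) keeps every percept long enough to be
reportable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (ONE_STREAM, TWO_STREAM, KoopstreamError,
                        PerceptTimeline, Recording)

__all__ = ["SynthParams", "simulate_percept_timeline", "simulate_lfp",
           "simulate_block"]


@dataclass
class SynthParams:
    """Parameters of the synthetic bistable-streaming block.

    Attributes
    ----------
    n_channels : int
        Number of simulated contacts.
    rate : float
        Output sampling rate, Hz.
    f_triplet : float
        Triplet presentation rate, Hz (1/0.6 s by default).
    n_harmonics : int
        Number of active harmonics m*f_triplet, m = 1..n_harmonics.
    harmonic_amplitudes : ndarray (n_channels, n_harmonics), optional
        Per-channel harmonic amplitudes.  Defaults to 1/m scaling with a
        seeded +-50% channel-specific variation.
    percept_phase_offsets : ndarray (n_harmonics,), optional
        Phase shift (radians) applied to each harmonic while the latent
        percept is in the two-stream state.  Defaults to pi/2 per harmonic;
        a constant offset across harmonics is deliberately *not* a time
        shift of the waveform, so the two percepts trace distinct loops in
        delay-coordinate space.
    slow_drift_amplitude : float
        Relative amplitude of a slow multiplicative envelope.
    slow_drift_period : float
        Period of the drift envelope, seconds.
    dwell_mean, dwell_sd : float
        Mean and SD (seconds) of the log-normal percept dwell times.
    noise_sd : float
        SD of additive white Gaussian noise.
    reaction_time : float
        Button-press latency after each switch, seconds.
    block_duration : float
        Stimulus block length, seconds.
    triplet_duration : float
        Triplet length, seconds.
    seed : int
        Seed for all randomness in the generator.
    """

    n_channels: int = 4
    rate: float = 1000.0
    f_triplet: float = 1.0 / 0.6
    n_harmonics: int = 3
    harmonic_amplitudes: np.ndarray | None = None
    percept_phase_offsets: np.ndarray | None = None
    slow_drift_amplitude: float = 0.05
    slow_drift_period: float = 45.0
    dwell_mean: float = 25.0
    dwell_sd: float = 20.0
    noise_sd: float = 2.0
    reaction_time: float = 0.65
    block_duration: float = 300.0
    triplet_duration: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise KoopstreamError("rate must be positive")
        if self.dwell_mean <= 0 or self.dwell_sd < 0:
            raise KoopstreamError("dwell parameters must be positive")
        if self.noise_sd < 0:
            raise KoopstreamError("noise_sd must be non-negative")
        if self.dwell_mean <= self.reaction_time:
            raise KoopstreamError("dwell_mean must exceed reaction_time")
        if self.n_channels < 1 or self.n_harmonics < 1:
            raise KoopstreamError("need at least one channel and harmonic")
        if self.percept_phase_offsets is None:
            self.percept_phase_offsets = np.full(self.n_harmonics, np.pi / 2)
        self.percept_phase_offsets = np.asarray(
            self.percept_phase_offsets, dtype=float)
        if len(self.percept_phase_offsets) != self.n_harmonics:
            raise KoopstreamError("need one phase offset per harmonic")
        if self.harmonic_amplitudes is None:
            amp_rng = np.random.default_rng(self.seed + 1_000_003)
            base = 1.0 / np.arange(1, self.n_harmonics + 1)
            jitter = amp_rng.uniform(0.5, 1.5,
                                     (self.n_channels, self.n_harmonics))
            self.harmonic_amplitudes = base[None, :] * jitter
        self.harmonic_amplitudes = np.atleast_2d(
            np.asarray(self.harmonic_amplitudes, dtype=float))
        if self.harmonic_amplitudes.shape != (self.n_channels,
                                              self.n_harmonics):
            raise KoopstreamError(
                "harmonic_amplitudes must be (n_channels, n_harmonics)")

    @property
    def dwell_floor(self) -> float:
        """Minimum percept duration: RT plus two triplets."""
        return self.reaction_time + 2 * self.triplet_duration


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    var = sd ** 2
    sigma2 = np.log1p(var / mean ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, np.sqrt(sigma2)


def simulate_percept_timeline(params: SynthParams) -> PerceptTimeline:
    """Draw a semi-Markov alternation between the two percepts.

    Dwell times are log-normal with the arithmetic mean/SD given in
    ``params``, truncated below at ``reaction_time + 2 * triplet_duration``
    (resampled until above the floor).  ``dwell_sd == 0`` degenerates to
    fixed dwells of exactly ``dwell_mean``.  The first percept is a seeded
    fair coin.  Deterministic given ``params.seed``.
    """
    if params.block_duration <= 0:
        raise KoopstreamError("block_duration must be positive")
    rng = np.random.default_rng(params.seed)
    first = ONE_STREAM if rng.random() < 0.5 else TWO_STREAM

    floor = params.dwell_floor
    if params.dwell_sd == 0 and params.dwell_mean < floor:
        raise KoopstreamError("fixed dwell below the truncation floor")
    mu, sigma = (0.0, 0.0) if params.dwell_sd == 0 else _lognormal_moments(
        params.dwell_mean, params.dwell_sd)

    switch_times = []
    t = 0.0
    while True:
        if params.dwell_sd == 0:
            dwell = params.dwell_mean
        else:
            dwell = 0.0
            for _ in range(10_000):
                dwell = float(rng.lognormal(mu, sigma))
                if dwell >= floor:
                    break
            else:  # pragma: no cover - unreachable for sane parameters
                raise KoopstreamError("dwell truncation rejection failed")
        t += dwell
        if t >= params.block_duration:
            break
        switch_times.append(t)

    seq = [first]
    for _ in switch_times:
        seq.append(TWO_STREAM if seq[-1] == ONE_STREAM else ONE_STREAM)
    return PerceptTimeline(
        switch_times=np.array(switch_times),
        percept_sequence=seq,
        reaction_time=params.reaction_time,
        block_duration=params.block_duration,
        triplet_duration=params.triplet_duration,
    )


def simulate_lfp(timeline: PerceptTimeline,
                 params: SynthParams) -> Recording:
    """Render the multichannel LFP-like signal for a percept timeline.

    Channel c is
    ``sum_m a_{c,m} cos(2 pi m f t + z(t) dphi_m) * (1 + drift(t)) + noise``
    with ``z(t)`` the latent percept state (0/1).  Deterministic given
    ``params.seed``.
    """
    if abs(timeline.block_duration - params.block_duration) > 1e-9:
        raise KoopstreamError("timeline duration does not match params")
    n = int(round(params.block_duration * params.rate))
    t = np.arange(n) / params.rate
    z = timeline.state_at(t).astype(float)

    drift = 1.0 + params.slow_drift_amplitude * np.sin(
        2 * np.pi * t / params.slow_drift_period)

    sig = np.zeros((n, params.n_channels))
    for m in range(1, params.n_harmonics + 1):
        phase = (2 * np.pi * m * params.f_triplet * t
                 + z * params.percept_phase_offsets[m - 1])
        carrier = np.cos(phase) * drift
        sig += carrier[:, None] * params.harmonic_amplitudes[:, m - 1][None, :]

    if params.noise_sd > 0:
        noise_rng = np.random.default_rng(params.seed + 7_777_777)
        sig = sig + noise_rng.normal(0.0, params.noise_sd,
                                     size=sig.shape)
    return Recording(values=sig, rate=params.rate, t0=0.0)


def simulate_block(params: SynthParams) -> tuple[PerceptTimeline, Recording]:
    """Convenience: timeline plus rendered recording for one block."""
    timeline = simulate_percept_timeline(params)
    return timeline, simulate_lfp(timeline, params)
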