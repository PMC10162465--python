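"""Extended dynamic mode decomposition over the diffusion-map dictionary.

The dictionary is the leading block of diffusion eigenvectors whose power
spectra concentrate at harmonics of the triplet presentation rate; the
cutoff is the start of the first run of ``run_length`` consecutive vectors
whose harmonic concentration falls below ``theta``.  eDMD then fits the
one-step least-squares operator K over the dictionary features and reads
off Koopman eigenvalues (discrete and exponential), eigenfunction time
series, and per-channel spatial modes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import (DiffusionBasis, KoopmanDecomposition,
                        KoopstreamError, Recording)

__all__ = ["select_dictionary", "harmonic_concentration", "run_edmd",
           "exponential_eigenvalues", "compute_modes", "DictionaryDiagnostics"]

log = logging.getLogger(__name__)


@dataclass
class DictionaryDiagnostics:
    """Per-eigenvector spectral diagnostics behind a dictionary cutoff."""

    cutoff: int
    concentration: np.ndarray   # harmonic power fraction per eigenvector
    total_power: np.ndarray     # non-DC power per eigenvector
    peak_freq: np.ndarray       # location of the spectral peak, Hz
    entropy: np.ndarray         # normalized spectral entropy (1 = flat)


def spectral_entropy(x: np.ndarray) -> float:
    """Normalized (0..1) Shannon entropy of the non-DC power spectrum.

    White noise is near 1; any spectrally organized series — harmonics,
    modulation sidebands, slow drifts — is markedly lower.
    """
    x = np.asarray(x, float)
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    p = spec[1:]
    total = p.sum()
    if total <= 0:
        return 0.0
    p = p / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(len(spec) - 1))


def harmonic_concentration(x: np.ndarray, rate: float, f_triplet: float,
                           tol_f: float = 0.2,
                           max_harmonic: int | None = None
                           ) -> tuple[float, float, float]:
    """Fraction of (non-DC) spectral power within ``tol_f`` of any harmonic
    m*f_triplet, plus the total non-DC power and the peak frequency."""
    x = np.asarray(x, float)
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    total = spec[1:].sum()
    if total <= 0:
        return 0.0, 0.0, 0.0
    if max_harmonic is None:
        max_harmonic = max(1, int(np.floor(rate / 2 / f_triplet)))
    m = np.round(freqs / f_triplet).astype(int)
    near = (m >= 1) & (m <= max_harmonic) & (
        np.abs(freqs - m * f_triplet) < tol_f)
    peak = freqs[1:][np.argmax(spec[1:])]
    return float(spec[near].sum() / total), float(total), float(peak)


def select_dictionary(basis: DiffusionBasis, f_triplet: float, rate: float,
                      tol_f: float = 0.2, theta: float = 0.3,
                      run_length: int = 3,
                      max_harmonic: int | None = None,
                      theta_entropy: float = 0.8
                      ) -> tuple[int, DictionaryDiagnostics]:
    """Find the dictionary cutoff index from eigenvector spectra.

    Scans eigenvectors in order (skipping the constant Perron vector at
    index 0, which carries no oscillatory power) and returns the start of
    the first run of ``run_length`` consecutive noise-like vectors.  A
    vector is noise-like when its harmonic concentration falls below
    ``theta`` *and* its spectrum is featureless (normalized spectral
    entropy above ``theta_entropy``): percept- and drift-modulated
    components carry power in sidebands away from the exact harmonics but
    remain spectrally organized, and belong in the dictionary.  If no such
    run exists all vectors are kept and a warning is emitted.
    """
    n = basis.n_eigs
    if n < 2:
        raise KoopstreamError("basis must contain at least 2 vectors")
    conc = np.full(n, np.nan)
    power = np.zeros(n)
    peak = np.zeros(n)
    ent = np.full(n, np.nan)
    for j in range(1, n):
        conc[j], power[j], peak[j] = harmonic_concentration(
            basis.eigvecs[:, j], rate, f_triplet, tol_f, max_harmonic)
        ent[j] = spectral_entropy(basis.eigvecs[:, j])

    cutoff = n
    run = 0
    for j in range(1, n):
        noisy = conc[j] < theta and ent[j] > theta_entropy
        run = run + 1 if noisy else 0
        if run == run_length:
            cutoff = j - run_length + 1
            break
    if cutoff == n:
        warnings.warn("no qualifying dictionary cutoff found; "
                      "keeping all eigenvectors", RuntimeWarning,
                      stacklevel=2)
    elif cutoff <= 1:
        # degenerate all-noise basis: only the constant vector qualifies
        warnings.warn("dictionary reduced to the constant eigenvector",
                      RuntimeWarning, stacklevel=2)
    diag = DictionaryDiagnostics(cutoff=cutoff, concentration=conc,
                                 total_power=power, peak_freq=peak,
                                 entropy=ent)
    return cutoff, diag


def exponential_eigenvalues(discrete: np.ndarray, dt: float) -> np.ndarray:
    """Continuous-time eigenvalues omega = ln(lambda) / dt.

    Re(omega) is the decay rate (1/s); Im(omega)/2pi the frequency in Hz.
    """
    discrete = np.asarray(discrete, complex)
    if np.any(discrete == 0):
        raise KoopstreamError("zero eigenvalue has no exponential form")
    return np.log(discrete) / dt


def run_edmd(dictionary: np.ndarray, dt: float,
             times: np.ndarray | None = None,
             zero_tol: float = 1e-10,
             deflate_constant: bool = True) -> KoopmanDecomposition:
    """Least-squares Koopman approximation over dictionary features.

    ``dictionary`` rows are consecutive embedded time samples of the
    feature vector Psi(x_k).  The finite operator K solves
    ``Psi_{k+1} ~= Psi_k K`` in the least-squares sense (via the
    Gram/cross-moment construction with a pseudoinverse); eigenfunctions
    are ``phi_j(t_k) = Psi(x_k) . xi_j`` with ``K xi_j = lambda_j xi_j``.

    With ``deflate_constant`` (default) near-constant dictionary columns
    are removed and the remaining features centered before the fit, and
    the exact invariant eigenpair (lambda = 1, constant eigenfunction) is
    appended afterwards.  This keeps the Perron eigenvalue from forming a
    near-degenerate cluster with slowly decaying modes, whose eigenvectors
    would otherwise mix.

    Eigenvalues with ``|lambda| < zero_tol`` are dropped with a warning.
    Eigenfunctions are scaled to unit RMS and rotated so their first sample
    has zero phase; ordering is by decreasing Re(ln lambda / dt).
    """
    psi = np.asarray(dictionary, float)
    if psi.ndim != 2 or psi.shape[0] < 3:
        raise KoopstreamError("dictionary must be a (time x features) matrix")
    add_constant = False
    if deflate_constant:
        span = psi.max(axis=0) - psi.min(axis=0)
        scale = np.max(np.abs(psi), axis=0)
        keep = span > 1e-10 * np.maximum(scale, 1e-300)
        add_constant = bool((~keep).any())
        if add_constant:
            # the dropped constant column absorbs the feature means, so
            # centering is lossless here (and only here)
            psi = psi[:, keep] - psi[:, keep].mean(axis=0)
        if psi.shape[1] == 0:
            raise KoopstreamError("dictionary contains no varying features")
    T, N = psi.shape
    x, y = psi[:-1], psi[1:]
    G = x.T @ x / (T - 1)
    A = x.T @ y / (T - 1)
    rank = np.linalg.matrix_rank(G)
    if rank < N:
        log.info("rank-deficient Gram matrix: effective rank %d < %d",
                 rank, N)
    K = np.linalg.pinv(G) @ A

    lam, xi = np.linalg.eig(K)
    keep = np.abs(lam) >= zero_tol
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} near-zero eigenvalues",
                      RuntimeWarning, stacklevel=2)
        lam, xi = lam[keep], xi[:, keep]

    phi = (psi @ xi).astype(complex)
    if add_constant:
        lam = np.concatenate([[1.0 + 0j], lam])
        phi = np.column_stack([np.ones(psi.shape[0], complex), phi])
    omega = exponential_eigenvalues(lam, dt)
    order = np.argsort(-omega.real, kind="stable")
    lam, omega, phi = lam[order], omega[order], phi[:, order]
    rms = np.sqrt(np.mean(np.abs(phi) ** 2, axis=0))
    rms[rms == 0] = 1.0
    phi = phi / rms
    # rotate so the first nonzero sample of each eigenfunction is real
    # positive; conjugate pairs stay conjugate under this convention
    for j in range(phi.shape[1]):
        nz = np.flatnonzero(np.abs(phi[:, j]) > 1e-12)
        if len(nz):
            phi[:, j] = phi[:, j] * np.exp(-1j * np.angle(phi[nz[0], j]))

    if times is None:
        times = np.arange(T) * dt
    return KoopmanDecomposition(discrete_eigvals=lam, exp_eigvals=omega,
                                eigfuns=phi, dt=dt,
                                dictionary_size=N + int(add_constant),
                                times=np.asarray(times, float))


def compute_modes(rec_preprocessed: Recording,
                  decomp: KoopmanDecomposition,
                  ridge: float = 0.0) -> np.ndarray:
    """Spatial modes: least-squares coefficients of each channel on the
    span of the eigenfunctions.

    The preprocessed recording is aligned to the embedded time indices via
    the decomposition's ``times``.  For real signals and a conjugate-
    symmetric eigenfunction set, the recovered modes of conjugate pairs are
    conjugate, making the reconstruction real.  An ill-conditioned
    regression falls back to a small ridge penalty (logged).
    """
    start = int(round((decomp.times[0] - rec_preprocessed.t0)
                      * rec_preprocessed.rate))
    T = decomp.eigfuns.shape[0]
    if start < 0 or start + T > rec_preprocessed.n_samples:
        raise KoopstreamError("eigenfunctions not aligned with recording")
    Y = rec_preprocessed.values[start:start + T]
    F = decomp.eigfuns
    G = F.conj().T @ F
    cond = np.linalg.cond(G)
    if ridge == 0.0 and cond > 1e12:
        ridge = 1e-8 * np.trace(G).real / G.shape[0]
        log.info("ill-conditioned mode regression (cond=%.2e); "
                 "ridge penalty %.2e applied", cond, ridge)
    if ridge > 0:
        G = G + ridge * np.eye(G.shape[0])
    modes = np.linalg.solve(G, F.conj().T @ Y)   # (N, nc)
    decomp.modes = modes
    return modes


def reconstruct(decomp: KoopmanDecomposition,
                indices=None) -> np.ndarray:
    """Real part of the (optionally index-restricted) mode reconstruction."""
    if decomp.modes is None:
        raise KoopstreamError("modes not computed")
    if indices is None:
        indices = np.arange(decomp.n_eigs)
    indices = np.asarray(list(indices), dtype=int)
    if len(indices) == 0:
        nc = decomp.modes.shape[1]
        return np.zeros((decomp.eigfuns.shape[0], nc))
    return (decomp.eigfuns[:, indices] @ decomp.modes[indices]).real
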