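"""Organization of the Koopman spectrum into J1/J2 branches and phi_star.

Eigenvalues whose frequencies sit at integer multiples of the triplet
presentation rate are grouped per harmonic: the conjugate pair with real
part closest to zero (slowest decay) forms the stimulus-encoding branch J1;
the next pair, when present, forms the perception-encoding branch J2.  The
near-zero eigenvalue with constant eigenfunction also belongs to J1.  The
slow percept-tracking feature phi_star is the purely real, slowest-decaying
non-constant eigenfunction; it belongs to J2.

All steps up to :func:`orient_phi_star` use no behavioral data.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (LABEL_CODES, ONE_STREAM, TWO_STREAM,
                        BranchAssignment, KoopmanDecomposition,
                        KoopstreamError)

__all__ = ["match_harmonics", "assign_branches", "find_phi_star",
           "orient_phi_star", "organize_spectrum", "phi_star_series"]

log = logging.getLogger(__name__)

#: |omega| below this (1/s) tags a candidate zero eigenvalue; the
#: eigenfunction's constancy decides (the slow percept feature can have
#: arbitrarily small decay, but its eigenfunction is far from constant)
ZERO_OMEGA_TOL = 1e-3


def _is_constant_eigfun(decomp: KoopmanDecomposition, j: int,
                        tol: float = 1e-6) -> bool:
    phi = decomp.eigfuns[:, j]
    rms = np.sqrt(np.mean(np.abs(phi) ** 2))
    spread = np.sqrt(np.mean(np.abs(phi - phi.mean()) ** 2))
    return rms == 0 or float(spread) < tol * rms


def match_harmonics(decomp: KoopmanDecomposition, f_triplet: float,
                    tol_f: float = 0.2) -> dict:
    """Tag each eigenvalue with the harmonic m >= 1 of ``f_triplet``
    nearest to its frequency, when within ``tol_f`` Hz; others untagged."""
    if decomp.n_eigs == 0:
        raise KoopstreamError("empty decomposition")
    harmonic_of: dict[int, int] = {}
    for j, f in enumerate(np.abs(decomp.frequencies)):
        m = int(round(f / f_triplet))
        if m >= 1 and abs(f - m * f_triplet) < tol_f:
            harmonic_of[j] = m
    return harmonic_of


def assign_branches(decomp: KoopmanDecomposition, harmonic_of: dict,
                    f_triplet: float) -> BranchAssignment:
    """Per harmonic, place the slowest-decaying conjugate pair in J1 and
    the next pair in J2; extra pairs are logged and dropped.

    The near-zero real eigenvalue (constant eigenfunction) joins J1.  The
    slow real eigenfunction phi_star is added to J2 by
    :func:`find_phi_star`.
    """
    omega = decomp.exp_eigvals
    J1: list[int] = []
    J2: list[int] = []

    # constant eigenfunction at the (near-)zero eigenvalue
    for j in range(decomp.n_eigs):
        if abs(omega[j]) < ZERO_OMEGA_TOL and _is_constant_eigfun(decomp, j):
            J1.append(j)

    harmonics = sorted(set(harmonic_of.values()))
    for m in harmonics:
        members = [j for j, mm in harmonic_of.items() if mm == m]
        pos = [j for j in members if omega[j].imag > 0]
        pos.sort(key=lambda j: -omega[j].real)  # Re closest to 0 first
        pairs = []
        for j in pos:
            mate = _conjugate_partner(omega, members, j)
            pairs.append((j, mate) if mate is not None else (j,))
        if len(pairs) > 2:
            log.info("harmonic %d has %d pairs; keeping two slowest-decaying",
                     m, len(pairs))
        if pairs:
            J1.extend(pairs[0])
        if len(pairs) > 1:
            J2.extend(pairs[1])
    return BranchAssignment(J1=sorted(J1), J2=sorted(J2),
                            harmonic_of=dict(harmonic_of),
                            f_triplet=f_triplet)


def _conjugate_partner(omega: np.ndarray, candidates, j: int):
    """Index of the eigenvalue conjugate to omega[j], if present."""
    target = np.conj(omega[j])
    best, best_d = None, np.inf
    for k in candidates:
        if k == j or omega[k].imag >= 0:
            continue
        d = abs(omega[k] - target)
        if d < best_d:
            best, best_d = k, d
    tol = max(1e-6, 1e-6 * abs(target))
    return best if best is not None and best_d < max(tol, 0.05) else None


def find_phi_star(decomp: KoopmanDecomposition,
                  branches: BranchAssignment,
                  tol_real: float = 0.05,
                  imag_tol: float = 1e-6) -> int:
    """Locate the slow percept-tracking eigenfunction.

    Among eigenvalues with |frequency| < ``tol_real`` Hz whose
    eigenfunctions are purely real (imaginary RMS below ``imag_tol`` of
    total RMS) and not constant, select the one with the largest real
    part (slowest decay).  The index is recorded in ``branches`` and
    appended to J2.
    """
    omega = decomp.exp_eigvals

    def is_real(j: int) -> bool:
        phi = decomp.eigfuns[:, j]
        rms = np.sqrt(np.mean(np.abs(phi) ** 2))
        return rms > 0 and np.sqrt(np.mean(phi.imag ** 2)) <= imag_tol * rms

    candidates = [j for j in range(decomp.n_eigs)
                  if abs(decomp.frequencies[j]) < tol_real
                  and not _is_constant_eigfun(decomp, j)
                  and is_real(j)]
    if not candidates:
        raise KoopstreamError("no purely real decaying eigenvalue found")
    if len(candidates) > 1:
        branches.multiple_real_candidates = True
        log.info("multiple real decaying eigenvalues %s; choosing the "
                 "slowest-decaying", candidates)
    star = max(candidates, key=lambda j: omega[j].real)
    branches.phi_star_index = star
    branches.omega_star = float(omega[star].real)
    if star not in branches.J2:
        branches.J2 = sorted(branches.J2 + [star])
    return star


def phi_star_series(decomp: KoopmanDecomposition,
                    branches: BranchAssignment) -> np.ndarray:
    """Real time series of phi_star."""
    if branches.phi_star_index is None:
        raise KoopstreamError("phi_star not located yet")
    return decomp.eigfuns[:, branches.phi_star_index].real.copy()


def orient_phi_star(phi_star: np.ndarray,
                    sample_labels: np.ndarray | None) -> tuple[np.ndarray, bool]:
    """Fix the arbitrary sign of phi_star using percept labels.

    By convention the median of phi_star over two-stream samples exceeds the
    median over one-stream samples; the series is negated when the medians
    are reversed.  This post hoc step is the only behavior-aware part of
    feature extraction.  Returns ``(series, oriented)`` where ``oriented``
    is False when labels were unavailable.
    """
    phi_star = np.asarray(phi_star, float)
    if sample_labels is None:
        return phi_star.copy(), False
    labels = np.asarray(sample_labels)
    one = phi_star[labels == LABEL_CODES[ONE_STREAM]]
    two = phi_star[labels == LABEL_CODES[TWO_STREAM]]
    if len(one) == 0 or len(two) == 0:
        return phi_star.copy(), False
    if np.median(two) < np.median(one):
        return -phi_star, True
    return phi_star.copy(), True


def organize_spectrum(decomp: KoopmanDecomposition, f_triplet: float,
                      tol_f: float = 0.2,
                      tol_real: float = 0.05) -> BranchAssignment:
    """Harmonic matching, branch assignment, and phi_star location."""
    harmonic_of = match_harmonics(decomp, f_triplet, tol_f)
    branches = assign_branches(decomp, harmonic_of, f_triplet)
    find_phi_star(decomp, branches, tol_real)
    return branches
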