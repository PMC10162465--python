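"""eDMD oracle suite: linear systems with known spectra, dictionary
selection, exponential eigenvalues, and mode regression."""

import numpy as np
import pytest

from koopstream.datatypes import (DiffusionBasis, KoopstreamError,
                                  Recording)
from koopstream.edmd import (compute_modes, exponential_eigenvalues,
                             harmonic_concentration, reconstruct, run_edmd,
                             select_dictionary, spectral_entropy)

DT = 0.005


def make_basis(vectors, dt=DT):
    vectors = np.asarray(vectors)
    n = vectors.shape[1]
    return DiffusionBasis(eigvals=np.linspace(1, 0.5, n), eigvecs=vectors,
                          epsilon=1.0, kmin=1, knn=1, dt=dt)


class TestRunEdmd:
    def test_diagonal_linear_system_recovered(self):
        # x_{k+1} = diag(0.9, 0.5) x_k observed through its coordinates:
        # eDMD on a linear-in-dictionary system equals DMD
        k = np.arange(200)
        dictionary = np.column_stack([0.9 ** k, 0.5 ** k])
        decomp = run_edmd(dictionary, DT)
        lam = np.sort(decomp.discrete_eigvals.real)[::-1]
        np.testing.assert_allclose(lam, [0.9, 0.5], atol=1e-10)
        np.testing.assert_allclose(decomp.exp_eigvals,
                                   np.log(decomp.discrete_eigvals) / DT)

    def test_rotation_gives_unit_circle_pair_at_frequency(self):
        f = 1.67
        t = np.arange(2000) * DT
        dictionary = np.column_stack([np.cos(2 * np.pi * f * t),
                                      np.sin(2 * np.pi * f * t)])
        decomp = run_edmd(dictionary, DT)
        lam = decomp.discrete_eigvals
        assert np.allclose(np.abs(lam), 1.0, atol=1e-8)
        freqs = np.sort(decomp.frequencies)
        np.testing.assert_allclose(freqs, [-f, f], atol=1e-8)

    def test_constant_feature_gives_unit_eigenvalue(self, rng):
        t = np.arange(500) * DT
        dictionary = np.column_stack([np.ones_like(t),
                                      np.cos(2 * np.pi * 2 * t) * 0.97 ** (
                                          t / DT)])
        decomp = run_edmd(dictionary, DT)
        i = np.argmin(np.abs(decomp.discrete_eigvals - 1.0))
        assert abs(decomp.discrete_eigvals[i] - 1.0) < 1e-8
        phi = decomp.eigfuns[:, i]
        assert np.allclose(phi, phi[0], atol=1e-6 * np.abs(phi[0]))

    def test_conjugate_symmetry_and_unit_rms(self):
        t = np.arange(1000) * DT
        dictionary = np.column_stack([
            np.cos(2 * np.pi * 1.67 * t) * np.exp(-0.1 * t),
            np.sin(2 * np.pi * 1.67 * t) * np.exp(-0.1 * t)])
        decomp = run_edmd(dictionary, DT)
        lam = decomp.discrete_eigvals
        assert np.allclose(np.sort(lam.imag), np.sort(-lam.imag))
        rms = np.sqrt(np.mean(np.abs(decomp.eigfuns) ** 2, axis=0))
        np.testing.assert_allclose(rms, 1.0, atol=1e-9)


class TestExponentialEigenvalues:
    @pytest.mark.parametrize("lam, dt, expected", [
        (1.0, DT, 0.0),
        (np.exp(-0.005), 0.005, -1.0),
    ])
    def test_real_cases(self, lam, dt, expected):
        assert exponential_eigenvalues([lam], dt)[0] == pytest.approx(
            expected, abs=1e-12)

    def test_complex_case(self):
        lam = 0.99 * np.exp(1j * 2 * np.pi * 1.67 * DT)
        om = exponential_eigenvalues([lam], DT)[0]
        assert om.imag / (2 * np.pi) == pytest.approx(1.67)
        assert om.real == pytest.approx(np.log(0.99) / DT)

    def test_zero_rejected(self):
        with pytest.raises(KoopstreamError):
            exponential_eigenvalues([0.0], DT)


class TestDictionarySelection:
    def test_cutoff_at_first_noise_vector(self, rng):
        t = np.arange(6000) * DT
        clean = [np.ones_like(t)] + [
            np.sin(2 * np.pi * f * t) for f in (1.67, 3.33, 5.0)]
        noise = [rng.normal(size=len(t)) for _ in range(5)]
        basis = make_basis(np.column_stack(clean + noise))
        cutoff, diag = select_dictionary(basis, 1.0 / 0.6, 200.0)
        assert cutoff == 4
        assert np.all(diag.concentration[1:4] > 0.9)

    def test_all_noise_keeps_only_constant_with_warning(self, rng):
        t = np.arange(4000) * DT
        cols = [np.ones_like(t)] + [rng.normal(size=len(t))
                                    for _ in range(6)]
        basis = make_basis(np.column_stack(cols))
        with pytest.warns(RuntimeWarning, match="constant"):
            cutoff, _ = select_dictionary(basis, 1.0 / 0.6, 200.0)
        assert cutoff == 1

    def test_no_cutoff_keeps_all_with_warning(self):
        t = np.arange(4000) * DT
        cols = [np.ones_like(t)] + [np.sin(2 * np.pi * m / 0.6 * t)
                                    for m in (1, 2, 3, 4)]
        basis = make_basis(np.column_stack(cols))
        with pytest.warns(RuntimeWarning, match="keeping all"):
            cutoff, _ = select_dictionary(basis, 1.0 / 0.6, 200.0)
        assert cutoff == 5

    def test_modulated_sidebands_not_mistaken_for_noise(self):
        # percept-style phase modulation spreads power into sidebands
        # around the harmonic; such vectors stay in the dictionary
        t = np.arange(12000) * DT
        z = (np.sin(2 * np.pi * t / 17.0) > 0).astype(float)
        cols = [np.ones_like(t)] + [
            np.sin(2 * np.pi * 1.67 * t + z * np.pi / 2 + ph)
            for ph in (0, np.pi / 3, np.pi / 2)]
        basis = make_basis(np.column_stack(cols))
        with pytest.warns(RuntimeWarning, match="keeping all"):
            cutoff, _ = select_dictionary(basis, 1.0 / 0.6, 200.0)
        assert cutoff == 4

    def test_entropy_separates_noise_from_structure(self, rng):
        t = np.arange(4000) * DT
        assert spectral_entropy(rng.normal(size=4000)) > 0.9
        assert spectral_entropy(np.sin(2 * np.pi * 1.67 * t)) < 0.2

    def test_harmonic_concentration_of_pure_tone(self):
        t = np.arange(6000) * DT
        h, _, peak = harmonic_concentration(np.sin(2 * np.pi * 3.33 * t),
                                            200.0, 1.0 / 0.6)
        assert h > 0.99
        assert peak == pytest.approx(3.33, abs=0.05)


class TestModes:
    def _decomp(self):
        t = np.arange(2000) * DT
        dictionary = np.column_stack([np.ones_like(t),
                                      np.cos(2 * np.pi * 1.67 * t),
                                      np.sin(2 * np.pi * 1.67 * t)])
        return run_edmd(dictionary, DT), t

    def test_exact_representation_recovered(self):
        decomp, t = self._decomp()
        pair = [j for j in range(3)
                if abs(decomp.frequencies[j]) > 0.1]
        target = 2 * decomp.eigfuns[:, pair[0]].real
        rec = Recording(target, rate=200.0)
        modes = compute_modes(rec, decomp)
        # conjugate pair modes are conjugate; off-pair mode vanishes
        np.testing.assert_allclose(modes[pair[0], 0],
                                   np.conj(modes[pair[1], 0]), atol=1e-8)
        other = [j for j in range(3) if j not in pair]
        assert np.all(np.abs(modes[other, 0]) < 1e-8)
        resid = reconstruct(decomp)[:, 0] - target
        assert np.max(np.abs(resid)) < 1e-8

    def test_reconstruction_in_span_has_tiny_residual(self, rng):
        decomp, t = self._decomp()
        y = (1.3 + 0.7 * np.cos(2 * np.pi * 1.67 * t + 0.4))
        rec = Recording(y, rate=200.0)
        compute_modes(rec, decomp)
        resid = reconstruct(decomp)[:, 0] - y
        assert np.max(np.abs(resid)) < 1e-8
        # imaginary part of the full complex sum is negligible
        full = decomp.eigfuns @ decomp.modes
        assert np.max(np.abs(full.imag)) < 1e-8 * np.max(np.abs(y))
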