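"""Optimal orthogonal filter design: LP solution, factorization, bandwidth."""

import numpy as np
import pytest
import pywt

from capdet.filterbank import (
    AutocorrelationSequence,
    InfeasibleDesignError,
    SpectralFactorizationError,
    WaveletFilterBank,
    autocorrelation,
    compute_rms_bandwidth,
    conjugate_quadrature,
    count_vanishing_moments,
    design_omsbm_filter,
    solve_min_bandwidth_autocorrelation,
    spectral_factorize,
)


def quadrature_bandwidth(h: np.ndarray, n: int = 1 << 17) -> float:
    """Independent oracle: (1/2pi) * integral of w^2 |H(w)|^2 dw on (-pi, pi)."""
    h = np.asarray(h, float) / np.linalg.norm(h)
    w = np.linspace(-np.pi, np.pi, n)
    H = np.exp(-1j * np.outer(w, np.arange(len(h)))) @ h
    integrand = w**2 * np.abs(H) ** 2
    return float(np.trapezoid(integrand, w) / (2 * np.pi))


class TestAutocorrelationSolver:
    def test_length_two_is_constraint_forced_haar(self):
        seq = solve_min_bandwidth_autocorrelation(2, 1)
        np.testing.assert_allclose(seq.r, [1.0, 0.5], atol=1e-9)

    @pytest.mark.parametrize("L,p", [(4, 1), (4, 2), (8, 2), (12, 4), (12, 6)])
    def test_solution_satisfies_invariants(self, L, p):
        seq = solve_min_bandwidth_autocorrelation(L, p)
        assert abs(seq.r[0] - 1.0) < 1e-8
        assert np.max(np.abs(seq.r[2::2])) < 1e-8
        omega = np.linspace(0, np.pi, 50001)
        assert seq.spectrum(omega).min() > -1e-8

    def test_max_moment_solution_is_daubechies(self):
        # with p = L/2 the feasible set is the single maximally-flat point
        seq = solve_min_bandwidth_autocorrelation(4, 2)
        db2 = np.asarray(pywt.Wavelet("db2").dec_lo, float)
        np.testing.assert_allclose(seq.r, autocorrelation(db2 / np.linalg.norm(db2)),
                                   atol=1e-7)

    def test_objective_beats_daubechies_and_symlet(self):
        seq = solve_min_bandwidth_autocorrelation(12, 4)
        b_opt = compute_rms_bandwidth(spectral_factorize(seq)).b_sq
        for name in ("db6", "sym6"):
            ref = np.asarray(pywt.Wavelet(name).dec_lo, float)
            assert b_opt < compute_rms_bandwidth(ref).b_sq
            assert b_opt < quadrature_bandwidth(ref)

    def test_infeasible_moment_count_raises(self):
        with pytest.raises(InfeasibleDesignError):
            solve_min_bandwidth_autocorrelation(12, 7)
        with pytest.raises(ValueError):
            solve_min_bandwidth_autocorrelation(11, 4)


class TestSpectralFactorization:
    def test_haar(self):
        h = spectral_factorize(np.array([1.0, 0.5]))
        np.testing.assert_allclose(h, np.array([1.0, 1.0]) / np.sqrt(2), atol=1e-12)

    @pytest.mark.parametrize("L,p", [(4, 2), (8, 3), (12, 4)])
    def test_roundtrip_on_designed_autocorrelations(self, L, p):
        seq = solve_min_bandwidth_autocorrelation(L, p)
        h = spectral_factorize(seq)
        assert len(h) == L
        assert np.max(np.abs(autocorrelation(h) - seq.r)) < 1e-5

    def test_roundtrip_on_strictly_positive_spectrum(self):
        # valid L=4 autocorrelation whose spectrum never touches zero
        r = np.array([1.0, 0.3, 0.0, 0.05])
        seq = AutocorrelationSequence(r)
        omega = np.linspace(0, np.pi, 10001)
        assert seq.spectrum(omega).min() > 0.1  # strictly positive, precondition
        h = spectral_factorize(r)
        assert np.max(np.abs(autocorrelation(h) - r)) < 1e-6

    def test_negative_spectrum_rejected(self):
        with pytest.raises(SpectralFactorizationError):
            spectral_factorize(np.array([1.0, 0.9, 0.0, 0.0]))  # R(pi) = -0.8

    def test_minimum_phase_convention(self):
        h = spectral_factorize(solve_min_bandwidth_autocorrelation(12, 4))
        # zeros away from z=-1 lie on or inside the unit circle
        roots = np.roots(h[::-1])
        off_minus_one = roots[np.abs(roots + 1) > 1e-3]
        assert np.all(np.abs(off_minus_one) <= 1.0 + 1e-6)


class TestVanishingMoments:
    def test_haar_highpass_has_one(self):
        g = np.array([1.0, -1.0]) / np.sqrt(2)
        assert count_vanishing_moments(g) == 1

    def test_daubechies2_highpass_has_two(self):
        h = np.asarray(pywt.Wavelet("db2").dec_lo, float)
        g = conjugate_quadrature(h)
        # oracle: direct moment sums
        n = np.arange(len(g))
        assert abs(np.sum(g)) < 1e-6 and abs(np.sum(n * g)) < 1e-6
        assert abs(np.sum(n**2 * g)) > 1e-6
        assert count_vanishing_moments(g) == 2

    def test_designed_bank_has_requested_moments(self, omsbm_bank):
        assert count_vanishing_moments(omsbm_bank.g, tol=1e-6) == 4
        assert omsbm_bank.vanishing_moments == 4


class TestFilterBank:
    def test_designed_bank_invariants(self, omsbm_bank):
        omsbm_bank.validate(tol=1e-6)
        assert abs(omsbm_bank.h.sum() - np.sqrt(2)) < 1e-6
        assert abs(omsbm_bank.g.sum()) < 1e-6
        assert omsbm_bank.orthogonality_defect() < 1e-6

    def test_design_is_deterministic(self, omsbm_bank):
        again = design_omsbm_filter(12, 4, 5)
        np.testing.assert_allclose(again.h, omsbm_bank.h, atol=1e-9)

    def test_save_load_roundtrip(self, omsbm_bank, tmp_path):
        path = tmp_path / "bank.txt"
        omsbm_bank.save(path)
        text = path.read_text()
        assert text.startswith("#L=12 #p=4")
        loaded = WaveletFilterBank.load(path)
        np.testing.assert_allclose(loaded.h, omsbm_bank.h, atol=1e-15)
        assert loaded.levels == 5 and loaded.vanishing_moments == 4


class TestRmsBandwidth:
    def test_haar_closed_form(self):
        b = compute_rms_bandwidth(np.array([1.0, 1.0]) / np.sqrt(2))
        assert abs(b.b_sq - (np.pi**2 / 3 - 2.0)) < 1e-12
        assert abs(b.b_sq - quadrature_bandwidth(np.array([1.0, 1.0]))) < 1e-6

    def test_allpass_impulse(self):
        assert abs(compute_rms_bandwidth(np.array([1.0])).b_sq - np.pi**2 / 3) < 1e-12

    def test_matches_numerical_quadrature(self, omsbm_bank):
        b = compute_rms_bandwidth(omsbm_bank.h)
        assert abs(b.b_sq - quadrature_bandwidth(omsbm_bank.h)) < 1e-6
        assert b.b == pytest.approx(np.sqrt(b.b_sq))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            compute_rms_bandwidth(np.array([]))
        with pytest.raises(ValueError):
            compute_rms_bandwidth(np.array([1.0, np.nan]))
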