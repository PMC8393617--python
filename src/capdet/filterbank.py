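"""Design of orthogonal wavelet filters with minimal mean-squared (RMS) bandwidth.

An orthogonal two-channel filter bank is determined by its real lowpass
``h[0..L-1]``; the highpass follows by the conjugate-quadrature rule
``g[n] = (-1)^n h[L-1-n]``.  Orthogonality constrains only the
autocorrelation ``r[k] = sum_n h[n] h[n+k]``: unit energy (``r[0] = 1``),
double-shift orthogonality (``r[2k] = 0``) and a nonnegative spectrum
``R(w) = r[0] + 2 sum_k r[k] cos(wk) = |H(w)|^2 >= 0``.  The frequency
localization of the lowpass is measured by its mean-squared bandwidth

    B^2 = (1/2pi) int_{-pi}^{pi} w^2 |H(w)|^2 dw
        = (pi^2/3) r[0] + 4 sum_{k>=1} (-1)^k r[k] / k^2,

a *linear* functional of ``r``.  Minimizing B^2 over the convex set of
admissible autocorrelations with ``p`` vanishing moments (a zero of order
``2p`` of ``R`` at ``w = pi``) is therefore a convex program; we solve it as
a linear program after factoring the vanishing-moment zero out exactly,
enforcing nonnegativity of the residual trigonometric polynomial on a dense
frequency grid and verifying on a denser one.  The lowpass is then recovered
from the optimal autocorrelation by minimum-phase spectral factorization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import linprog

__all__ = [
    "AutocorrelationSequence",
    "WaveletFilterBank",
    "BandwidthValue",
    "FilterDesignError",
    "InfeasibleDesignError",
    "SpectralFactorizationError",
    "solve_min_bandwidth_autocorrelation",
    "spectral_factorize",
    "design_omsbm_filter",
    "compute_rms_bandwidth",
    "count_vanishing_moments",
    "conjugate_quadrature",
    "autocorrelation",
]


class FilterDesignError(RuntimeError):
    """Raised when a filter design problem cannot be solved."""


class InfeasibleDesignError(FilterDesignError):
    """Raised when the requested (length, vanishing moments) pair is infeasible."""


class SpectralFactorizationError(FilterDesignError):
    """Raised when an autocorrelation cannot be factorized into a real filter."""


def autocorrelation(h: np.ndarray) -> np.ndarray:
    """Nonnegative-lag autocorrelation ``r[k] = sum_n h[n] h[n+k]``."""
    h = np.asarray(h, dtype=float)
    full = np.correlate(h, h, mode="full")
    return full[len(h) - 1 :]


@dataclass(frozen=True)
class AutocorrelationSequence:
    """Autocorrelation of an orthogonal lowpass filter.

    ``r[k]`` for lags ``k = 0..L-1``.  Valid instances have unit energy,
    vanishing even nonzero lags and a nonnegative spectrum ``R(w)``.
    """

    r: np.ndarray
    tol: float = 1e-8

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))

    @property
    def L(self) -> int:
        return len(self.r)

    def spectrum(self, omega: np.ndarray) -> np.ndarray:
        """Evaluate ``R(w) = r[0] + 2 sum_{k>=1} r[k] cos(wk)``."""
        omega = np.asarray(omega, dtype=float)
        k = np.arange(1, self.L)
        return self.r[0] + 2.0 * np.cos(np.multiply.outer(omega, k)) @ self.r[1:]

    def validate(self, n_grid: int = 4096) -> None:
        """Raise ``ValueError`` if any defining invariant is violated."""
        if abs(self.r[0] - 1.0) > self.tol:
            raise ValueError(f"r[0] = {self.r[0]!r}, expected 1 (unit energy)")
        even = self.r[2::2]
        if even.size and np.max(np.abs(even)) > self.tol:
            raise ValueError("even nonzero lags violate double-shift orthogonality")
        rmin = self.spectrum(np.linspace(0.0, np.pi, n_grid)).min()
        if rmin < -self.tol:
            raise ValueError(f"spectrum negative: min R(w) = {rmin:g}")


@dataclass(frozen=True)
class BandwidthValue:
    """Mean-squared bandwidth ``B^2`` (rad^2/sample^2) and its square root."""

    b_sq: float

    @property
    def b(self) -> float:
        return math.sqrt(self.b_sq)


@dataclass
class WaveletFilterBank:
    """Orthogonal conjugate-quadrature pair with a decomposition depth.

    Attributes
    ----------
    h : lowpass coefficients, normalized so ``sum(h) = sqrt(2)``.
    g : highpass coefficients, ``g[n] = (-1)^n h[L-1-n]``.
    levels : dyadic decomposition depth.
    vanishing_moments : number of vanishing moments of ``g``.
    """

    h: np.ndarray
    g: np.ndarray
    levels: int
    vanishing_moments: int
    name: str = ""

    @property
    def L(self) -> int:
        return len(self.h)

    @classmethod
    def from_lowpass(
        cls, h: np.ndarray, levels: int, name: str = ""
    ) -> "WaveletFilterBank":
        h = np.asarray(h, dtype=float)
        g = conjugate_quadrature(h)
        p = count_vanishing_moments(g)
        return cls(h=h, g=g, levels=levels, vanishing_moments=p, name=name)

    def validate(self, tol: float = 1e-6) -> None:
        h = self.h
        if abs(h.sum() - math.sqrt(2)) > tol:
            raise ValueError(f"sum(h) = {h.sum():g}, expected sqrt(2)")
        r = autocorrelation(h)
        target = np.zeros(self.L)
        target[0] = 1.0
        defect = np.max(np.abs(r[::2] - target[::2]))
        if defect > tol:
            raise ValueError(f"double-shift orthogonality defect {defect:g}")
        if abs(self.g.sum()) > tol:
            raise ValueError(f"sum(g) = {self.g.sum():g}, expected 0")

    def orthogonality_defect(self) -> float:
        """Largest deviation of ``sum_n h[n] h[n+2k]`` from ``delta[k]``."""
        r = autocorrelation(self.h)[::2]
        r[0] -= 1.0
        return float(np.max(np.abs(r)))

    def save(self, path: str | Path) -> None:
        """Write coefficients to a plain-text file, one per line."""
        path = Path(path)
        lines = [
            f"#L={self.L} #p={self.vanishing_moments} #levels={self.levels}",
        ]
        lines += [f"{c:.17e}" for c in self.h]
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WaveletFilterBank":
        levels = 5
        coeffs: list[float] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.replace("#", " ").split():
                    if tok.startswith("levels="):
                        levels = int(tok.split("=")[1])
                continue
            coeffs.append(float(line))
        return cls.from_lowpass(np.array(coeffs), levels=levels)


def conjugate_quadrature(h: np.ndarray) -> np.ndarray:
    """Highpass ``g[n] = (-1)^n h[L-1-n]`` of a lowpass ``h``."""
    h = np.asarray(h, dtype=float)
    signs = (-1.0) ** np.arange(len(h))
    return signs * h[::-1]


def count_vanishing_moments(g: np.ndarray, tol: float = 1e-6) -> int:
    """Largest ``p`` with ``|sum_n n^m g[n]| < tol`` for all ``m < p``.

    Moments are evaluated with index origin 0, so the count is invariant
    to the sign convention of ``g`` but not to index shifts, which only
    rescale the moment sums by lower-order ones already tested.
    """
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("empty filter")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = np.arange(len(g), dtype=float)
    p = 0
    for m in range(len(g)):
        if abs(np.sum(n**m * g)) >= tol:
            break
        p += 1
    return p


def _binomial_lowpass_factor(p: int) -> np.ndarray:
    """Coefficients of ``((1 + z)/2)^p``."""
    return np.array([math.comb(p, i) for i in range(p + 1)], dtype=float) / 2.0**p


def _q_to_r_matrix(L: int, p: int) -> np.ndarray:
    """Linear map from cosine coefficients of Q to ``r[0..L-1]``.

    Parameterizes ``R(w) = ((1 + cos w)/2)^p Q(w)`` with
    ``Q(w) = q[0] + 2 sum_{k=1}^{K} q[k] cos(wk)``, ``K = L-1-p``, so the
    order-2p zero at ``w = pi`` (the vanishing-moment condition) holds by
    construction and nonnegativity of R reduces to nonnegativity of Q.
    """
    K = L - 1 - p
    V = np.array([0.25, 0.5, 0.25])
    Vp = np.array([1.0])
    for _ in range(p):
        Vp = np.convolve(Vp, V)
    M = np.zeros((L, K + 1))
    for j in range(K + 1):
        lau = np.zeros(2 * K + 1)
        lau[K] = 1.0 if j == 0 else 0.0
        if j > 0:
            lau[K + j] = 1.0
            lau[K - j] = 1.0
        full = np.convolve(Vp, lau)
        c = len(full) // 2
        M[:, j] = full[c : c + L]
    return M


def bandwidth_functional(L: int) -> np.ndarray:
    """Coefficient vector c with ``B^2 = c @ r`` for lags ``0..L-1``.

    From ``(1/2pi) int w^2 e^{-jwk} dw = 2 (-1)^k / k^2`` (``k != 0``) and
    ``pi^2/3`` at ``k = 0``; the factor 2 on positive lags accounts for the
    symmetric negative lags.
    """
    k = np.arange(1, L)
    return np.concatenate([[np.pi**2 / 3.0], 4.0 * (-1.0) ** k / k**2])


def solve_min_bandwidth_autocorrelation(
    L: int, p: int, n_grid: int = 16385
) -> AutocorrelationSequence:
    """Minimize the mean-squared bandwidth over orthogonal autocorrelations.

    Parameters
    ----------
    L : filter length (even, >= 2).
    p : vanishing moments (1 <= p <= L/2).
    n_grid : frequency samples on [0, pi] for the nonnegativity constraint.

    Returns
    -------
    AutocorrelationSequence
        The optimal ``r`` with ``r[0] = 1``, zero even lags, an order-2p
        zero of ``R`` at ``pi`` and ``R(w) >= 0``.

    Notes
    -----
    The objective and every constraint are linear in the residual
    trigonometric polynomial Q (see ``_q_to_r_matrix``), so the problem is
    solved as a linear program with the HiGHS solver, which is
    deterministic.  The semi-infinite constraint ``Q(w) >= 0`` is sampled
    on ``n_grid`` points and re-verified on a 16x denser grid afterwards;
    spectral factorization projects any residual between-grid dip (of order
    ``(pi/n_grid)^2``) back onto the nonnegative cone.
    """
    if L < 2 or L % 2:
        raise ValueError(f"filter length must be even and >= 2, got {L}")
    if L > 40:
        raise ValueError(
            f"filter length {L} unsupported: double-precision spectral "
            "factorization is unreliable beyond L = 40"
        )
    if not 1 <= p <= L // 2:
        raise InfeasibleDesignError(
            f"vanishing moments p={p} infeasible for length L={L}; need 1 <= p <= L/2"
        )
    K = L - 1 - p
    M = _q_to_r_matrix(L, p)
    c_q = M.T @ bandwidth_functional(L)
    rows = [0] + [2 * i for i in range(1, L // 2)]
    A_eq = M[rows, :]
    b_eq = np.zeros(len(rows))
    b_eq[0] = 1.0
    omega = np.linspace(0.0, np.pi, n_grid)
    C = np.ones((n_grid, K + 1))
    for j in range(1, K + 1):
        C[:, j] = 2.0 * np.cos(j * omega)
    res = linprog(
        c_q,
        A_ub=-C,
        b_ub=np.zeros(n_grid),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(None, None)] * (K + 1),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleDesignError(
            f"no orthogonal length-{L} autocorrelation with {p} vanishing moments"
        )
    if res.status != 0:
        raise FilterDesignError(f"LP solver failed: {res.message} (status {res.status})")
    r = M @ res.x
    seq = AutocorrelationSequence(r=r)
    seq.validate(n_grid=16 * n_grid)
    return seq


def _deflate_pi_zeros(P: np.ndarray, tol: float) -> tuple[np.ndarray, int]:
    """Divide out ``(1+z)^2`` factors (zeros of R at w = pi), tracking count."""
    scale = np.max(np.abs(P))
    m = 0
    while len(P) > 2:
        quo, rem = npoly.polydiv(P, np.array([1.0, 2.0, 1.0]))
        if np.max(np.abs(rem)) >= tol * scale:
            break
        P = 4.0 * quo  # the 1/(4z) of (1+cos w)/2 = (1+z)^2/(4z) re-centers lags
        m += 1
    return P, m


def _select_minphase_roots(roots: np.ndarray, circle_tol: float = 1e-5) -> list[complex]:
    """Pick one root of each reciprocal pair, minimum-phase convention.

    Strictly interior roots are kept as-is.  Roots on the unit circle occur
    with even multiplicity in a nonnegative spectrum; they are clustered by
    angle magnitude and half of each cluster is retained at the mean angle,
    preserving conjugate symmetry so the factor stays real.  This also
    projects a spectrum with tiny negative dips (grid-discretization
    artifacts) onto the nonnegative cone.
    """
    kept: list[complex] = [z for z in roots if abs(z) < 1.0 - circle_tol]
    circ = np.array([z for z in roots if abs(abs(z) - 1.0) <= circle_tol])
    if circ.size == 0:
        return kept
    angs = np.sort(np.abs(np.angle(circ)))
    clusters: list[list[float]] = [[angs[0]]]
    for a in angs[1:]:
        if a - clusters[-1][-1] < 0.05:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    for cl in clusters:
        n = len(cl)
        theta = float(np.mean(cl))
        real_axis = theta < 1e-6 or abs(theta - np.pi) < 1e-6
        if real_axis:
            if n % 2:
                raise SpectralFactorizationError(
                    "odd-multiplicity unit-circle root: spectrum significantly "
                    "negative; project R onto the nonnegative cone first"
                )
            kept += [complex(np.cos(theta))] * (n // 2)
        else:
            if n % 4:
                raise SpectralFactorizationError(
                    "unpaired unit-circle roots: spectrum significantly "
                    "negative; project R onto the nonnegative cone first"
                )
            kept += [np.exp(1j * theta), np.exp(-1j * theta)] * (n // 4)
    return kept


def _refine_orthogonality(h: np.ndarray, p: int, max_iter: int = 8) -> np.ndarray:
    """Gauss-Newton projection onto the exact orthonormality manifold.

    Root-finding on the spectrum polynomial leaves an O(1e-8) defect in the
    double-shift orthogonality, which would otherwise propagate into the
    perfect-reconstruction and Parseval identities of a deep decomposition.
    A few minimum-norm Newton steps enforce ``sum_n h[n] h[n+2k] = delta[k]``,
    ``sum h = sqrt(2)`` and the ``p`` (linear) vanishing-moment conditions to
    machine precision, perturbing the coefficients by no more than the
    factorization error itself.
    """
    L = len(h)
    n_idx = np.arange(L)
    moment_rows = [
        ((L - 1.0 - n_idx) ** m) * (-1.0) ** (L - 1 - n_idx) for m in range(p)
    ]
    for _ in range(max_iter):
        r = autocorrelation(h)
        res = [r[0] - 1.0] + [r[2 * k] for k in range(1, L // 2)]
        res.append(h.sum() - math.sqrt(2))
        res += [row @ h for row in moment_rows]
        F = np.array(res)
        if np.max(np.abs(F)) < 1e-14:
            break
        rows = []
        for k in range(L // 2):
            grad = np.zeros(L)
            for j in range(L):
                if j + 2 * k < L:
                    grad[j] += h[j + 2 * k]
                if j - 2 * k >= 0:
                    grad[j] += h[j - 2 * k]
            rows.append(grad)
        rows.append(np.ones(L))
        rows += moment_rows
        J = np.stack(rows)
        h = h - J.T @ np.linalg.solve(J @ J.T, F)
    return h


def spectral_factorize(
    r: AutocorrelationSequence | np.ndarray,
    residual_tol: float = 1e-5,
    deflation_tol: float = 1e-6,
) -> np.ndarray:
    """Recover a real lowpass ``h`` with ``autocorrelation(h) = r``.

    Roots of the spectrum polynomial are split by reciprocal pairs under the
    minimum-phase convention (roots on or inside the unit circle kept);
    zeros at ``z = -1`` are deflated analytically first and re-attached as an
    exact binomial factor, so the vanishing-moment structure survives
    factorization at machine precision.  The result is scaled to
    ``sum(h) = sqrt(2)`` with positive sum.

    Raises
    ------
    SpectralFactorizationError
        If the spectrum is negative beyond tolerance or the round-trip
        residual ``max_k |autocorrelation(h)[k] - r[k]|`` exceeds
        ``residual_tol``.
    """
    if isinstance(r, AutocorrelationSequence):
        rvec = r.r
    else:
        rvec = np.asarray(r, dtype=float)
    L = len(rvec)
    lau = np.concatenate([rvec[:0:-1], rvec])  # ascending coeffs of z^{L-1} R(z)
    P, m = _deflate_pi_zeros(lau, deflation_tol)
    if len(P) > 1:
        roots = np.roots(P[::-1])
        kept = _select_minphase_roots(roots)
        f = np.real(npoly.polyfromroots(kept))
        acf = np.correlate(f, f, mode="full")
        # least-squares scale matching all lags of the deflated spectrum
        s_sq = float(acf @ P) / float(acf @ acf)
        if s_sq <= 0:
            raise SpectralFactorizationError("spectrum not factorizable (negative scale)")
        f = f * math.sqrt(s_sq)
    else:
        f = np.array([math.sqrt(max(P[0], 0.0))])
    h = np.convolve(f, _binomial_lowpass_factor(m)) if m else f
    if len(h) != L:
        raise SpectralFactorizationError(
            f"factor length {len(h)} != {L}; invalid autocorrelation"
        )
    if h.sum() < 0:
        h = -h
    # an orthogonal design with R(pi) = 0 has R(0) = 2, i.e. sum(h) = sqrt(2);
    # snap to the exact normalization and polish orthogonality only then
    # (a generic nonnegative spectrum fixes its own scale through r)
    if abs(h.sum() - math.sqrt(2)) < 1e-3:
        h = h * (math.sqrt(2) / h.sum())
        h = _refine_orthogonality(h, p=m)
    resid = float(np.max(np.abs(autocorrelation(h) - rvec)))
    if resid > residual_tol:
        raise SpectralFactorizationError(
            f"round-trip residual {resid:g} > {residual_tol:g}; spectrum may be "
            "negative — project R onto the nonnegative cone before factorization"
        )
    return h


def compute_rms_bandwidth(h: np.ndarray) -> BandwidthValue:
    """Mean-squared bandwidth of a filter, normalized to unit energy."""
    h = np.asarray(h, dtype=float)
    if h.size == 0 or not np.all(np.isfinite(h)):
        raise ValueError("filter must be non-empty and finite")
    r = autocorrelation(h / np.linalg.norm(h))
    return BandwidthValue(b_sq=float(bandwidth_functional(len(h)) @ r))


def design_omsbm_filter(
    L: int = 12, p: int = 4, levels: int = 5
) -> WaveletFilterBank:
    """Design the minimum-RMS-bandwidth orthogonal wavelet filter bank.

    Composes :func:`solve_min_bandwidth_autocorrelation` and
    :func:`spectral_factorize`, then builds the conjugate-quadrature
    highpass.  Defaults (length 12, 4 vanishing moments, 5 levels) are the
    configuration used for CAP phase detection.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    seq = solve_min_bandwidth_autocorrelation(L, p)
    h = spectral_factorize(seq)
    fb = WaveletFilterBank.from_lowpass(h, levels=levels, name=f"omsbm{L}-{p}")
    if fb.vanishing_moments < p:
        raise FilterDesignError(
            f"designed filter has {fb.vanishing_moments} vanishing moments, expected {p}"
        )
    return fb
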