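"""Linear spatiotemporal resonance of the distributed circuit.

A drifting-grating input ``j = j0 cos(kx - wt)`` drives a response carried by
four wave components (cosine/sine of each population).  Substituting the
component ansatz into the linearized field equations yields a linear system
``H Z = I0`` whose 4x4 wave-component interaction matrix depends on the
stimulus frequencies (k, w).  The squared magnitude of the determinant
decomposes into three terms,

    H = mu [ (k^2 - k_n^2 + lam^2)^2 + 4 k_n^2 lam^2 ]^2         (spatial)
      + w^2 [ kappa4 k^4 - kappa2 k^2 ]                          (interaction)
      + w^2 [ tau_E^2 w^2 + kappa0 ]                             (temporal)

and the stimulus frequencies minimizing H (hence maximizing the response
magnitude, whose denominator it is) define the spatial resonance k_r(w) and
temporal resonance w_r(k).  The asymptote kappa_asymp = kappa2 / (2 kappa4)
separates regime 1 (k_r rises with w) from regime 2 (k_r falls with w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .greens import NonOscillatoryError, wave_params
from .params import ContinuumParams

__all__ = [
    "interaction_matrix",
    "WaveComponentVector",
    "solve_amplitudes",
    "DetCoefficients",
    "det_coefficients",
    "spatial_resonance",
    "temporal_resonance",
    "response_surface",
    "NearResonanceError",
]


class NearResonanceError(ArithmeticError):
    """The interaction matrix is singular at the requested (k, omega)."""


def interaction_matrix(k: float, omega: float, c: ContinuumParams) -> np.ndarray:
    """The 4x4 wave-component interaction matrix at stimulus frequencies (k, w).

    Component order is (E_C, E_S, I_C, I_S): cosine and sine amplitudes of
    the excitatory, then inhibitory, population.
    """
    A = c.W_EE - 1.0 - k**2 * c.D_EE
    B = -c.W_EI + k**2 * c.D_EI
    C = c.W_IE - k**2 * c.D_IE
    D = -c.W_II - 1.0 + k**2 * c.D_II
    tw = c.tau_E * omega
    return np.array(
        [
            [A, tw, B, 0.0],
            [-tw, A, 0.0, B],
            [C, 0.0, D, omega],
            [0.0, C, -omega, D],
        ]
    )


@dataclass(frozen=True)
class WaveComponentVector:
    """Cosine/sine amplitudes of the drifting-grating response."""

    E_C: float
    E_S: float
    I_C: float
    I_S: float

    @property
    def E_amplitude(self) -> float:
        return math.hypot(self.E_C, self.E_S)

    @property
    def I_amplitude(self) -> float:
        return math.hypot(self.I_C, self.I_S)


def solve_amplitudes(
    k: float, omega: float, j0: float, c: ContinuumParams, det_tol: float = 1e-12
) -> WaveComponentVector:
    """Cramer's-rule solution of H Z = I0 with I0 = -j0 (alpha, 0, 1-alpha, 0)."""
    H = interaction_matrix(k, omega, c)
    detH = np.linalg.det(H)
    scale = max(np.abs(H).max() ** 4, 1.0)
    if abs(detH) < det_tol * scale:
        raise NearResonanceError(
            f"near-resonance singularity: |det H| = {abs(detH):.3g} at "
            f"(k={k}, omega={omega})"
        )
    I0 = -j0 * np.array([c.alpha, 0.0, 1.0 - c.alpha, 0.0])
    comps = []
    for i in range(4):
        Hi = H.copy()
        Hi[:, i] = I0
        comps.append(np.linalg.det(Hi) / detH)
    return WaveComponentVector(*comps)


@dataclass(frozen=True)
class DetCoefficients:
    """Weight-dependent constants of the determinant decomposition."""

    mu: float
    kappa4: float
    kappa2: float
    kappa0: float
    k_n: float
    lam: float

    @property
    def kappa_asymp(self) -> float:
        return self.kappa2 / (2.0 * self.kappa4)

    def H(self, k, omega):
        """Evaluate the decomposed determinant at (k, omega) (vectorized)."""
        k = np.asarray(k, dtype=float)
        omega = np.asarray(omega, dtype=float)
        term_a = self.mu * ((k**2 - self.k_n**2 + self.lam**2) ** 2
                            + 4.0 * self.k_n**2 * self.lam**2) ** 2
        term_b = omega**2 * (self.kappa4 * k**4 - self.kappa2 * k**2)
        term_c = omega**2 * (0.0 + omega**2 * self._tauE2 + self.kappa0)
        return term_a + term_b + term_c

    # tau_E^2 is stored privately so H() carries everything it needs
    _tauE2: float = 1.0


def det_coefficients(c: ContinuumParams, n_check: int = 100, rtol: float = 1e-8,
                     rng: np.random.Generator | None = None) -> DetCoefficients:
    """Extract (mu, kappa4, kappa2, kappa0) so the three-term decomposition
    reproduces det H identically.

    The constants follow from the exact expansion of the determinant (the
    4x4 matrix is the real representation of a complex 2x2 system, so
    det H = |det_c|^2): with P(u) the static quadratic (u = k^2) and
    R(u) = A + tau_E D its trace-like companion,

        mu = p2^2,  kappa4 = R1^2 - 2 tau_E p2,
        kappa2 = -(2 R0 R1 - 2 tau_E p1),  kappa0 = R0^2 - 2 tau_E p0.

    The identity is then verified against the numeric determinant at
    ``n_check`` random (k, omega) points; failure raises with the maximum
    residual (a guard against a wrong term decomposition).
    """
    w = wave_params(c)  # raises NonOscillatoryError outside the wave regime
    p2, p1, p0 = c.static_poly()
    R0 = (c.W_EE - 1.0) - c.tau_E * (c.W_II + 1.0)
    R1 = c.tau_E * c.D_II - c.D_EE
    coeffs = DetCoefficients(
        mu=p2**2,
        kappa4=R1**2 - 2.0 * c.tau_E * p2,
        kappa2=2.0 * c.tau_E * p1 - 2.0 * R0 * R1,
        kappa0=R0**2 - 2.0 * c.tau_E * p0,
        k_n=w.k_n,
        lam=w.lam,
        _tauE2=c.tau_E**2,
    )
    rng = rng or np.random.default_rng(0)
    ks = rng.uniform(0.0, 3.0 * w.k_n, n_check)
    ws = rng.uniform(-5.0, 5.0, n_check)
    worst = 0.0
    for k, om in zip(ks, ws):
        ref = np.linalg.det(interaction_matrix(k, om, c))
        val = float(coeffs.H(k, om))
        worst = max(worst, abs(val - ref) / max(abs(ref), 1e-12))
    if worst > rtol:
        raise ArithmeticError(
            f"determinant decomposition mismatch: max relative residual {worst:.3g}"
        )
    return coeffs


def _regime(coeffs: DetCoefficients) -> int:
    return 1 if coeffs.k_n**2 - coeffs.lam**2 < coeffs.kappa_asymp else 2


def spatial_resonance(omega: float, c: ContinuumParams,
                      coeffs: DetCoefficients | None = None) -> dict:
    """Spatial resonance frequency k_r at stimulus temporal frequency omega.

    Solves dH/dk = 0 on the branch continuous with sqrt(k_n^2 - lam^2) at
    omega = 0.  In regime 1 (k_n^2 - lam^2 < kappa_asymp) k_r rises with
    omega toward sqrt(kappa_asymp); in regime 2 it falls toward the same
    asymptote.  Returns a dict with ``k_r``, ``regime`` and ``asymptote``.
    """
    coeffs = coeffs or det_coefficients(c)
    a = coeffs.k_n**2 - coeffs.lam**2
    ka = coeffs.kappa_asymp
    regime = _regime(coeffs)
    if omega == 0.0:
        return {"k_r": math.sqrt(a), "regime": regime, "asymptote": math.sqrt(ka) if ka > 0 else math.nan}
    if ka <= 0:
        # no positive asymptote: resonance collapses toward k = 0 at high omega
        ka_edge = 0.0
    else:
        ka_edge = ka

    # dH/dk = 0  <=>  omega^2 = (2 mu / kappa4) * [(u-a)^2 + 4 kn^2 lam^2] * (u-a) / (ka - u)
    # with u = k^2, valid on the branch between a and ka.
    mu, k4 = coeffs.mu, coeffs.kappa4
    b2 = 4.0 * coeffs.k_n**2 * coeffs.lam**2

    def omega2_of_u(u):
        return 2.0 * mu / k4 * ((u - a) ** 2 + b2) * (u - a) / (ka - u)

    lo, hi = (a, ka_edge) if a < ka_edge else (ka_edge, a)
    eps = 1e-12 + 1e-9 * abs(hi - lo)
    f = lambda u: omega2_of_u(u) - omega**2
    try:
        u_r = brentq(f, lo + eps, hi - eps, xtol=1e-12, rtol=1e-12)
    except ValueError:
        return {"k_r": math.nan, "regime": regime, "asymptote": math.sqrt(ka) if ka > 0 else math.nan,
                "status": "out-of-range omega"}
    return {"k_r": math.sqrt(max(u_r, 0.0)), "regime": regime,
            "asymptote": math.sqrt(ka) if ka > 0 else math.nan}


def temporal_resonance(k: float, c: ContinuumParams,
                       coeffs: DetCoefficients | None = None) -> dict:
    """Temporal resonance frequency omega_r at stimulus spatial frequency k.

    From dH/domega = 0:  omega_r^2 = (kappa2 k^2 - kappa4 k^4 - kappa0) /
    (2 tau_E^2).  A negative right-hand side is a typed no-resonance result,
    not an error.
    """
    coeffs = coeffs or det_coefficients(c)
    rhs = (coeffs.kappa2 * k**2 - coeffs.kappa4 * k**4 - coeffs.kappa0) / (
        2.0 * coeffs._tauE2
    )
    if rhs < 0:
        return {"omega_r": math.nan, "status": "no temporal resonance at this k"}
    return {"omega_r": math.sqrt(rhs), "status": "ok"}


def response_surface(
    k_values, omega_values, j0: float, c: ContinuumParams
) -> dict:
    """Excitatory response amplitude over a (k, omega) grid, with ridge line.

    The amplitude is the magnitude of the excitatory cosine/sine pair from
    the Cramer solution.  The ridge is the per-omega argmax over k.  Singular
    (near-resonant) points are masked (NaN) and counted.
    """
    k_values = np.asarray(k_values, dtype=float)
    omega_values = np.asarray(omega_values, dtype=float)
    if np.any(np.diff(k_values) <= 0) or np.any(np.diff(omega_values) < 0):
        raise ValueError("frequency grids must be sorted")
    amp = np.empty((omega_values.size, k_values.size))
    n_masked = 0
    for i, om in enumerate(omega_values):
        for j, k in enumerate(k_values):
            try:
                amp[i, j] = solve_amplitudes(k, om, j0, c).E_amplitude
            except NearResonanceError:
                amp[i, j] = np.nan
                n_masked += 1
    ridge = k_values[np.nanargmax(amp, axis=1)]
    return {
        "k": k_values,
        "omega": omega_values,
        "amplitude": amp,
        "ridge_k": ridge,
        "n_masked": n_masked,
    }
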