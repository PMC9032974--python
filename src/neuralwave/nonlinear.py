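"""Contrast-dependent resonance from the nonlinear wave-interaction matrix.

For a static grating ``j = j0 cos(kx)`` the single-harmonic ansatz
``r_E = E cos(kx)``, ``r_I = I cos(kx)`` (third and higher spatial harmonics
discarded) reduces the cubic field equations to a 2x2 algebraic system

    M(E, I) Y = J0,   Y = (E, I)^T,   J0 = -j0 (alpha, 1-alpha)^T

whose matrix depends on the solution amplitudes through the cubic terms:
M_EE and M_II each acquire a ``-(3/4) gamma A^2`` self-correction (the 3/4
is the cos^3 -> cos first-harmonic projection).  The fixed point of
``Y_{n+1} = M(Y_n)^{-1} J0`` is the contrast-dependent response; its
resonance condition shifts with amplitude,

    k_r^2 = (k_n^2 - lam^2) - xi_I I^2 + xi_E E^2,

so the direction of the contrast-induced peak shift is set by the sign of
``xi_E - xi_I``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .greens import wave_params
from .params import ContinuumParams
from .resonance import solve_amplitudes

__all__ = [
    "wave_interaction_matrix",
    "NonlinearState",
    "NonlinearCoefficients",
    "nonlinear_coefficients",
    "iterate_amplitudes",
    "contrast_surface",
    "resonance_shift",
]


def wave_interaction_matrix(E: float, I: float, k: float, c: ContinuumParams) -> np.ndarray:
    """The amplitude-dependent 2x2 wave-interaction matrix M(E, I)."""
    return np.array(
        [
            [
                c.W_EE - 0.75 * c.gamma_E * E**2 - 1.0 - k**2 * c.D_EE,
                -c.W_EI + k**2 * c.D_EI,
            ],
            [
                c.W_IE - k**2 * c.D_IE,
                -c.W_II - 0.75 * c.gamma_I * I**2 - 1.0 + k**2 * c.D_II,
            ],
        ]
    )


@dataclass(frozen=True)
class NonlinearState:
    """Converged (or partial) solution of the amplitude fixed point."""

    E: float
    I: float
    k: float
    j0: float
    iterations: int
    converged: bool
    residual: float
    relaxation: float = 1.0

    def defect(self, c: ContinuumParams) -> float:
        """Residual of M(Y) Y = J0, independent of the iteration path."""
        M = wave_interaction_matrix(self.E, self.I, self.k, c)
        J0 = -self.j0 * np.array([c.alpha, 1.0 - c.alpha])
        return float(np.linalg.norm(M @ np.array([self.E, self.I]) - J0))


@dataclass(frozen=True)
class NonlinearCoefficients:
    """Constants of the explicit amplitude iteration map.

    Derived by expanding the Cramer solution of the amplitude system: with
    P(u) = p2 u^2 + p1 u + p0 the static determinant (u = k^2) and
    b^2 = 4 k_n^2 lam^2,

        det M / p2 = (k^2 - k_n^2 + lam^2 + xi_I I^2 - xi_E E^2)^2
                     + 4 lam^2 k_n^2 + sigma_I I^2 - sigma_E E^2
                     + O(gamma^2, amplitude^4)

    and the numerators are Psi + Phi k^2 + eta A^2 with the eta terms
    carrying the cross-population cubic correction.  All of eta, xi, sigma
    are proportional to the nonlinearity parameters gamma_E, gamma_I and
    vanish in the linear limit.  ``provenance`` records the derivation.
    """

    Psi_E: float
    Phi_E: float
    eta_E: float
    Psi_I: float
    Phi_I: float
    eta_I: float
    xi_E: float
    xi_I: float
    sigma_E: float
    sigma_I: float
    provenance: str = (
        "first-order-in-gamma expansion of the Cramer solution of the "
        "single-harmonic amplitude system"
    )


def nonlinear_coefficients(c: ContinuumParams) -> NonlinearCoefficients:
    """Constants of the amplitude map for parameter set ``c``.

    The excitatory numerator is ``j0 (Psi_E + Phi_E k^2 + eta_E I^2)`` (the
    cubic self-term of the *inhibitory* row enters the excitatory Cramer
    numerator, hence eta_E is proportional to gamma_I) and symmetrically for
    the inhibitory numerator.
    """
    p2, p1, p0 = c.static_poly()
    a = c.alpha
    # numerator_E = j0 [ alpha (W_II + 1) - (1-alpha) W_EI
    #                    + k^2 ((1-alpha) D_EI - alpha D_II)
    #                    + (3/4) gamma_I alpha I^2 ]
    Psi_E = a * (c.W_II + 1.0) - (1.0 - a) * c.W_EI
    Phi_E = (1.0 - a) * c.D_EI - a * c.D_II
    eta_E = 0.75 * c.gamma_I * a
    # numerator_I = j0 [ (1-alpha)(W_EE - 1) - alpha W_IE ... ] with the sign
    # conventions of det M; the gamma_E self-term of the excitatory row
    # enters here.
    Psi_I = -(1.0 - a) * (c.W_EE - 1.0) + a * c.W_IE
    Phi_I = (1.0 - a) * c.D_EE - a * c.D_IE
    eta_I = 0.75 * c.gamma_E * (1.0 - a)
    # resonance-shift and width terms of det M / p2
    xi_E = 0.75 * c.gamma_E * c.D_II / (2.0 * p2)
    xi_I = 0.75 * c.gamma_I * c.D_EE / (2.0 * p2)
    aa = -p1 / (2.0 * p2)  # k_n^2 - lam^2
    sigma_E = 2.0 * aa * xi_E - 0.75 * c.gamma_E * (c.W_II + 1.0) / p2
    sigma_I = 2.0 * aa * xi_I - 0.75 * c.gamma_I * (c.W_EE - 1.0) / p2
    return NonlinearCoefficients(
        Psi_E=Psi_E, Phi_E=Phi_E, eta_E=eta_E,
        Psi_I=Psi_I, Phi_I=Phi_I, eta_I=eta_I,
        xi_E=xi_E, xi_I=xi_I, sigma_E=sigma_E, sigma_I=sigma_I,
    )


def iterate_amplitudes(
    j0: float,
    k: float,
    c: ContinuumParams,
    tol: float = 1e-10,
    max_iter: int = 500,
    relaxation: float | None = None,
) -> NonlinearState:
    """Fixed-point iteration Y_{n+1} = M(Y_n)^{-1} J0.

    Starts from the linear (gamma = 0) Cramer solution.  If the raw
    iteration oscillates, a fixed under-relaxation of 0.5 is applied
    (recorded in the state); ``relaxation`` overrides the automatism.
    """
    if j0 < 0:
        raise ValueError("j0 must be nonnegative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    lin = solve_amplitudes(k, 0.0, j0, c.replace(gamma_E=0.0, gamma_I=0.0))
    Y = np.array([lin.E_C, lin.I_C])
    J0 = -j0 * np.array([c.alpha, 1.0 - c.alpha])
    omega_relax = relaxation if relaxation is not None else 1.0
    last_steps: list[np.ndarray] = []
    residual = math.inf
    for it in range(1, max_iter + 1):
        M = wave_interaction_matrix(Y[0], Y[1], k, c)
        det = np.linalg.det(M)
        if abs(det) < 1e-14 * max(np.abs(M).max() ** 2, 1.0):
            raise ArithmeticError(
                f"singular wave-interaction matrix at iteration {it} "
                f"(k={k}, j0={j0})"
            )
        Y_new = np.linalg.solve(M, J0)
        step = Y_new - Y
        # oscillation heuristic: successive steps pointing in opposite
        # directions without shrinking -> damp the update
        if relaxation is None and len(last_steps) >= 2:
            s1, s2 = last_steps[-1], last_steps[-2]
            if np.dot(step, s1) < 0 and np.linalg.norm(step) > 0.9 * np.linalg.norm(s2):
                omega_relax = 0.5
        Y = Y + omega_relax * step
        last_steps.append(step)
        residual = float(np.linalg.norm(omega_relax * step))
        if residual < tol:
            return NonlinearState(
                E=float(Y[0]), I=float(Y[1]), k=k, j0=j0,
                iterations=it, converged=True, residual=residual,
                relaxation=omega_relax,
            )
    return NonlinearState(
        E=float(Y[0]), I=float(Y[1]), k=k, j0=j0,
        iterations=max_iter, converged=False, residual=residual,
        relaxation=omega_relax,
    )


def contrast_surface(j0_values, k_values, c: ContinuumParams, tol: float = 1e-10,
                     max_iter: int = 500) -> dict:
    """Converged |E| over a contrast x spatial-frequency sweep.

    Returns the amplitude surface (contrast rows, k columns; non-converged
    cells masked as NaN), the per-contrast peak-k curve, and the count of
    masked cells.
    """
    j0_values = np.asarray(j0_values, dtype=float)
    k_values = np.asarray(k_values, dtype=float)
    if np.any(np.diff(j0_values) < 0) or np.any(np.diff(k_values) <= 0):
        raise ValueError("sweeps must be sorted")
    surf = np.empty((j0_values.size, k_values.size))
    n_masked = 0
    for i, j0 in enumerate(j0_values):
        for j, k in enumerate(k_values):
            try:
                st = iterate_amplitudes(j0, k, c, tol=tol, max_iter=max_iter)
            except ArithmeticError:
                st = None
            if st is None or not st.converged:
                surf[i, j] = np.nan
                n_masked += 1
            else:
                surf[i, j] = abs(st.E)
    peak_k = k_values[np.nanargmax(surf, axis=1)]
    return {
        "j0": j0_values,
        "k": k_values,
        "amplitude": surf,
        "peak_k": peak_k,
        "n_masked": n_masked,
    }


def resonance_shift(c: ContinuumParams, E: float, I: float) -> dict:
    """Amplitude-shifted resonance frequency.

    Evaluates ``k_r^2 = (k_n^2 - lam^2) - xi_I I^2 + xi_E E^2``; with the
    equal-amplitude simplification ``E = I = A`` this is
    ``k_r^2 = (k_n^2 - lam^2) - A^2 (xi_I - xi_E)``.  A negative right-hand
    side is returned as a typed "resonance suppressed" result.
    """
    w = wave_params(c)
    nc = nonlinear_coefficients(c)
    rhs = (w.k_n**2 - w.lam**2) - nc.xi_I * I**2 + nc.xi_E * E**2
    if rhs < 0:
        return {"k_r": math.nan, "status": "resonance suppressed", "rhs": rhs}
    return {"k_r": math.sqrt(rhs), "status": "ok", "rhs": rhs}
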