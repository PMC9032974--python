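"""Explicit integration of the continuum two-population field equations.

The model integrated here is

    tau_E dr_E/dt = -r_E + W_EE r_E + D_EE r_E'' - W_EI r_I - D_EI r_I''
                    + alpha j - gamma_E (tau_E dr_E/dt + r_E)^3
          dr_I/dt = -r_I + W_IE r_E + D_IE r_E'' - W_II r_I - D_II r_I''
                    + (1 - alpha) j - gamma_I (dr_I/dt + r_I)^3

The cubic terms contain the time derivative itself.  Writing
``y = tau dr/dt + r`` turns each equation into ``y + gamma y^3 = F`` with
``F`` the linear right-hand side plus ``r``; the cubic is strictly monotone
in ``y`` so its unique real root gives ``dr/dt = (y - r)/tau`` exactly, and
the update remains an ordinary explicit step.
"""

from __future__ import annotations

import numpy as np

from .chain import ChainInstabilityError
from .fields import ResponseField
from .params import ContinuumParams
from .stimuli import Stimulus1D

__all__ = ["simulate_pde", "stable_dt"]


def _solve_monotone_cubic(F: np.ndarray, gamma: float) -> np.ndarray:
    """Unique real root y of gamma*y^3 + y = F (gamma >= 0)."""
    if gamma == 0.0:
        return F
    # depressed cubic y^3 + p y + q = 0 with p = 1/gamma > 0 -> one real root
    p = 1.0 / gamma
    q = -F / gamma
    disc = np.sqrt((q / 2.0) ** 2 + (p / 3.0) ** 3)
    return np.cbrt(-q / 2.0 + disc) + np.cbrt(-q / 2.0 - disc)


def _laplacian(r: np.ndarray, dx: float, periodic: bool) -> np.ndarray:
    if periodic:
        return (np.roll(r, -1) - 2.0 * r + np.roll(r, 1)) / dx**2
    lap = np.empty_like(r)
    lap[1:-1] = r[2:] - 2.0 * r[1:-1] + r[:-2]
    lap[0] = r[1] - 2.0 * r[0]          # absorbing: zero beyond the edge
    lap[-1] = r[-2] - 2.0 * r[-1]
    return lap / dx**2


def stable_dt(c: ContinuumParams, dx: float, safety: float = 0.2) -> float:
    """Conservative explicit-Euler step for the coupled diffusion system."""
    dmax = max(abs(c.D_EE), abs(c.D_EI), abs(c.D_IE), abs(c.D_II), 1e-12)
    tau_min = min(c.tau_E, 1.0)
    return safety * min(tau_min * dx**2 / (4.0 * dmax), 0.25 * tau_min)


def simulate_pde(
    c: ContinuumParams,
    s: Stimulus1D,
    domain: tuple[float, float] = (-60.0, 60.0),
    nx: int = 512,
    t_end: float = 400.0,
    dt: float | None = None,
    tol: float = 1e-8,
    boundary: str = "absorbing",
    record: bool = False,
    record_stride: int = 200,
    blowup: float = 1e6,
) -> ResponseField:
    """Integrate the field equations to steady state (or for ``t_end``).

    ``boundary`` is ``"absorbing"`` (zero value beyond the edges; default, the
    domain should extend well past the stimulus) or ``"periodic"``.
    """
    if nx < 64:
        raise ValueError("nx must be at least 64")
    if boundary not in ("absorbing", "periodic"):
        raise ValueError("boundary must be 'absorbing' or 'periodic'")
    periodic = boundary == "periodic"

    x = np.linspace(domain[0], domain[1], nx, endpoint=periodic is False)
    if periodic:
        x = domain[0] + (domain[1] - domain[0]) * np.arange(nx) / nx
    dx = float(x[1] - x[0])
    if dt is None:
        dt = stable_dt(c, dx)
    if dt <= 0 or t_end <= dt:
        raise ValueError("need 0 < dt < t_end")

    j_amp = s.render(x)
    r_E = np.zeros(nx)
    r_I = np.zeros(nx)
    n_steps = int(round(t_end / dt))
    frames_E, frames_I, times = [], [], []
    converged = False
    max_deriv = np.inf

    for step in range(n_steps):
        t = step * dt
        j = j_amp * np.cos(s.omega * t) if s.omega != 0.0 else j_amp
        lap_E = _laplacian(r_E, dx, periodic)
        lap_I = _laplacian(r_I, dx, periodic)
        F_E = (
            c.W_EE * r_E + c.D_EE * lap_E - c.W_EI * r_I - c.D_EI * lap_I
            + c.alpha * j
        )
        F_I = (
            c.W_IE * r_E + c.D_IE * lap_E - c.W_II * r_I - c.D_II * lap_I
            + (1.0 - c.alpha) * j
        )
        y_E = _solve_monotone_cubic(F_E, c.gamma_E)
        y_I = _solve_monotone_cubic(F_I, c.gamma_I)
        dE = (y_E - r_E) / c.tau_E
        dI = y_I - r_I
        r_E = r_E + dt * dE
        r_I = r_I + dt * dI
        if not (np.all(np.isfinite(r_E)) and np.all(np.isfinite(r_I))) or (
            np.abs(r_E).max() > blowup or np.abs(r_I).max() > blowup
        ):
            raise ChainInstabilityError(
                f"field integration diverged at t={t:.3f} (dt={dt}, dx={dx:.4f})"
            )
        max_deriv = max(np.abs(dE).max(), np.abs(dI).max())
        if record and step % record_stride == 0:
            frames_E.append(r_E.copy())
            frames_I.append(r_I.copy())
            times.append(t + dt)
        if s.omega == 0.0 and max_deriv < tol:
            converged = True
            break

    meta = {
        "solver": "explicit_euler_pde",
        "dt": dt,
        "dx": dx,
        "t_end": t_end,
        "boundary": boundary,
        "max_abs_deriv": float(max_deriv),
        "steady_state": converged,
    }
    if record:
        return ResponseField(
            grid=x,
            r_E=np.array(frames_E + [r_E]),
            r_I=np.array(frames_I + [r_I]),
            times=np.array(times + [min((step + 1) * dt, t_end)]),
            converged=converged or s.omega != 0.0,
            meta=meta,
        )
    return ResponseField(grid=x, r_E=r_E, r_I=r_I, converged=converged or s.omega != 0.0, meta=meta)
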