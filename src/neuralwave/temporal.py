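"""Temporal interference in a single motif and duration thresholds.

A single excitatory-inhibitory motif in the damped-oscillatory regime rings
at a fixed natural period after a brief pulse.  Oscillations evoked at
different instants superpose (linearly, at small amplitude), so pulse pairs
separated by a full period interfere constructively and pairs separated by
half a period destructively -- the temporal analogue of two-point spatial
interference.

Detection of a stimulus is modeled as the excitatory trace exceeding a
threshold ``theta_det``.  The smallest pulse duration that reaches the
criterion ("duration threshold") is tracked as a function of stimulus
contrast: with excitation-dominated input (high alpha) it declines
monotonically with contrast, whereas with inhibition-dominated input (low
alpha) the sigmoid saturation of excitation lets the growing inhibitory
drive suppress the response at high contrast, making the threshold
non-monotonic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import MotifWeights
from .stimuli import PulseTrain

__all__ = [
    "node_frequency",
    "node_oscillation",
    "duration_threshold",
    "duration_threshold_curve",
    "DurationThresholdCurve",
]


def node_frequency(m: MotifWeights) -> dict:
    """Natural (damped) temporal frequency of the linearized single motif.

    Returns the oscillation frequency ``omega_0`` (imaginary part of the
    eigenvalue pair), decay rate, natural period, and whether the node is in
    the oscillatory (underdamped) regime.
    """
    gE = m.sigmoid_E.slope_at_zero()
    gI = m.sigmoid_I.slope_at_zero()
    J = np.array(
        [
            [(gE * m.w_EE - 1.0) / m.tau_E, -gE * m.w_EI / m.tau_E],
            [gI * m.w_IE, -(gI * m.w_II + 1.0)],
        ]
    )
    ev = np.linalg.eigvals(J)
    omega0 = float(np.abs(ev.imag).max())
    decay = float(-ev.real.max())
    return {
        "omega_0": omega0,
        "decay_rate": decay,
        "period": 2.0 * math.pi / omega0 if omega0 > 0 else math.inf,
        "oscillatory": omega0 > 0,
        "stable": decay > 0,
    }


def node_oscillation(
    m: MotifWeights,
    pulses: PulseTrain,
    t_grid: np.ndarray,
    require_oscillatory: bool = True,
) -> dict:
    """Integrate the single-motif equations driven by a pulse train.

    Returns the excitatory and inhibitory traces on ``t_grid``.  In the
    overdamped regime there is no oscillation to interfere; that case raises
    unless ``require_oscillatory=False``.
    """
    freq = node_frequency(m)
    if require_oscillatory and not freq["oscillatory"]:
        raise ValueError("node is overdamped: no oscillation to interfere")
    t_grid = np.asarray(t_grid, dtype=float)
    dt = float(t_grid[1] - t_grid[0])
    n_sub = max(1, int(math.ceil(dt / (0.02 * min(m.tau_E, 1.0)))))
    h = dt / n_sub
    r_E = np.zeros_like(t_grid)
    r_I = np.zeros_like(t_grid)
    e = i = 0.0
    for n in range(1, t_grid.size):
        t = t_grid[n - 1]
        for ssub in range(n_sub):
            j = float(pulses(np.array([t + ssub * h]))[0])
            C_E = m.w_EE * e - m.w_EI * i + m.alpha * j
            C_I = m.w_IE * e - m.w_II * i + (1.0 - m.alpha) * j
            e = e + h * (-e + m.sigmoid_E(C_E)) / m.tau_E
            i = i + h * (-i + m.sigmoid_I(C_I))
        r_E[n] = e
        r_I[n] = i
    return {"t": t_grid, "r_E": r_E, "r_I": r_I, **freq}


def _peak_after(trace: dict, t_from: float = 0.0) -> float:
    sel = trace["t"] >= t_from
    return float(trace["r_E"][sel].max())


def duration_threshold(
    contrast: float,
    m: MotifWeights,
    theta_det: float = 0.1,
    durations: np.ndarray | None = None,
    t_pad: float = 20.0,
    dt: float = 0.05,
    criterion: str = "peak",
) -> float:
    """Smallest stimulus duration at which the stimulus is "just visible".

    The stimulus is a single rectangular pulse of height ``contrast``.
    Detection criteria: ``"peak"`` -- the excitatory trace exceeds
    ``theta_det`` at any time; ``"integral"`` -- the time-integral of
    supra-zero excitatory activity exceeds ``theta_det``.  Returns ``inf``
    when no tested duration reaches the criterion ("not visible").
    """
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    if durations is None:
        durations = np.concatenate(
            [np.arange(dt, 2.0, dt), np.arange(2.0, 12.0 + 1e-9, 4 * dt)]
        )
    for dur in durations:
        t_grid = np.arange(0.0, dur + t_pad, dt)
        trace = node_oscillation(
            m, PulseTrain(times=(0.0,), amplitudes=(contrast,), width=float(dur)),
            t_grid, require_oscillatory=False,
        )
        if criterion == "peak":
            score = float(trace["r_E"].max())
        elif criterion == "integral":
            score = float(np.trapezoid(np.clip(trace["r_E"], 0.0, None), t_grid))
        else:
            raise ValueError("criterion must be 'peak' or 'integral'")
        if score >= theta_det:
            return float(dur)
    return math.inf


@dataclass(frozen=True)
class DurationThresholdCurve:
    contrasts: np.ndarray
    thresholds: np.ndarray      # inf where never detected
    alpha: float
    theta_det: float
    monotone_decreasing: bool


def duration_threshold_curve(
    contrasts,
    m: MotifWeights,
    theta_det: float = 0.1,
    **kw,
) -> DurationThresholdCurve:
    """Duration threshold across a contrast sweep, with monotonicity label."""
    contrasts = np.asarray(contrasts, dtype=float)
    th = np.array([duration_threshold(ct, m, theta_det=theta_det, **kw) for ct in contrasts])
    finite = np.isfinite(th)
    mono = bool(np.all(np.diff(th[finite]) <= 1e-12)) if finite.sum() >= 2 else False
    return DurationThresholdCurve(
        contrasts=contrasts, thresholds=th, alpha=m.alpha,
        theta_det=theta_det, monotone_decreasing=mono,
    )
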