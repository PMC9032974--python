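"""Circuit parameterizations at the discrete-motif and continuum levels.

The building block of the model is a Wilson-Cowan motif: one excitatory and
one inhibitory unit with reciprocal and recurrent connections.  Motifs are
repeated along a chain with complete nearest-neighbor connectivity.  Two
equivalent parameterizations are used:

* :class:`MotifWeights` -- within-motif weights ``w_xy`` and between-motif
  weights ``wt_xy`` of the discrete chain, plus the sigmoid activation
  parameters of each cell class.
* :class:`ContinuumParams` -- the local interaction weights ``W_xy`` and
  spatial-spread coefficients ``D_xy`` of the continuum limit, where
  ``W_xy = w_xy + 2*wt_xy`` and ``D_xy = wt_xy`` (one unit of length equals
  one motif spacing), plus cubic nonlinearity coefficients ``gamma_E/I``
  arising from the Taylor expansion of the sigmoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SigmoidParams",
    "MotifWeights",
    "ContinuumParams",
    "continuum_from_motif",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic activation function with a zero-crossing at zero input.

    ``g(x) = saturation * (sigma(gain*(x - threshold)) - sigma(-gain*threshold))``
    with ``sigma`` the standard logistic.  The offset makes ``g(0) = 0`` so the
    quiescent state is a fixed point of the unstimulated circuit.  With
    ``threshold = 0`` the slope at the origin is ``saturation * gain / 4``; the
    default ``gain = 4 / saturation`` normalizes that slope to one, which makes
    the linearized chain match the continuum weights directly.
    """

    saturation: float = 1.0
    gain: float | None = None
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.saturation <= 0:
            raise ValueError("sigmoid saturation must be positive")
        if self.gain is None:
            object.__setattr__(self, "gain", 4.0 / self.saturation)
        if self.gain <= 0:
            raise ValueError("sigmoid gain must be positive")

    def __call__(self, x):
        a, th, s = self.gain, self.threshold, self.saturation
        base = 1.0 / (1.0 + math.exp(a * th))
        z = np.clip(-a * (np.asarray(x, dtype=float) - th), -700.0, 700.0)
        return s * (1.0 / (1.0 + np.exp(z)) - base)

    def slope_at_zero(self) -> float:
        a, th, s = self.gain, self.threshold, self.saturation
        e = math.exp(a * th)
        return s * a * e / (1.0 + e) ** 2

    def cubic_coefficient(self) -> float:
        """-g'''(0)/6 of the centered expansion; the gamma of the continuum model.

        For the symmetric case (threshold 0) ``g(x) ~ g'(0) x - gamma x^3`` with
        ``gamma = saturation * gain^3 / 48``.
        """
        a, th, s = self.gain, self.threshold, self.saturation
        # third derivative of the logistic at -a*th
        u = 1.0 / (1.0 + math.exp(a * th))
        g3 = s * a**3 * u * (1 - u) * (1 - 6 * u + 6 * u**2)
        return -g3 / 6.0


_PAIRS = ("EE", "EI", "IE", "II")


@dataclass(frozen=True)
class MotifWeights:
    """Connection weights of the discrete motif chain.

    ``w_xy`` couple cells within a motif, ``wt_xy`` couple cells of
    nearest-neighbor motifs (the tilde weights).  ``tau_E`` is the relaxation
    time of excitation in units of the inhibitory relaxation time.  ``alpha``
    is the fraction of the input current delivered to excitatory cells.
    """

    w_EE: float
    w_EI: float
    w_IE: float
    w_II: float
    wt_EE: float
    wt_EI: float
    wt_IE: float
    wt_II: float
    tau_E: float = 1.0
    alpha: float = 0.5
    sigmoid_E: SigmoidParams = field(default_factory=SigmoidParams)
    sigmoid_I: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        for name in [f"w_{p}" for p in _PAIRS] + [f"wt_{p}" for p in _PAIRS]:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.tau_E <= 0:
            raise ValueError("tau_E must be positive")


@dataclass(frozen=True)
class ContinuumParams:
    """Weights of the continuum (PDE) description of the chain.

    ``W_xy`` control local interaction, ``D_xy`` the spatial spread
    (second-difference coupling).  ``gamma_E`` and ``gamma_I`` are the cubic
    damping coefficients of the nonlinear terms.
    """

    W_EE: float
    W_EI: float
    W_IE: float
    W_II: float
    D_EE: float
    D_EI: float
    D_IE: float
    D_II: float
    tau_E: float = 1.0
    alpha: float = 0.5
    gamma_E: float = 0.0
    gamma_I: float = 0.0

    def __post_init__(self) -> None:
        for name in [f"W_{p}" for p in _PAIRS] + [f"D_{p}" for p in _PAIRS]:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.tau_E <= 0:
            raise ValueError("tau_E must be positive")
        if self.gamma_E < 0 or self.gamma_I < 0:
            raise ValueError("gamma coefficients must be nonnegative")

    def replace(self, **kw) -> "ContinuumParams":
        d = asdict(self)
        d.update(kw)
        return ContinuumParams(**d)

    # --- static (zero-frequency) characteristic polynomial -----------------
    def static_poly(self) -> tuple[float, float, float]:
        """Coefficients (p2, p1, p0) of the static determinant P(u) in u = k^2.

        P(u) = det of the linearized static 2x2 system at spatial frequency k,
        ``P = (W_EE - 1 - u D_EE)(-(W_II + 1) + u D_II) - (-W_EI + u D_EI)(W_IE - u D_IE)``.
        """
        p2 = self.D_EI * self.D_IE - self.D_EE * self.D_II
        p1 = (
            (self.W_EE - 1) * self.D_II
            + self.D_EE * (self.W_II + 1)
            - (self.W_EI * self.D_IE + self.W_IE * self.D_EI)
        )
        p0 = self.W_EI * self.W_IE - (self.W_EE - 1) * (self.W_II + 1)
        return p2, p1, p0


def continuum_from_motif(m: MotifWeights) -> ContinuumParams:
    """Map motif-chain weights to continuum weights.

    ``W_xy = w_xy + 2*wt_xy`` and ``D_xy = wt_xy``; the time constant and
    input split carry over.  The cubic coefficients are taken from the Taylor
    expansion of the motif sigmoids around the quiescent state.
    """
    kw = {}
    for p in _PAIRS:
        kw[f"W_{p}"] = getattr(m, f"w_{p}") + 2.0 * getattr(m, f"wt_{p}")
        kw[f"D_{p}"] = getattr(m, f"wt_{p}")
    return ContinuumParams(
        tau_E=m.tau_E,
        alpha=m.alpha,
        gamma_E=max(m.sigmoid_E.cubic_coefficient(), 0.0),
        gamma_I=max(m.sigmoid_I.cubic_coefficient(), 0.0),
        **kw,
    )
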