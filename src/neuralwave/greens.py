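"""Analytic standing-wave response to point stimulation and its superpositions.

In the oscillatory regime the static linearized field equations have a
Green's function of damped-cosine form,

    G_E(x) = exp(-lam |x|) (Gamma_E cos(k_n x) - Delta_E sign(x) sin(k_n x))
    G_I(x) = exp(-lam |x|) (Gamma_I cos(k_n x) - Delta_I sign(x) sin(k_n x))

with sign(0) = 0.  The intrinsic spatial frequency ``k_n`` and decay rate
``lam`` come from the complex roots of the static spatial characteristic
polynomial; the amplitude coefficients follow from the jump conditions a
delta input imposes at the origin.  Responses to arbitrary inputs are
superpositions (convolutions) of the Green's function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fields import ResponseField
from .params import ContinuumParams
from .stimuli import Stimulus1D

__all__ = [
    "WaveParams",
    "NonOscillatoryError",
    "wave_params",
    "greens_function",
    "linear_response",
    "InterferenceMap",
    "interference_map",
    "zone2_spectrum",
    "decay_null_xmin",
]


class NonOscillatoryError(ValueError):
    """The static system has purely real spatial roots: no intrinsic wave."""


@dataclass(frozen=True)
class WaveParams:
    """Intrinsic wave descriptors of the circuit.

    ``k_n``: intrinsic spatial frequency (radians per unit length);
    ``lam``: spatial decay rate; ``Gamma_*``/``Delta_*``: amplitude
    coefficients of the excitatory and inhibitory components.
    """

    k_n: float
    lam: float
    Gamma_E: float
    Delta_E: float
    Gamma_I: float
    Delta_I: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.k_n <= 0:
            raise ValueError("k_n must be positive in the oscillatory regime")
        for f in (self.Gamma_E, self.Delta_E, self.Gamma_I, self.Delta_I):
            if not math.isfinite(f):
                raise ValueError("wave coefficients must be finite")

    @property
    def period(self) -> float:
        """Intrinsic spatial period 2*pi/k_n."""
        return 2.0 * math.pi / self.k_n


def wave_params(c: ContinuumParams, j0: float = 1.0) -> WaveParams:
    """Extract the intrinsic wave of ``c`` from the static linear system.

    The spatial ansatz exp(s x) in the static, linearized equations gives a
    quadratic in s^2 (the 4th-order characteristic polynomial).  Complex
    conjugate roots s^2 = (lam +- i k_n)^2 define the damped oscillation; real
    roots mean a purely decaying profile and raise
    :class:`NonOscillatoryError`.  The Gamma/Delta coefficients are obtained
    by matching the derivative jumps that a delta input of weight ``j0``
    imposes at x = 0 (the input splits alpha : 1-alpha between E and I).
    """
    p2, p1, p0 = c.static_poly()
    disc = p1 * p1 - 4.0 * p2 * p0
    if p2 == 0.0 or disc >= 0.0:
        raise NonOscillatoryError(
            f"static characteristic polynomial has real roots "
            f"(discriminant {disc:.6g} >= 0): purely decaying profiles"
        )
    # roots of p2 u^2 + p1 u + p0 in u = s^2: a +- i b
    a = -p1 / (2.0 * p2)
    b = math.sqrt(-disc) / (2.0 * p2)
    # s^2 = (lam +- i k_n)^2 = lam^2 - k_n^2 +- 2 i lam k_n ; the static
    # ansatz uses u = s^2 so a = lam^2 - k_n^2 is the real part seen from the
    # decaying side.  In terms of the wavenumber k (u = -k^2) the complex
    # pair sits at k^2 = k_n^2 - lam^2 +- 2 i k_n lam, hence:
    k_n2 = (a + math.hypot(a, b)) / 2.0
    k_n = math.sqrt(k_n2)
    lam = math.sqrt(k_n2 - a)
    if lam == 0.0:
        raise NonOscillatoryError("zero decay rate: marginal (undamped) case")

    # jump conditions at the origin.  For x > 0 the decaying solution is
    # r_E = Re[C exp(s x)], r_I = Re[C phi exp(s x)] with s = -lam + i k_n and
    # phi the eigenvector ratio from the first static equation.
    s = complex(-lam, k_n)
    s2 = s * s
    num = (c.W_EE - 1.0) + c.D_EE * s2
    den = c.W_EI + c.D_EI * s2
    if abs(den) < 1e-14:
        raise NonOscillatoryError("degenerate eigenvector ratio (W_EI + D_EI s^2 = 0)")
    phi = num / den
    # integrating each equation across the delta gives, using even symmetry,
    #   2 (D_EE G_E'(0+) - D_EI G_I'(0+)) = -alpha j0
    #   2 (D_IE G_E'(0+) - D_II G_I'(0+)) = -(1 - alpha) j0
    # with G'(0+) = Re[C s] resp. Re[C phi s]; a real 2x2 system in C.
    aE = (c.D_EE - c.D_EI * phi) * s
    aI = (c.D_IE - c.D_II * phi) * s
    A = np.array([[aE.real, -aE.imag], [aI.real, -aI.imag]])
    rhs = np.array([-c.alpha * j0 / 2.0, -(1.0 - c.alpha) * j0 / 2.0])
    det = np.linalg.det(A)
    if abs(det) < 1e-14:
        raise NonOscillatoryError("singular jump-condition system")
    Cr, Ci = np.linalg.solve(A, rhs)
    C = complex(Cr, Ci)
    CI = C * phi
    return WaveParams(
        k_n=k_n,
        lam=lam,
        Gamma_E=C.real,
        Delta_E=C.imag,
        Gamma_I=CI.real,
        Delta_I=CI.imag,
    )


def greens_function(w: WaveParams, x) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the standing-wave Green's function at positions ``x``.

    Uses the convention sign(0) = 0, so G_E(0) = Gamma_E exactly.
    """
    x = np.asarray(x, dtype=float)
    env = np.exp(-w.lam * np.abs(x))
    sgn = np.sign(x)
    G_E = env * (w.Gamma_E * np.cos(w.k_n * x) - w.Delta_E * sgn * np.sin(w.k_n * x))
    G_I = env * (w.Gamma_I * np.cos(w.k_n * x) - w.Delta_I * sgn * np.sin(w.k_n * x))
    return G_E, G_I


def linear_response(s: Stimulus1D, w: WaveParams, grid) -> ResponseField:
    """Static linear response: convolution of the input with the Green's function.

    Point stimuli are superposed analytically (sums of shifted Green's
    functions); distributed profiles are convolved numerically on the grid.
    The grid must resolve the intrinsic period with at least 8 samples.
    """
    grid = np.asarray(grid, dtype=float)
    dx = float(grid[1] - grid[0])
    if dx > w.period / 8.0:
        raise ValueError(
            f"grid too coarse: dx={dx:.4f} gives fewer than 8 samples per "
            f"intrinsic period {w.period:.4f}"
        )
    if s.kind in ("point", "point_pair"):
        r_E = np.zeros_like(grid)
        r_I = np.zeros_like(grid)
        for p in s.positions:
            gE, gI = greens_function(w, grid - p)
            r_E += s.j0 * gE
            r_I += s.j0 * gI
    else:
        j = s.render(grid)
        # kernel on a symmetric grid long enough for the decay
        half = max(grid[-1] - grid[0], 10.0 / w.lam)
        n_half = int(np.ceil(half / dx))
        xk = np.arange(-n_half, n_half + 1) * dx
        gE, gI = greens_function(w, xk)
        # full convolution; entry i + n_half aligns the kernel center with x_i
        r_E = np.convolve(j, gE, mode="full")[n_half : n_half + grid.size] * dx
        r_I = np.convolve(j, gI, mode="full")[n_half : n_half + grid.size] * dx
    return ResponseField(
        grid=grid, r_E=r_E, r_I=r_I, converged=True,
        meta={"solver": "analytic_superposition", "k_n": w.k_n, "lam": w.lam},
    )


@dataclass
class InterferenceMap:
    """Two-point interference responses over a range of separations."""

    distances: np.ndarray          # separations d
    grid: np.ndarray               # positions x
    field: np.ndarray              # r_E per (d, x)
    energy: np.ndarray             # integral of r_E^2 over x, per d
    peak_amplitude: np.ndarray     # max |r_E| per d
    period_estimate: float         # dominant spatial period of the map

    def row_period(self, i: int) -> float:
        """Dominant spatial period of row ``i`` from zero-crossing spacing."""
        return _dominant_period_zero_crossings(self.grid, self.field[i])


def _dominant_period_zero_crossings(x: np.ndarray, r: np.ndarray) -> float:
    sign = np.sign(r)
    nz = sign != 0
    xs, ss = x[nz], sign[nz]
    idx = np.nonzero(np.diff(ss))[0]
    if idx.size < 2:
        return math.inf
    crossings = 0.5 * (xs[idx] + xs[idx + 1])
    return 2.0 * float(np.mean(np.diff(crossings)))


def interference_map(
    w: WaveParams,
    d_values,
    grid,
    j0: float = 1.0,
) -> InterferenceMap:
    """Linear two-point responses for each separation in ``d_values``.

    Each row is the superposition G_E(x - d/2) + G_E(x + d/2).  The summary
    ``energy`` is the integral of the squared excitatory response over the
    grid -- a phase-robust measure of total activation; ``peak_amplitude`` is
    also reported.
    """
    d_values = np.asarray(d_values, dtype=float)
    if np.any(d_values < 0):
        raise ValueError("separations must be nonnegative")
    grid = np.asarray(grid, dtype=float)
    dx = float(grid[1] - grid[0])
    rows = np.empty((d_values.size, grid.size))
    for i, d in enumerate(d_values):
        gL, _ = greens_function(w, grid + d / 2.0)
        gR, _ = greens_function(w, grid - d / 2.0)
        rows[i] = j0 * (gL + gR)
    energy = np.sum(rows**2, axis=1) * dx
    peak = np.max(np.abs(rows), axis=1)
    periods = [
        _dominant_period_zero_crossings(grid, rows[i]) for i in range(d_values.size)
    ]
    finite = [p for p in periods if math.isfinite(p)]
    return InterferenceMap(
        distances=d_values,
        grid=grid,
        field=rows,
        energy=energy,
        peak_amplitude=peak,
        period_estimate=float(np.median(finite)) if finite else math.inf,
    )


def zone2_spectrum(
    r: ResponseField,
    stim_region: tuple[float, float],
    min_periods: float = 3.0,
    k_hint: float | None = None,
) -> dict:
    """Dominant spatial frequency of the laterally activated segment.

    The lateral (zone 2) segment is everything beyond the right edge of
    ``stim_region``.  Two estimators are reported: the peak of a Hann-windowed
    periodogram of the segment, and the spacing of zero crossings.  The
    segment must extend at least ``min_periods`` estimated periods past the
    edge (checked against ``k_hint`` when given, else against the
    zero-crossing estimate).

    Returns a dict with keys ``k_spectral``, ``k_zero_crossing``,
    ``uncertainty`` (one spectral bin) and ``oscillatory`` (False when the
    spectral peak sits at the zero bin: a pure-decay, non-wave profile).
    """
    rE, _ = r.final()
    x = r.grid
    dx = r.dx
    lateral = x > stim_region[1]
    seg = rE[lateral]
    xs = x[lateral]
    if seg.size < 16:
        raise ValueError("lateral segment too short for spectral estimation")

    period_zc = _dominant_period_zero_crossings(xs, seg)
    k_zc = 2.0 * math.pi / period_zc if math.isfinite(period_zc) else 0.0
    k_ref = k_hint if k_hint is not None else k_zc
    if k_ref > 0 and (xs[-1] - xs[0]) < min_periods * 2.0 * math.pi / k_ref:
        raise ValueError(
            f"lateral segment spans less than {min_periods} intrinsic periods"
        )

    win = np.hanning(seg.size)
    spec = np.abs(np.fft.rfft((seg - seg.mean()) * win)) ** 2
    freqs = np.fft.rfftfreq(seg.size, d=dx) * 2.0 * math.pi
    ipk = int(np.argmax(spec))
    dk = float(freqs[1] - freqs[0])
    # detect the degenerate pure-decay case: spectrum of the raw (not
    # mean-subtracted) segment peaking at the zero bin
    spec_raw = np.abs(np.fft.rfft(seg * win)) ** 2
    oscillatory = int(np.argmax(spec_raw)) != 0 and k_zc > 0
    return {
        "k_spectral": float(freqs[ipk]),
        "k_zero_crossing": float(k_zc),
        "uncertainty": dk,
        "oscillatory": bool(oscillatory),
        "n_samples": int(seg.size),
    }


def decay_null_xmin(A: float, B: float, lam: float, x0: float, x1: float) -> float:
    """Location of the single extremum of a two-sided pure-decay profile.

    If lateral activity were pure exponential decay from two flanking
    stimuli, ``r_E = A exp(-lam (x + x0)) + B exp(-lam (x1 - x))``, the
    derivative vanishes at exactly one point,

        x_min = ln(A exp(lam (x1 - x0)) / B) / (2 lam),

    in contrast to a wave profile with multiple minima.  This is the null
    model against which oscillatory lateral modulation is compared.
    """
    if A <= 0 or B <= 0:
        raise ValueError("boundary activations A, B must be positive")
    if lam <= 0:
        raise ValueError("decay rate must be positive")
    return math.log(A * math.exp(lam * (x1 - x0)) / B) / (2.0 * lam)
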