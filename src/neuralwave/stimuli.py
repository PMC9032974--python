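"""Parametric stimulus descriptions (1D spatial, 2D spatial, temporal)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Stimulus1D", "Stimulus2D", "PulseTrain"]

_KINDS = ("point", "point_pair", "bounded_grating", "custom_profile")


@dataclass(frozen=True)
class Stimulus1D:
    """Input current profile ``j(x, t) = profile(x) * cos(omega t)`` on a line.

    Kinds
    -----
    ``point``
        Discrete approximation of a delta function of weight ``j0`` at each
        entry of ``positions`` (a single entry for one point).
    ``point_pair``
        Two delta functions of weight ``j0`` at ``positions``.
    ``bounded_grating``
        ``j0 * cos(k x + phase)`` inside ``region = (lo, hi)``, zero outside.
    ``custom_profile``
        An arbitrary callable ``profile(x)``.
    """

    kind: str = "point"
    j0: float = 1.0
    k: float = 0.0
    omega: float = 0.0
    region: tuple[float, float] | None = None
    positions: tuple[float, ...] = (0.0,)
    phase: float = 0.0
    profile: object = None  # callable for kind == "custom_profile"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.j0 < 0:
            raise ValueError("j0 must be nonnegative")
        if self.kind == "bounded_grating":
            if self.region is None or not self.region[0] < self.region[1]:
                raise ValueError("bounded_grating needs a well-ordered region (lo, hi)")
        if self.kind == "point_pair" and len(self.positions) != 2:
            raise ValueError("point_pair needs exactly two positions")
        if self.kind == "custom_profile" and not callable(self.profile):
            raise ValueError("custom_profile needs a callable profile")

    def render(self, x: np.ndarray) -> np.ndarray:
        """Spatial profile of the input current sampled on grid ``x``.

        Point sources carry total weight ``j0`` (delta normalization): the
        sample at the nearest grid node gets amplitude ``j0 / dx``.
        """
        x = np.asarray(x, dtype=float)
        j = np.zeros_like(x)
        if self.kind in ("point", "point_pair"):
            dx = float(x[1] - x[0])
            for p in self.positions:
                if not (x[0] - 0.5 * dx <= p <= x[-1] + 0.5 * dx):
                    raise ValueError(f"point position {p} outside the grid")
                # split the weight over the two bracketing nodes (linear
                # interpolation) so off-node positions stay second-order
                f = (p - x[0]) / dx
                i0 = int(np.clip(np.floor(f), 0, x.size - 1))
                i1 = min(i0 + 1, x.size - 1)
                w1 = np.clip(f - i0, 0.0, 1.0)
                j[i0] += self.j0 * (1.0 - w1) / dx
                j[i1] += self.j0 * w1 / dx
        elif self.kind == "bounded_grating":
            lo, hi = self.region
            mask = (x >= lo) & (x < hi)
            j[mask] = self.j0 * np.cos(self.k * x[mask] + self.phase)
        else:
            j = self.j0 * np.asarray(self.profile(x), dtype=float)
        return j


def _ring_mask(X, Y, a, b, width, j0):
    """Elliptical-ring amplitude map: j0 inside the annulus of the ellipse
    with semi-axes (a, b) and radial half-width ``width / 2``."""
    # implicit ellipse coordinate; the annulus is defined between the two
    # scaled ellipses (1 -/+ w) with w the relative half width
    rho = np.sqrt((X / a) ** 2 + (Y / b) ** 2)
    w = width / (2.0 * min(a, b))
    return np.where(np.abs(rho - 1.0) <= w, j0, 0.0)


@dataclass(frozen=True)
class Stimulus2D:
    """2D input-amplitude map on a lattice, with named generators."""

    kind: str = "point"
    j0: float = 1.0
    a: float = 1.0         # semi-axis along x (elliptical_ring)
    b: float = 1.0         # semi-axis along y
    width: float = 0.5     # full radial width of the ring
    position: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "elliptical_ring", "custom_mask"):
            raise ValueError(f"unknown 2D stimulus kind {self.kind!r}")
        if self.j0 < 0:
            raise ValueError("j0 must be nonnegative")
        if self.kind == "elliptical_ring" and (self.a <= 0 or self.b <= 0 or self.width <= 0):
            raise ValueError("elliptical_ring needs positive semi-axes and width")

    def render(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        X, Y = np.meshgrid(x, y, indexing="ij")
        if self.kind == "point":
            dx = float(x[1] - x[0])
            dy = float(y[1] - y[0])
            j = np.zeros_like(X)
            ix = int(np.argmin(np.abs(x - self.position[0])))
            iy = int(np.argmin(np.abs(y - self.position[1])))
            j[ix, iy] = self.j0 / (dx * dy)
            return j
        if self.kind == "elliptical_ring":
            return _ring_mask(X, Y, self.a, self.b, self.width, self.j0)
        m = np.asarray(self.mask, dtype=float)
        if m.shape != X.shape:
            raise ValueError("custom mask shape does not match the lattice")
        return m


@dataclass(frozen=True)
class PulseTrain:
    """Temporal input: rectangular pulses ``amplitudes[i]`` starting at
    ``times[i]``, each of duration ``width`` (time units of the inhibitory
    relaxation time)."""

    times: tuple[float, ...]
    amplitudes: tuple[float, ...]
    width: float = 0.2

    def __post_init__(self) -> None:
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must have equal length")
        if self.width <= 0:
            raise ValueError("pulse width must be positive")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        j = np.zeros_like(t)
        for t0, amp in zip(self.times, self.amplitudes):
            j += np.where((t >= t0) & (t < t0 + self.width), amp, 0.0)
        return j
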