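"""Sampled activity containers and their tabular serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ResponseField", "Field2D"]


@dataclass
class ResponseField:
    """Excitatory/inhibitory firing rates sampled on a uniform 1D grid.

    ``r_E`` and ``r_I`` are either 1D (steady state) or 2D with shape
    ``(n_times, n_x)`` when time-resolved; ``times`` is then populated.
    ``meta`` records parameter provenance and solver diagnostics.
    """

    grid: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    times: np.ndarray | None = None
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.r_E = np.asarray(self.r_E, dtype=float)
        self.r_I = np.asarray(self.r_I, dtype=float)
        if self.r_E.shape != self.r_I.shape:
            raise ValueError("r_E and r_I shapes differ")
        if self.r_E.shape[-1] != self.grid.shape[0]:
            raise ValueError("field shape does not match grid")
        if not (np.all(np.isfinite(self.r_E)) and np.all(np.isfinite(self.r_I))):
            raise ValueError("non-finite values in response field")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def final(self) -> tuple[np.ndarray, np.ndarray]:
        """Last time slice (the field itself if already static)."""
        if self.r_E.ndim == 1:
            return self.r_E, self.r_I
        return self.r_E[-1], self.r_I[-1]

    def to_frame(self) -> pd.DataFrame:
        rE, rI = self.final()
        return pd.DataFrame({"x": self.grid, "r_E": rE, "r_I": rI})

    def save(self, stem: str | Path) -> list[Path]:
        """Write ``<stem>.csv`` (steady state), ``<stem>.npz`` (full arrays)
        and ``<stem>.meta.json``; returns the written paths."""
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        paths = []
        csv = stem.with_suffix(".csv")
        self.to_frame().to_csv(csv, index=False)
        paths.append(csv)
        npz = stem.with_suffix(".npz")
        arrays = {"grid": self.grid, "r_E": self.r_E, "r_I": self.r_I}
        if self.times is not None:
            arrays["times"] = self.times
        np.savez_compressed(npz, **arrays)
        paths.append(npz)
        meta = stem.with_suffix(".meta.json")
        meta.write_text(json.dumps({"converged": self.converged, **self.meta}, indent=2, default=str))
        paths.append(meta)
        return paths


@dataclass
class Field2D:
    """Steady-state activity maps on a 2D lattice."""

    x: np.ndarray
    y: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.r_E = np.asarray(self.r_E, dtype=float)
        self.r_I = np.asarray(self.r_I, dtype=float)
        if self.r_E.shape != (self.x.size, self.y.size):
            raise ValueError("field shape does not match lattice")
        if not (np.all(np.isfinite(self.r_E)) and np.all(np.isfinite(self.r_I))):
            raise ValueError("non-finite values in 2D field")

    @property
    def spacing(self) -> tuple[float, float]:
        return float(self.x[1] - self.x[0]), float(self.y[1] - self.y[0])

    def save(self, stem: str | Path) -> list[Path]:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        npz = stem.with_suffix(".npz")
        np.savez_compressed(npz, x=self.x, y=self.y, r_E=self.r_E, r_I=self.r_I)
        meta = stem.with_suffix(".meta.json")
        meta.write_text(json.dumps({"converged": self.converged, **self.meta}, indent=2, default=str))
        return [npz, meta]
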