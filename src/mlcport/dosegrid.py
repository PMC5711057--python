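"""Dose grid container: 3D (or planar) dose with per-voxel uncertainty."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GridSpec:
    """Axis-aligned scoring grid: lower corner, voxel sizes, voxel counts."""

    origin: tuple          # (x0, y0, z0) cm, lower corner
    voxel: tuple           # (dx, dy, dz) cm
    shape: tuple           # (nx, ny, nz)

    @classmethod
    def plane(cls, x_range, y_range, nx, ny, z_plane, thickness=0.2):
        """A single-voxel-thick planar grid centered on ``z_plane``."""
        dx = (x_range[1] - x_range[0]) / nx
        dy = (y_range[1] - y_range[0]) / ny
        return cls((x_range[0], y_range[0], z_plane - 0.5 * thickness),
                   (dx, dy, thickness), (nx, ny, 1))

    def centers(self, axis: int) -> np.ndarray:
        return (self.origin[axis]
                + (np.arange(self.shape[axis]) + 0.5) * self.voxel[axis])

    def boundaries(self, axis: int) -> np.ndarray:
        return (self.origin[axis]
                + np.arange(self.shape[axis] + 1) * self.voxel[axis])


@dataclass
class DoseGrid:
    """Dose array (x, y, z axis order) with relative per-voxel uncertainty."""

    spec: GridSpec
    dose: np.ndarray                 # Gy or Gy/particle, shape = spec.shape
    rel_uncertainty: np.ndarray      # fractional sigma, same shape
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.rel_uncertainty = np.asarray(self.rel_uncertainty, dtype=float)
        if self.dose.shape != tuple(self.spec.shape):
            raise ValueError(
                f"dose shape {self.dose.shape} != spec {self.spec.shape}")
        if self.rel_uncertainty.shape != self.dose.shape:
            raise ValueError("uncertainty shape mismatch")
        if np.any(self.dose < 0) or np.any(self.rel_uncertainty < 0):
            raise ValueError("dose and uncertainty must be non-negative")

    def scaled(self, factor: float, **meta) -> "DoseGrid":
        """Linearly rescaled copy; relative uncertainties unchanged."""
        m = dict(self.meta)
        m.update(meta)
        return DoseGrid(self.spec, self.dose * factor,
                        self.rel_uncertainty.copy(), m)

    @property
    def max(self) -> float:
        return float(self.dose.max())
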