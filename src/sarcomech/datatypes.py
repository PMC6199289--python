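"""Core data containers shared across the morphometry/geometry/mechanics stages.

Conventions
-----------
* Image stacks are indexed ``(z, y, x)``; ``x`` is the image column axis and,
  for phantoms, the nominal fiber axis.
* All physical lengths are micrometres, forces are micro-newtons, times are
  seconds, angles are degrees.
* Orientations are *axial* quantities: ``theta`` and ``theta + 180`` describe
  the same striation normal, and every average over orientations uses the
  doubled-angle embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class ImageStack:
    """A 3D intensity volume with physical voxel sizes.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, ny, nx)
        Non-negative intensities.
    pixel_size_um : float
        In-plane pixel pitch (isotropic in x and y).
    z_step_um : float
        Axial distance between consecutive slices.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a 3D (z, y, x) array with >= 1 slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_area_um2(self) -> float:
        """Physical area of one full slice (frame area, not fiber area)."""
        ny, nx = self.voxels.shape[1:]
        return ny * nx * self.pixel_size_um**2

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width_x, height_y) of the imaged field in micrometres."""
        ny, nx = self.voxels.shape[1:]
        return nx * self.pixel_size_um, ny * self.pixel_size_um


@dataclass
class OrientationField:
    """Per-pixel axial orientation of the striation normal in one slice.

    ``theta_deg`` lies in (-90, +90] and is meaningful only where ``mask``
    is true; ``energy`` is the non-negative boundary-tensor magnitude used
    both for masking and as the averaging weight.
    """

    theta_deg: np.ndarray
    energy: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.theta_deg.shape == self.energy.shape == self.mask.shape):
            raise ValueError("theta/energy/mask shapes must agree")
        if np.any(self.energy < 0):
            raise ValueError("energy must be non-negative")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class StepAnnotation:
    """One experimental step inside a force trace.

    kind is ``"pca"`` (value = pCa of the bathing solution) or ``"stretch"``
    (value = step size in micrometres).
    """

    kind: str
    value: float
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("pca", "stretch"):
            raise ValueError(f"unknown step kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise ValueError("step window must have positive duration")


@dataclass
class ForceTrace:
    """A sampled force recording with optional actuator position."""

    time_s: np.ndarray
    force_un: np.ndarray
    position_um: Optional[np.ndarray] = None
    annotations: Sequence[StepAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_un = np.asarray(self.force_un, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.force_un.shape:
            raise ValueError("time and force must be 1D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.position_um is not None:
            self.position_um = np.asarray(self.position_um, dtype=float)
            if self.position_um.shape != self.time_s.shape:
                raise ValueError("position must match the time base")
        anns = sorted(self.annotations, key=lambda a: a.start_s)
        for a, b in zip(anns, anns[1:]):
            if b.start_s < a.end_s:
                raise ValueError("step annotations must not overlap")
        self.annotations = anns

    def window(self, start_s: float, end_s: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (t, F) restricted to [start_s, end_s)."""
        sel = (self.time_s >= start_s) & (self.time_s < end_s)
        return self.time_s[sel], self.force_un[sel]
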