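"""Core image containers shared across all pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Volume3D", "DscSeries", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class Volume3D:
    """A scalar 3D image with physical voxel spacing.

    Voxel ``(i, j, k)`` has its center at ``origin_mm + (i, j, k) * spacing_mm``
    (0-based indices, physical millimeters). Axis orientation codes default to
    RAS; they are carried as metadata and preserved by all operations.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def require_same_grid(self, other: "Volume3D") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing_mm} vs "
                f"{other.shape}/{other.spacing_mm}"
            )

    def with_values(self, values: np.ndarray) -> "Volume3D":
        """Copy of this volume with new voxel data, metadata preserved."""
        return replace(self, values=np.asarray(values))

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-physical affine (axis-aligned)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass
class DscSeries:
    """A 4D dynamic susceptibility contrast acquisition: (x, y, z, t) signal.

    ``n_baseline`` pre-bolus time points precede contrast arrival; ``te_ms``
    is the echo time used for the relaxivity conversion; ``dt_s`` the
    sampling interval.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    te_ms: float = 40.0
    dt_s: float = 1.5
    n_baseline: int = 10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"expected a 4D array, got ndim={self.values.ndim}")
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        if not 0 < self.n_baseline < self.values.shape[3]:
            raise ValueError(
                f"n_baseline={self.n_baseline} must lie in (0, n_timepoints)"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt_s
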