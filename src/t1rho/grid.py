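"""Image-grid geometry.

All volumes in the package live on a :class:`GridSpec`: an in-plane grid of
``(nx, ny)`` square-ish pixels covering a shared field of view, replicated
over ``nz`` axial slices with a fixed slice thickness and gap.  Coordinates
are pixel-centre aligned with the FOV origin at the volume centre: the
in-plane centre of pixel ``i`` is ``(i + 0.5) * dx - fov_x / 2`` and slice
``k`` sits at ``(k - (nz - 1) / 2) * pitch`` where ``pitch`` is thickness
plus gap.  Slice index 0 is the most inferior slice.

The two standard grids of the acquisition protocol are provided as
constructors: the 60x60 anatomical grid used for ROI drawing and the 34x34
grid of the spin-lock series, both covering a 15.94 x 15.94 mm FOV with
ten 1 mm slices separated by 0.2 mm gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridError, InvalidParameterError

#: shared cropped field of view of the anatomical and spin-lock grids (mm)
DEFAULT_FOV_MM = 15.94


@dataclass(frozen=True)
class GridSpec:
    """Uniform voxel grid: ``(nx, ny)`` in-plane over ``nz`` axial slices."""

    nx: int
    ny: int
    nz: int
    fov_x_mm: float = DEFAULT_FOV_MM
    fov_y_mm: float = DEFAULT_FOV_MM
    slice_thickness_mm: float = 1.0
    slice_gap_mm: float = 0.2

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise InvalidParameterError("grid dimensions must be positive")
        if self.fov_x_mm <= 0 or self.fov_y_mm <= 0:
            raise InvalidParameterError("FOV must be positive")
        if self.slice_thickness_mm <= 0 or self.slice_gap_mm < 0:
            raise InvalidParameterError("bad slice thickness/gap")

    # -- spacings ---------------------------------------------------------
    @property
    def dx_mm(self) -> float:
        return self.fov_x_mm / self.nx

    @property
    def dy_mm(self) -> float:
        return self.fov_y_mm / self.ny

    @property
    def slice_pitch_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def pixel_area_mm2(self) -> float:
        return self.dx_mm * self.dy_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    # -- voxel-centre coordinates (mm, FOV-centred) -----------------------
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx_mm - self.fov_x_mm / 2

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy_mm - self.fov_y_mm / 2

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) - (self.nz - 1) / 2) * self.slice_pitch_mm

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate volumes, each of shape ``(nx, ny, nz)``."""
        return np.meshgrid(
            self.x_centers(), self.y_centers(), self.z_centers(), indexing="ij"
        )

    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to mm coordinates."""
        aff = np.diag([self.dx_mm, self.dy_mm, self.slice_pitch_mm, 1.0])
        aff[0, 3] = self.x_centers()[0]
        aff[1, 3] = self.y_centers()[0]
        aff[2, 3] = self.z_centers()[0]
        return aff


def anatomical_grid(nz: int = 10) -> GridSpec:
    """60x60 grid of the anatomical (ROI-drawing) images."""
    return GridSpec(60, 60, nz)


def t1rho_grid(nz: int = 10) -> GridSpec:
    """34x34 grid of the cropped spin-lock series."""
    return GridSpec(34, 34, nz)


def check_same_fov(a: GridSpec, b: GridSpec, atol_mm: float = 1e-6) -> None:
    """Raise :class:`GridError` unless two grids share FOV and slice layout."""
    if abs(a.fov_x_mm - b.fov_x_mm) > atol_mm or abs(a.fov_y_mm - b.fov_y_mm) > atol_mm:
        raise GridError(
            f"FOV mismatch: ({a.fov_x_mm}, {a.fov_y_mm}) vs ({b.fov_x_mm}, {b.fov_y_mm})"
        )
    if a.nz != b.nz:
        raise GridError(f"slice count mismatch: {a.nz} vs {b.nz}")
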