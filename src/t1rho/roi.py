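"""ROI handling and derived tumour/brain metrics.

ROIs are drawn on the higher-resolution anatomical grid and transferred to
the coarser spin-lock grid by exact area-overlap resampling: a target
voxel receives a label iff at least half of its in-plane area is covered
by source voxels of that label (inclusive threshold; on an exact 50/50
split between two labels the higher label id, i.e. tumour, wins).  Both
grids must share the cropped FOV and slice structure, so the transfer is
purely in-plane.

Derived metrics:

* ``delta_t1rho`` — the tumour-vs-brain percent difference of mean T1rho,
  ``100 * (tumour - brain) / brain``; computed per measurement (per
  mouse-week) and per FSL.
* ``dispersion_ratios`` — the relative change of T1rho between two
  spin-lock amplitudes, ``(T1rho(FSL_high) - T1rho(FSL_low)) /
  T1rho(FSL_low)``, for every ordered pair of amplitudes (six ratios for
  the four-FSL protocol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import (
    EmptyRoiError,
    GridError,
    InsufficientDataError,
    InvalidParameterError,
)
from .grid import GridSpec, check_same_fov
from .relaxation import T1rhoMap


@dataclass
class RoiMask:
    """Label volume (0 = none, 1 = brain ROI, 2 = tumour ROI) on a grid."""

    labels: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise InvalidParameterError("mask shape does not match grid")


@dataclass(frozen=True)
class RoiSummary:
    """Mean/SD T1rho over the usable voxels of one ROI."""

    roi: str
    mean_t1rho_ms: float
    sd_ms: float
    n_voxels: int
    n_excluded: int


@dataclass(frozen=True)
class DeltaRecord:
    mouse: str
    week: int
    fsl_hz: float
    delta_pct: float


@dataclass(frozen=True)
class DispersionRecord:
    fsl_low_hz: float
    fsl_high_hz: float
    ratio: float


def _overlap_matrix(n_src: int, n_tgt: int) -> np.ndarray:
    """Fraction of target cell j covered by source cell i along one axis.

    Both axes span the same FOV, so with unit FOV the source cells are
    ``[i/n_src, (i+1)/n_src)`` and target cells ``[j/n_tgt, (j+1)/n_tgt)``;
    entry (j, i) is overlap length divided by the target cell width.
    """
    src_edges = np.arange(n_src + 1) / n_src
    tgt_edges = np.arange(n_tgt + 1) / n_tgt
    lo = np.maximum(tgt_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(tgt_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None) * n_tgt


def resample_mask(mask: RoiMask, target_grid: GridSpec) -> RoiMask:
    """Transfer a label mask to another grid by >= 50% area overlap.

    Deterministic and label-conserving: no label can appear in the output
    that is absent from the source.
    """
    check_same_fov(mask.grid, target_grid)
    ox = _overlap_matrix(mask.grid.nx, target_grid.nx)
    oy = _overlap_matrix(mask.grid.ny, target_grid.ny)
    out = np.zeros(target_grid.shape, dtype=mask.labels.dtype)
    labels = sorted(int(v) for v in np.unique(mask.labels) if v != 0)
    for lab in labels:  # ascending: at an exact 50/50 tie the higher id wins
        for k in range(mask.grid.nz):
            frac = ox @ (mask.labels[:, :, k] == lab).astype(float) @ oy.T
            out[:, :, k][frac >= 0.5 - 1e-12] = lab
    return RoiMask(out, target_grid)


def roi_mean(t1rho_map: T1rhoMap, mask: RoiMask, label: int | str,
             label_names: Mapping[int, str] = {1: "brain", 2: "tumour"},
             ) -> RoiSummary:
    """Mean/SD of the fitted T1rho over in-mask, non-missing voxels."""
    if mask.labels.shape != t1rho_map.t1rho_ms.shape:
        raise GridError("map and mask are not on the same grid")
    if isinstance(label, str):
        ids = {v: k for k, v in label_names.items()}
        if label not in ids:
            raise InvalidParameterError(f"unknown ROI label {label!r}")
        label_id, name = ids[label], label
    else:
        label_id, name = int(label), label_names.get(int(label), str(label))
    in_mask = mask.labels == label_id
    vals = t1rho_map.t1rho_ms[in_mask]
    usable = vals[np.isfinite(vals)]
    if usable.size == 0:
        raise EmptyRoiError(f"ROI {name!r} has no usable voxels")
    sd = float(np.std(usable, ddof=1)) if usable.size > 1 else 0.0
    return RoiSummary(roi=name, mean_t1rho_ms=float(usable.mean()), sd_ms=sd,
                      n_voxels=int(usable.size),
                      n_excluded=int(in_mask.sum() - usable.size))


def delta_t1rho(tumour_mean_ms: float, brain_mean_ms: float) -> float:
    """Percent difference of tumour vs brain mean T1rho."""
    if brain_mean_ms <= 0:
        raise InvalidParameterError("brain mean must be positive")
    return 100.0 * (tumour_mean_ms - brain_mean_ms) / brain_mean_ms


def dispersion_ratios(t1rho_by_fsl_ms: Mapping[float, float],
                      ) -> list[DispersionRecord]:
    """Relative T1rho ratios for every ordered FSL pair (low, high)."""
    fsls = sorted(t1rho_by_fsl_ms)
    if len(fsls) < 2:
        raise InsufficientDataError("need at least two FSLs for dispersion")
    if any(t1rho_by_fsl_ms[f] <= 0 for f in fsls):
        raise InvalidParameterError("all T1rho values must be positive")
    out = []
    for i, lo in enumerate(fsls):
        for hi in fsls[i + 1:]:
            ratio = (t1rho_by_fsl_ms[hi] - t1rho_by_fsl_ms[lo]) / t1rho_by_fsl_ms[lo]
            out.append(DispersionRecord(fsl_low_hz=lo, fsl_high_hz=hi, ratio=ratio))
    return out
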