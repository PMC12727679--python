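"""File formats: NIfTI volumes with JSON sidecars, CSV tables, config.

Spin-lock series are stored as 4-D NIfTI-1 (``.nii.gz``), one file per
spin-lock amplitude, shaped ``(nx, ny, n_slices, n_tsl)``; acquisition
metadata travels in a JSON sidecar next to the image (same stem, ``.json``)
with keys ``tsl_ms``, ``fsl_hz``, ``tau_ms``, ``te_ms`` plus the grid
geometry.  Masks are NIfTI label volumes with a sidecar carrying the grid.
The sidecar convention (rather than NIfTI header extensions) keeps the
metadata human-readable and portable.

Study configuration is a validated :class:`StudyConfig` (unknown keys are
rejected); its canonical JSON serialisation is hashed into every output
manifest so any configuration change is visible in the results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import FormatError
from .grid import GridSpec
from .phantom import Cohort, Measurement
from .protocol import SpinLockProtocol
from .roi import RoiMask
from .series import SpinLockSeries


# ---------------------------------------------------------------------------
# NIfTI + sidecar round trip
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _grid_meta(grid: GridSpec) -> dict[str, Any]:
    return dict(nx=grid.nx, ny=grid.ny, n_slices=grid.nz,
                fov_x_mm=grid.fov_x_mm, fov_y_mm=grid.fov_y_mm,
                slice_thickness_mm=grid.slice_thickness_mm,
                slice_gap_mm=grid.slice_gap_mm)


def _grid_from_meta(meta: dict[str, Any]) -> GridSpec:
    return GridSpec(nx=int(meta["nx"]), ny=int(meta["ny"]),
                    nz=int(meta["n_slices"]),
                    fov_x_mm=float(meta["fov_x_mm"]),
                    fov_y_mm=float(meta["fov_y_mm"]),
                    slice_thickness_mm=float(meta["slice_thickness_mm"]),
                    slice_gap_mm=float(meta["slice_gap_mm"]))


def write_series(series: SpinLockSeries, path: str | Path) -> Path:
    """Write a series as 4-D NIfTI-1 plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.data.astype(np.float64), series.grid.affine())
    nib.save(img, str(path))
    meta = dict(tsl_ms=list(series.protocol.tsl_ms), fsl_hz=series.fsl_hz,
                tau_ms=series.protocol.tau_ms, te_ms=series.protocol.te_ms,
                **_grid_meta(series.grid))
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_series(path: str | Path) -> SpinLockSeries:
    """Read a series written by :func:`write_series`; lossless round trip."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    meta = json.loads(sidecar.read_text())
    for key in ("tsl_ms", "fsl_hz", "tau_ms"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key {key!r}")
    data = np.asarray(nib.load(str(path)).get_fdata())
    if data.ndim != 4:
        raise FormatError(f"{path} is not a 4-D series")
    if data.shape[3] != len(meta["tsl_ms"]):
        raise FormatError(
            f"sidecar lists {len(meta['tsl_ms'])} TSLs but {path} has "
            f"{data.shape[3]} volumes")
    grid = _grid_from_meta(meta)
    protocol = SpinLockProtocol(
        tsl_ms=tuple(meta["tsl_ms"]), fsl_hz=(meta["fsl_hz"],),
        tau_ms=meta["tau_ms"], te_ms=meta.get("te_ms", 0.0),
        n_slices=grid.nz, slice_thickness_mm=grid.slice_thickness_mm,
        slice_gap_mm=grid.slice_gap_mm)
    return SpinLockSeries(data=data, fsl_hz=float(meta["fsl_hz"]),
                          protocol=protocol, grid=grid)


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.labels.astype(np.int16), mask.grid.affine())
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps(_grid_meta(mask.grid), indent=1, sort_keys=True))
    return path


def read_mask(path: str | Path) -> RoiMask:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    grid = _grid_from_meta(json.loads(sidecar.read_text()))
    labels = np.asarray(nib.load(str(path)).get_fdata()).astype(np.int16)
    return RoiMask(labels, grid)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a simulated cohort: series + masks + study/truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = cohort.study_table.copy()
    mask_paths, series_paths = [], []
    for meas in cohort.measurements:
        stem = f"{meas.mouse}_w{meas.week}"
        mpath = write_mask(RoiMask(meas.roi_labels, cohort.design.anat_grid),
                           out / "masks" / f"{stem}_roi.nii.gz")
        mask_paths.append(str(mpath.relative_to(out)))
        paths = {}
        for fsl, series in meas.series.items():
            spath = write_series(series,
                                 out / "series" / f"{stem}_fsl{int(fsl)}.nii.gz")
            paths[fsl] = str(spath.relative_to(out))
        series_paths.append(json.dumps({str(int(k)): v
                                        for k, v in sorted(paths.items())}))
    if cohort.measurements:
        study["roi_mask"] = mask_paths
        study["series_files"] = series_paths
    study.to_csv(out / "study_table.csv", index=False)
    cohort.truth_table.to_csv(out / "ground_truth.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tsl_ms: list[float] = list(SpinLockProtocol().tsl_ms)
    fsl_hz: list[float] = list(SpinLockProtocol().fsl_hz)
    tau_ms: float = 2000.0
    te_ms: float = 4.59
    n_slices: int = 10
    slice_thickness_mm: float = 1.0
    slice_gap_mm: float = 0.2


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mice: list[str] | None = None   # None: full default schedule
    weeks: list[int] | None = None
    tumour_model: str = "delta"
    brain_tumour_corr: float = 0.5
    cross_fsl_corr: float = 0.5
    s0: float = 100.0
    snr: float | None = 50.0
    noise_model: str = "rician"
    sat_model: str = "msat"


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t1rho_bounds_ms: tuple[float, float] = (1.0, 2000.0)
    tol: float = 1e-8
    r2_threshold: float = 0.5


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fdr: float = 0.05
    dispersion_alpha: float = 0.05
    pooled_weeks: list[int] = [2, 3, 4]


class StudyConfig(BaseModel):
    """Validated end-to-end pipeline configuration."""

    model_config = ConfigDict(extra="forbid")
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    correction_on: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def spin_lock_protocol(self) -> SpinLockProtocol:
        p = self.protocol
        return SpinLockProtocol(tsl_ms=tuple(p.tsl_ms), fsl_hz=tuple(p.fsl_hz),
                                tau_ms=p.tau_ms, te_ms=p.te_ms,
                                n_slices=p.n_slices,
                                slice_thickness_mm=p.slice_thickness_mm,
                                slice_gap_mm=p.slice_gap_mm)

    def cohort_design(self):
        from .phantom import CohortDesign
        c = self.cohort
        design = CohortDesign(protocol=self.spin_lock_protocol(),
                              tumour_model=c.tumour_model,
                              brain_tumour_corr=c.brain_tumour_corr,
                              cross_fsl_corr=c.cross_fsl_corr, s0=c.s0,
                              snr=c.snr, noise_model=c.noise_model,
                              sat_model=c.sat_model)
        if c.mice is not None or c.weeks is not None:
            design = design.subset(
                mice=None if c.mice is None else set(c.mice),
                weeks=None if c.weeks is None else set(c.weeks))
        return design


def config_hash(config: StudyConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of a config."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
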