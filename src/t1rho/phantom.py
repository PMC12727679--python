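"""Digital mouse-brain phantoms and synthetic spin-lock cohorts.

The phantom is deliberately minimal: an ellipsoidal "brain" of healthy
tissue centred in the FOV and, optionally, a spherical tumour implanted
just right of the midline, mimicking an intracranial injection into the
right cerebral cortex.  Voxels are labelled by voxel-centre inclusion.
Each tissue class carries a :class:`~t1rho.relaxation.TissueRelaxation`
(T1, T2, per-FSL T1rho, S0).

The signal model for a multislice spin-lock series is

    S(TSL) = S0 * f_sat(TSL) * exp(-TSL / T1rho(FSL)),

where ``f_sat`` is the steady-state saturation factor Mz/M0 (the default
``sat_model="msat"``, exactly invertible by the correction in
:mod:`t1rho.relaxation`) or a variant in which the spin-lock decay itself,
``exp(-TSL/T1rho)``, drives the saturation (``sat_model="t1rho_decay"``,
used to probe the bias of the correction when its assumed saturation
mechanism is wrong).  Magnitude noise is Rician: independent Gaussian
noise of standard deviation sigma on both quadrature channels; the SNR of
a series is defined as ``S0 / sigma``.

:func:`generate_cohort` draws whole cohorts.  Per measurement (mouse-week)
and FSL, a brain T1rho is drawn from the group's per-FSL distribution; for
tumour-bearing measurements the tumour value is derived by default from a
drawn per-measurement tumour-vs-brain percent difference (the "delta"
model, so the cohort's delta distribution matches its configured mean/SD
exactly in expectation), or from a correlated bivariate normal on the
brain/tumour distributions (``tumour_model="bivariate"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import studyparams as sp
from .errors import GeometryError, InvalidParameterError
from .grid import GridSpec, anatomical_grid, t1rho_grid
from .protocol import SpinLockProtocol
from .relaxation import TissueRelaxation, mz_over_m0
from .series import SpinLockSeries

BACKGROUND, BRAIN, TUMOUR = 0, 1, 2
LABEL_IDS = {"brain": BRAIN, "tumour": TUMOUR}

DEFAULT_BRAIN_SEMIAXES_MM = (2.4, 2.4, 7.2)
DEFAULT_TUMOUR_CENTER_MM = (1.0, 0.0, 0.0)
DEFAULT_S0 = 100.0
DEFAULT_SNR = 50.0
#: default tumour radius (mm) per study week; sizes put per-slice tumour
#: areas inside the observed 13 +/- 10 mm^2 range while staying inside the
#: small healthy-tissue ellipsoid
TUMOUR_RADIUS_BY_WEEK_MM = {1: 1.0, 2: 1.1, 3: 1.25, 4: 1.35}


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + tissue parameters + noise level of one phantom."""

    grid: GridSpec
    brain_semiaxes_mm: tuple[float, float, float] = DEFAULT_BRAIN_SEMIAXES_MM
    tumour_center_mm: tuple[float, float, float] = DEFAULT_TUMOUR_CENTER_MM
    tumour_radius_mm: float = 0.0
    tissue_params: Mapping[str, TissueRelaxation] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.brain_semiaxes_mm) <= 0:
            raise InvalidParameterError("brain semi-axes must be positive")
        if self.tumour_radius_mm < 0:
            raise InvalidParameterError("tumour radius cannot be negative")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise sigma cannot be negative")


@dataclass
class GroundTruthVolume:
    """Voxelwise labels and true relaxation parameters of a phantom."""

    label_map: np.ndarray
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    t1rho_ms_by_fsl: dict[float, np.ndarray]
    s0: np.ndarray
    grid: GridSpec


def build_phantom(spec: PhantomSpec) -> GroundTruthVolume:
    """Rasterise a phantom spec into labels and parameter volumes.

    Voxels are classified by the position of their centre; the tumour must
    lie inside the brain at voxel resolution (every tumour voxel centre
    inside the ellipsoid), otherwise a :class:`GeometryError` is raised.
    A radius of zero means no tumour.
    """
    x, y, z = spec.grid.meshgrid()
    ax, ay, az = spec.brain_semiaxes_mm
    in_brain = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0

    labels = np.where(in_brain, BRAIN, BACKGROUND).astype(np.int16)
    if spec.tumour_radius_mm > 0:
        cx, cy, cz = spec.tumour_center_mm
        in_tum = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
                  <= spec.tumour_radius_mm ** 2)
        if np.any(in_tum & ~in_brain):
            raise GeometryError("tumour extends outside the brain")
        labels[in_tum] = TUMOUR

    return ground_truth_from_labels(labels, spec.grid, spec.tissue_params)


def ground_truth_from_labels(labels: np.ndarray, grid: GridSpec,
                             tissue_params: Mapping[str, TissueRelaxation],
                             ) -> GroundTruthVolume:
    """Assemble a ground-truth volume from an existing label map."""
    shape = grid.shape
    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    s0 = np.zeros(shape)
    fsls: set[float] = set()
    for params in tissue_params.values():
        fsls.update(params.t1rho_by_fsl_ms)
    t1rho = {f: np.zeros(shape) for f in sorted(fsls)}
    for name, label_id in LABEL_IDS.items():
        mask = labels == label_id
        if not mask.any():
            continue
        if name not in tissue_params:
            raise InvalidParameterError(f"no tissue parameters for {name!r}")
        p = tissue_params[name]
        t1[mask], t2[mask], s0[mask] = p.t1_ms, p.t2_ms, p.s0
        for f, v in p.t1rho_by_fsl_ms.items():
            t1rho[f][mask] = v
    return GroundTruthVolume(np.asarray(labels, dtype=np.int16), t1, t2,
                             t1rho, s0, grid)


def label_areas_mm2(labels: np.ndarray, grid: GridSpec, label_id: int) -> np.ndarray:
    """Per-slice area (mm^2) covered by a label."""
    return (labels == label_id).sum(axis=(0, 1)) * grid.pixel_area_mm2


def roi_masks_from_labels(labels: np.ndarray, grid: GridSpec,
                          midline_margin_mm: float = 0.3) -> np.ndarray:
    """Derive analysis ROIs from a phantom label map.

    The tumour ROI is the tumour label itself; the healthy-brain ROI is
    the contralateral (left, x < -margin) part of the brain label,
    mimicking a manually drawn region of healthy tissue opposite the
    implantation site.  Returns a label volume with the ROI ids of
    :data:`LABEL_IDS`.
    """
    x = grid.x_centers()[:, None, None]
    roi = np.zeros_like(labels)
    roi[(labels == BRAIN) & (x < -midline_margin_mm)] = BRAIN
    roi[labels == TUMOUR] = TUMOUR
    return roi


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

def simulate_series(gt: GroundTruthVolume, protocol: SpinLockProtocol,
                    fsl_hz: float, noise_model: str = "rician",
                    sat_model: str = "msat", sigma: float = 0.0,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> SpinLockSeries:
    """Simulate the observed magnitude series at one spin-lock amplitude.

    The noiseless signal is ``S0 * f_sat(TSL) * exp(-TSL/T1rho(fsl))``;
    background voxels (S0 = 0) are exactly zero before noise.  Identical
    ``seed`` (or an rng in an identical state) yields identical output.
    """
    if fsl_hz not in gt.t1rho_ms_by_fsl:
        raise KeyError(f"no ground-truth T1rho for FSL {fsl_hz} Hz")
    if sigma < 0:
        raise InvalidParameterError("noise sigma cannot be negative")
    if noise_model not in ("rician", "gaussian", "none"):
        raise InvalidParameterError(f"unknown noise model {noise_model!r}")
    if sat_model not in ("msat", "t1rho_decay"):
        raise InvalidParameterError(f"unknown saturation model {sat_model!r}")

    tsl = protocol.tsl_array()
    t1rho = gt.t1rho_ms_by_fsl[fsl_hz]
    fg = gt.label_map != BACKGROUND

    shape = gt.grid.shape + (tsl.size,)
    mean = np.zeros(shape)
    if fg.any():
        t1 = gt.t1_ms[fg][:, None]
        t1r = t1rho[fg][:, None]
        decay = np.exp(-tsl[None, :] / t1r)
        e1 = np.exp(-protocol.tau_ms / t1)
        if sat_model == "msat":
            t2r = 2.0 * gt.t1_ms[fg] * gt.t2_ms[fg] / (gt.t1_ms[fg] + gt.t2_ms[fg])
            msat = np.exp(-tsl[None, :] / t2r[:, None])
        else:  # spin-lock decay itself drives the saturation
            msat = decay
        fsat = msat * (1.0 - e1) / (1.0 - msat * e1)
        mean[fg] = gt.s0[fg][:, None] * fsat * decay

    if noise_model == "none" or sigma == 0.0:
        data = mean
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            data = np.clip(mean + sigma * rng.standard_normal(shape), 0.0, None)
        else:
            data = np.hypot(mean + sigma * rng.standard_normal(shape),
                            sigma * rng.standard_normal(shape))
    return SpinLockSeries(data=data, fsl_hz=fsl_hz, protocol=protocol,
                          grid=gt.grid)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic cohort.

    ``schedule`` lists (mouse_id, group, week, has_tumour) imaging
    sessions; the default reproduces the study's pooled weeks-2-4
    tumour/brain measurement counts of 0/15, 9/14 and 7/12 for the naive,
    wild-type and mutant groups.  Group distributions default to the
    study's group-average tables.  ``cross_fsl_corr`` is the correlation
    of a measurement's draws across FSLs; ``brain_tumour_corr`` is used by
    the bivariate tumour model.  ``weekly_drift_ms`` optionally adds a
    linear per-week shift of the brain T1rho mean per group (off by
    default).
    """

    schedule: tuple[tuple[str, int, int, bool], ...] = sp.DEFAULT_SCHEDULE
    protocol: SpinLockProtocol = SpinLockProtocol()
    brain_t1rho: Mapping[int, Mapping[float, tuple[float, float]]] = field(
        default_factory=lambda: sp.BRAIN_T1RHO_MS)
    tumour_t1rho: Mapping[int, Mapping[float, tuple[float, float]]] = field(
        default_factory=lambda: sp.TUMOUR_T1RHO_MS)
    delta_t1rho: Mapping[int, Mapping[float, tuple[float, float]]] = field(
        default_factory=lambda: sp.DELTA_T1RHO_PCT)
    t1_t2: Mapping[int, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: sp.T1_T2_MS)
    tumour_model: str = "delta"  # or "bivariate"
    brain_tumour_corr: float = 0.5
    cross_fsl_corr: float = 0.5
    s0: float = DEFAULT_S0
    snr: float | None = DEFAULT_SNR
    sat_model: str = "msat"
    noise_model: str = "rician"
    weekly_drift_ms: Mapping[int, float] = field(default_factory=dict)
    anat_grid: GridSpec = anatomical_grid()
    map_grid: GridSpec = t1rho_grid()

    def __post_init__(self) -> None:
        if self.tumour_model not in ("delta", "bivariate"):
            raise InvalidParameterError(f"unknown tumour model {self.tumour_model!r}")
        for corr in (self.brain_tumour_corr, self.cross_fsl_corr):
            if not 0.0 <= corr <= 1.0:
                raise InvalidParameterError("correlations must be in [0, 1]")
        for mouse, group, week, has_tumour in self.schedule:
            if group == 1 and has_tumour:
                raise InvalidParameterError("naive group cannot bear tumours")

    @property
    def noise_sigma(self) -> float:
        return 0.0 if self.snr is None else self.s0 / self.snr

    def subset(self, mice: set[str] | None = None, weeks: set[int] | None = None,
               fsls: tuple[float, ...] | None = None) -> "CohortDesign":
        """Restricted copy of the design (smaller cohorts for quick runs)."""
        sched = tuple(r for r in self.schedule
                      if (mice is None or r[0] in mice)
                      and (weeks is None or r[2] in weeks))
        proto = self.protocol if fsls is None else replace(self.protocol, fsl_hz=fsls)
        return replace(self, schedule=sched, protocol=proto)


@dataclass
class Measurement:
    """One simulated imaging session of one mouse."""

    mouse: str
    group: int
    week: int
    has_tumour: bool
    truth: GroundTruthVolume
    anat_labels: np.ndarray
    roi_labels: np.ndarray
    series: dict[float, SpinLockSeries]
    true_t1rho: dict[str, dict[float, float]]
    true_delta: dict[float, float]


@dataclass
class Cohort:
    """A generated cohort: study table, ground-truth table, measurements."""

    design: CohortDesign
    study_table: pd.DataFrame
    truth_table: pd.DataFrame
    measurements: list[Measurement]


def _correlated_draws(rng: np.random.Generator, n_fsl: int, kappa: float) -> np.ndarray:
    """Standard-normal draws for one measurement, correlated kappa across FSLs."""
    shared = rng.standard_normal()
    own = rng.standard_normal(n_fsl)
    return np.sqrt(kappa) * shared + np.sqrt(1.0 - kappa) * own


def _draw_measurement_t1rho(rng: np.random.Generator, design: CohortDesign,
                            group: int, week: int, has_tumour: bool,
                            ) -> tuple[dict[float, float], dict[float, float],
                                       dict[float, float]]:
    """Draw per-FSL ground-truth brain/tumour T1rho for one session."""
    fsls = design.protocol.fsl_hz
    kappa = design.cross_fsl_corr
    drift = design.weekly_drift_ms.get(group, 0.0) * (week - 2)
    zb = _correlated_draws(rng, len(fsls), kappa)
    brain: dict[float, float] = {}
    tumour: dict[float, float] = {}
    delta: dict[float, float] = {}
    if design.tumour_model == "bivariate" and has_tumour:
        rho = design.brain_tumour_corr
        zt = rho * zb + np.sqrt(1.0 - rho ** 2) * _correlated_draws(
            rng, len(fsls), kappa)
    else:
        # delta model: the percent difference is its own random quantity
        zd = _correlated_draws(rng, len(fsls), kappa) if has_tumour else None
    for i, f in enumerate(fsls):
        mb, sb = design.brain_t1rho[group][f]
        b = max(mb + drift + sb * zb[i], 20.0)
        brain[f] = b
        if has_tumour:
            if design.tumour_model == "bivariate":
                mt, st = design.tumour_t1rho[group][f]
                t = max(mt + drift + st * zt[i], 20.0)
            else:
                md, sd_ = design.delta_t1rho[group][f]
                d = max(md + sd_ * zd[i], -90.0)
                t = b * (1.0 + d / 100.0)
            tumour[f] = t
            delta[f] = 100.0 * (t - b) / b
    return brain, tumour, delta


def _tumour_radius(rng: np.random.Generator, week: int) -> float:
    base = TUMOUR_RADIUS_BY_WEEK_MM.get(week, 1.25)
    return base + rng.uniform(-0.05, 0.05)


def generate_cohort(design: CohortDesign | None = None,
                    out_dir: str | Path | None = None,
                    seed: int = 0, imaging: bool = True) -> Cohort:
    """Simulate a whole cohort.

    Per scheduled session, draws ground-truth tissue T1rho values, and
    (when ``imaging``) builds the phantom on the spin-lock grid, simulates
    the series at every FSL, and derives ROI masks on the anatomical grid.
    With ``imaging=False`` only the ground-truth measurement table is
    produced (fast path for statistical replication studies).  Writing to
    ``out_dir`` is handled by :mod:`t1rho.io` (imported lazily to keep
    this module free of file I/O).

    Identical ``(design, seed)`` give identical output.
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    proto = design.protocol
    study_rows = []
    truth_rows = []
    measurements: list[Measurement] = []

    for mouse, group, week, has_tumour in design.schedule:
        brain_t, tumour_t, delta_t = _draw_measurement_t1rho(
            rng, design, group, week, has_tumour)
        radius = _tumour_radius(rng, week) if has_tumour else 0.0
        study_rows.append(dict(mouse=mouse, group=group, week=week,
                               has_tumour=has_tumour))
        for f in proto.fsl_hz:
            truth_rows.append(dict(mouse=mouse, group=group, week=week, fsl=f,
                                   roi="brain", metric="t1rho", value=brain_t[f]))
            if has_tumour:
                truth_rows.append(dict(mouse=mouse, group=group, week=week,
                                       fsl=f, roi="tumour", metric="t1rho",
                                       value=tumour_t[f]))
                truth_rows.append(dict(mouse=mouse, group=group, week=week,
                                       fsl=f, roi="tumour", metric="delta",
                                       value=delta_t[f]))
        if not imaging:
            continue

        tissue = {"brain": TissueRelaxation(*design.t1_t2[group]["brain"],
                                            t1rho_by_fsl_ms=brain_t, s0=design.s0)}
        if has_tumour:
            tissue["tumour"] = TissueRelaxation(*design.t1_t2[group]["tumour"],
                                                t1rho_by_fsl_ms=tumour_t,
                                                s0=design.s0)
        # rasterise once on the fine anatomical grid; the coarse-grid tissue
        # class of a voxel is then defined by the same >=50% area-majority
        # rule used to transfer ROIs, so ROI assignment and true class agree
        from .roi import RoiMask, resample_mask
        spec_anat = PhantomSpec(grid=design.anat_grid,
                                tumour_radius_mm=radius, tissue_params=tissue,
                                noise_sigma=design.noise_sigma)
        anat_labels = build_phantom(spec_anat).label_map
        map_labels = resample_mask(RoiMask(anat_labels, design.anat_grid),
                                   design.map_grid).labels
        gt = ground_truth_from_labels(map_labels, design.map_grid, tissue)
        roi_labels = roi_masks_from_labels(anat_labels, design.anat_grid)
        series = {f: simulate_series(gt, proto, f, design.noise_model,
                                     design.sat_model, design.noise_sigma,
                                     rng=rng)
                  for f in proto.fsl_hz}
        measurements.append(Measurement(
            mouse=mouse, group=group, week=week, has_tumour=has_tumour,
            truth=gt, anat_labels=anat_labels, roi_labels=roi_labels,
            series=series,
            true_t1rho={"brain": brain_t, "tumour": tumour_t},
            true_delta=delta_t))

    cohort = Cohort(design=design,
                    study_table=pd.DataFrame(study_rows,
                                             columns=["mouse", "group", "week",
                                                      "has_tumour"]),
                    truth_table=pd.DataFrame(truth_rows,
                                             columns=["mouse", "group", "week",
                                                      "fsl", "roi", "metric",
                                                      "value"]),
                    measurements=measurements)
    if out_dir is not None:
        from .io import write_cohort
        write_cohort(cohort, out_dir)
    return cohort


def default_cohort_design() -> CohortDesign:
    """The study's default cohort design."""
    return CohortDesign()
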