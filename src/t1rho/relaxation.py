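"""Rotating-frame relaxation math: saturation correction and T1rho fitting.

In a multislice spin-lock acquisition with a recovery delay tau comparable
to T1, the longitudinal magnetisation available to each slice is reduced by
the spin-lock preparation of the preceding slices.  At steady state the
residual fraction is

    Mz / M0 = Msat * (1 - exp(-tau/T1)) / (1 - Msat * exp(-tau/T1)),

where ``Msat = exp(-TSL / T2rho,eff)`` and the effective relaxation time
during the (averaged) preparation obeys

    1 / T2rho,eff = (1/2) * (1/T1 + 1/T2).

Dividing the measured signal at each TSL by Mz/M0 restores the ideal
monoexponential decay

    S(TSL) = S0 * exp(-TSL / T1rho),

whose two free parameters (S0, T1rho) are estimated per voxel by bounded
least squares.  :func:`fit_monoexponential` fits a single decay curve with
a trust-region solver initialised from the closed-form log-linear fit;
:func:`fit_map` fits whole volumes using variable projection (S0 has a
closed-form optimum given T1rho, leaving a 1-D profiled sum of squares that
is bracketed on a log grid and refined by golden-section search, fully
vectorised over voxels).  Both solve the same least-squares problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidParameterError,
)
from .grid import GridSpec
from .series import SpinLockSeries

DEFAULT_T1RHO_BOUNDS_MS: tuple[float, float] = (1.0, 2000.0)
DEFAULT_R2_THRESHOLD: float = 0.5
DEFAULT_FIT_TOL: float = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueRelaxation:
    """Relaxation parameters of one tissue class.

    ``t1rho_by_fsl`` maps spin-lock amplitude (Hz) to the rotating-frame
    relaxation time (ms) at that amplitude; ``s0`` is the equilibrium
    signal amplitude in arbitrary units.
    """

    t1_ms: float
    t2_ms: float
    t1rho_by_fsl_ms: Mapping[float, float] = field(default_factory=dict)
    s0: float = 100.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise InvalidParameterError("T1 and T2 must be positive")
        if self.t2_ms > self.t1_ms:
            raise InvalidParameterError("T2 cannot exceed T1")
        if self.s0 <= 0:
            raise InvalidParameterError("S0 must be positive")
        if any(v <= 0 for v in self.t1rho_by_fsl_ms.values()):
            raise InvalidParameterError("all T1rho values must be positive")


@dataclass(frozen=True)
class CorrectionFactor:
    """Steady-state saturation factors at one TSL.

    ``msat`` is the residual transverse-prepared fraction after the
    spin-lock pulse; ``mz_over_m0`` is the longitudinal fraction available
    at steady state, i.e. the factor the measured signal must be divided by.
    """

    t2rho_eff_ms: float
    msat: float
    mz_over_m0: float


@dataclass
class DecayCurve:
    """Signal magnitudes sampled at a set of spin-lock durations."""

    tsl_ms: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.tsl_ms = np.asarray(self.tsl_ms, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.tsl_ms.ndim != 1 or self.tsl_ms.shape != self.signal.shape:
            raise InvalidParameterError("tsl and signal must be 1-D and equal length")
        if np.any(np.diff(self.tsl_ms) <= 0):
            raise InvalidParameterError("TSLs must be strictly increasing")
        if np.any(self.signal < 0):
            raise InvalidParameterError("signals must be non-negative")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a monoexponential fit for a single voxel/curve."""

    s0_hat: float
    t1rho_hat_ms: float
    r_squared: float
    converged: bool
    at_bound: bool = False
    message: str = ""


@dataclass
class T1rhoMap:
    """Voxelwise T1rho fit over a volume at one spin-lock amplitude.

    Voxels that were not fitted, failed to converge, or failed quality
    control are NaN in ``t1rho_ms``; ``converged`` and ``r_squared`` retain
    their raw diagnostics.
    """

    t1rho_ms: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    converged: np.ndarray
    fsl_hz: float
    grid: GridSpec
    n_fitted: int = 0
    n_failed_qc: int = 0


# ---------------------------------------------------------------------------
# correction factors
# ---------------------------------------------------------------------------

def t2rho_effective(t1_ms: float, t2_ms: float):
    """Effective relaxation time governing saturation during spin-lock prep.

    Harmonic-mean form ``T2rho,eff = 2 * T1 * T2 / (T1 + T2)``; symmetric in
    its arguments and bounded by ``[min(T1,T2), 2*min(T1,T2)]``.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    t2 = np.asarray(t2_ms, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise InvalidParameterError("T1 and T2 must be positive")
    out = 2.0 * t1 * t2 / (t1 + t2)
    return float(out) if out.ndim == 0 else out


def saturation_factor(t1_ms: float, t2_ms: float, tsl_ms, tau_ms: float):
    """Steady-state saturation correction at one or more TSLs.

    Returns a :class:`CorrectionFactor` (scalar ``tsl_ms``) or an array of
    ``mz_over_m0`` packed into a CorrectionFactor with vector fields.
    ``mz_over_m0`` decreases with TSL (more saturation) and increases with
    tau (more recovery); as TSL -> 0 or tau >> T1 it approaches 1 and Msat
    respectively.
    """
    tsl = np.asarray(tsl_ms, dtype=float)
    if np.any(tsl <= 0):
        raise InvalidParameterError("TSL must be positive")
    if tau_ms <= 0:
        raise InvalidParameterError("tau must be positive")
    t2r = t2rho_effective(t1_ms, t2_ms)
    msat = np.exp(-tsl / t2r)
    e1 = np.exp(-tau_ms / np.asarray(t1_ms, dtype=float))
    mz = msat * (1.0 - e1) / (1.0 - msat * e1)
    if tsl.ndim == 0:
        return CorrectionFactor(float(t2r), float(msat), float(mz))
    return CorrectionFactor(float(t2r), msat, mz)


def mz_over_m0(t1_ms, t2_ms, tsl_ms, tau_ms: float):
    """Convenience: the ``Mz/M0`` factor(s) only, vectorised over inputs."""
    return saturation_factor(t1_ms, t2_ms, tsl_ms, tau_ms).mz_over_m0


def correct_series(curve: DecayCurve, t1_ms: float, t2_ms: float,
                   tau_ms: float) -> DecayCurve:
    """Divide each signal by its steady-state saturation factor.

    On data generated with the same forward model this exactly restores the
    pure monoexponential decay ``S0 * exp(-TSL/T1rho)``.
    """
    factors = mz_over_m0(t1_ms, t2_ms, curve.tsl_ms, tau_ms)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise InvalidParameterError("degenerate correction factor")
    return DecayCurve(curve.tsl_ms.copy(), curve.signal / factors)


# ---------------------------------------------------------------------------
# single-curve fit
# ---------------------------------------------------------------------------

def _loglinear_init(tsl: np.ndarray, sig: np.ndarray,
                    bounds: tuple[float, float]) -> tuple[float, float]:
    """Closed-form log-linear estimate of (S0, T1rho), clipped to bounds."""
    pos = sig > 0
    lo, hi = bounds
    if pos.sum() >= 2 and len(np.unique(tsl[pos])) >= 2:
        slope, intercept = np.polyfit(tsl[pos], np.log(sig[pos]), 1)
        t0 = -1.0 / slope if slope < 0 else hi
        s0 = float(np.exp(intercept))
    else:
        t0, s0 = np.sqrt(lo * hi), float(max(sig.max(), 1e-12))
    return s0, float(np.clip(t0, lo, hi))


def fit_monoexponential(curve: DecayCurve,
                        t1rho_bounds_ms: tuple[float, float] = DEFAULT_T1RHO_BOUNDS_MS,
                        tol: float = DEFAULT_FIT_TOL) -> FitResult:
    """Least-squares fit of ``S0 * exp(-TSL/T1rho)`` to one decay curve.

    Bounded trust-region least squares, initialised from the closed-form
    log-linear fit.  Signals are normalised by their maximum internally so
    the fit is scale-equivariant: scaling the signal scales ``s0_hat`` and
    leaves ``t1rho_hat_ms`` unchanged.  Non-convergence or a boundary
    solution is reported through ``converged`` / ``at_bound`` rather than
    raised.
    """
    tsl, sig = curve.tsl_ms, curve.signal
    if tsl.size < 3:
        raise InsufficientDataError("need at least 3 samples")
    if len(np.unique(tsl)) < 2:
        raise InsufficientDataError("need at least 2 distinct TSLs")
    if not np.any(sig > 0):
        raise InsufficientDataError("signals are all zero")
    lo, hi = t1rho_bounds_ms
    if not (0 < lo < hi):
        raise InvalidParameterError("bad T1rho bounds")

    scale = float(sig.max())
    y = sig / scale
    s0_init, t_init = _loglinear_init(tsl, y, (lo, hi))
    s0_hi = 10.0  # 10x the (normalised) max signal
    x0 = np.array([float(np.clip(s0_init, 1e-12, s0_hi)), t_init])

    def resid(p):
        return p[0] * np.exp(-tsl / p[1]) - y

    def jac(p):
        e = np.exp(-tsl / p[1])
        return np.column_stack([e, p[0] * e * tsl / p[1] ** 2])

    sol = least_squares(resid, x0, jac=jac, bounds=([0.0, lo], [s0_hi, hi]),
                        method="trf", xtol=tol, ftol=tol, gtol=tol, max_nfev=200)
    s0_hat, t_hat = sol.x
    res = resid(sol.x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res ** 2)) / sst if sst > 0 else np.nan
    span = hi - lo
    at_bound = bool(t_hat - lo < 1e-9 * span or hi - t_hat < 1e-9 * span)
    return FitResult(
        s0_hat=float(s0_hat * scale),
        t1rho_hat_ms=float(t_hat),
        r_squared=r2,
        converged=bool(sol.success) and not at_bound,
        at_bound=at_bound,
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# vectorised volume fit (variable projection)
# ---------------------------------------------------------------------------

def _profiled_sse(tsl: np.ndarray, y: np.ndarray, t: np.ndarray,
                  s0_hi: float) -> tuple[np.ndarray, np.ndarray]:
    """SSE and optimal S0 at candidate T1rho values.

    ``y``: (V, n) signals; ``t``: (V,) candidate T1rho per voxel.  For fixed
    T the model is linear in S0, so ``S0* = <y, e> / <e, e>`` with
    ``e = exp(-TSL/T)``, clipped to ``[0, s0_hi]``.
    """
    e = np.exp(-tsl[None, :] / t[:, None])
    num = np.einsum("vn,vn->v", y, e)
    den = np.einsum("vn,vn->v", e, e)
    s0 = np.clip(num / den, 0.0, s0_hi)
    sse = np.einsum("vn,vn->v", y, y) - 2.0 * s0 * num + s0 ** 2 * den
    return sse, s0


def _fit_curves_vectorised(tsl: np.ndarray, y: np.ndarray,
                           t1rho_bounds_ms: tuple[float, float],
                           n_grid: int = 60, n_golden: int = 60,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``S0 * exp(-TSL/T)`` to every row of ``y`` (V, n).

    Variable projection reduces the problem to minimising the profiled SSE
    over T alone; a log-spaced grid scan brackets the minimum and
    golden-section search refines it far below any tolerance of interest.
    Returns (t1rho, s0, r_squared, at_bound).
    """
    lo, hi = t1rho_bounds_ms
    scale = y.max(axis=1)
    ok = scale > 0
    ys = np.where(ok[:, None], y / np.where(ok, scale, 1.0)[:, None], 0.0)
    s0_hi = 10.0

    grid = np.geomspace(lo, hi, n_grid)
    sse_grid = np.empty((y.shape[0], n_grid))
    for j, tj in enumerate(grid):
        sse_grid[:, j], _ = _profiled_sse(tsl, ys, np.full(y.shape[0], tj), s0_hi)
    best = np.argmin(sse_grid, axis=1)
    a = grid[np.maximum(best - 1, 0)]
    b = grid[np.minimum(best + 1, n_grid - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, _ = _profiled_sse(tsl, ys, c, s0_hi)
    fd, _ = _profiled_sse(tsl, ys, d, s0_hi)
    for _ in range(n_golden):
        left = fc < fd  # minimum is in [a, d]; else in [c, b]
        a = np.where(left, a, c)
        b = np.where(left, d, b)
        new_pt = np.where(left, b - invphi * (b - a), a + invphi * (b - a))
        f_new, _ = _profiled_sse(tsl, ys, new_pt, s0_hi)
        c, d, fc, fd = (np.where(left, new_pt, d), np.where(left, c, new_pt),
                        np.where(left, f_new, fd), np.where(left, fc, f_new))
    t_hat = 0.5 * (a + b)
    sse, s0n = _profiled_sse(tsl, ys, t_hat, s0_hi)

    sst = np.sum((ys - ys.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
    span = hi - lo
    at_bound = (t_hat - lo < 1e-6 * span) | (hi - t_hat < 1e-6 * span)
    t_hat = np.where(ok, t_hat, np.nan)
    r2 = np.where(ok, r2, np.nan)
    at_bound = at_bound | ~ok
    return t_hat, s0n * scale, r2, at_bound


def fit_map(series: SpinLockSeries,
            t1_by_class: Mapping[str, float],
            t2_by_class: Mapping[str, float],
            mask_by_class: Mapping[str, np.ndarray],
            tau_ms: float | None = None,
            correction_on: bool = True,
            t1rho_bounds_ms: tuple[float, float] = DEFAULT_T1RHO_BOUNDS_MS,
            r2_threshold: float = DEFAULT_R2_THRESHOLD) -> T1rhoMap:
    """Voxelwise T1rho map from a spin-lock series.

    The steady-state correction is applied per tissue class with a single
    (group-average) T1/T2 per class, mirroring the use of cohort-average
    relaxation times when per-mouse maps are unavailable; pass per-class
    single-voxel masks for a per-voxel correction.  With
    ``correction_on=False`` the raw magnitudes are fitted directly (the
    "uncorrected" analysis mode).  Voxels failing convergence or with
    ``r_squared`` below ``r2_threshold`` are set to NaN in the map.
    """
    tau = series.protocol.tau_ms if tau_ms is None else tau_ms
    tsl = series.protocol.tsl_array()
    shape = series.grid.shape

    occupied = np.zeros(shape, dtype=bool)
    for cls, mask in mask_by_class.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise InvalidParameterError(f"mask for class {cls!r} has wrong shape")
        if np.any(occupied & mask):
            raise InvalidParameterError("class masks overlap; they must partition "
                                        "the fitted region")
        occupied |= mask

    t1rho = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    n_fitted = 0
    n_failed = 0

    for cls, mask in mask_by_class.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            continue
        if correction_on:
            if cls not in t1_by_class or cls not in t2_by_class:
                raise ConfigurationError(f"no T1/T2 configured for class {cls!r}")
            factors = mz_over_m0(t1_by_class[cls], t2_by_class[cls], tsl, tau)
        else:
            factors = np.ones_like(tsl)
        y = series.data[mask] / factors[None, :]
        t_hat, s0_hat, r2_hat, at_bound = _fit_curves_vectorised(
            tsl, y, t1rho_bounds_ms)
        good = ~at_bound & np.isfinite(r2_hat) & (r2_hat >= r2_threshold)
        conv[mask] = ~at_bound
        r2[mask] = r2_hat
        s0[mask] = s0_hat
        t1rho[mask] = np.where(good, t_hat, np.nan)
        n_fitted += int(good.sum())
        n_failed += int((~good).sum())

    return T1rhoMap(t1rho_ms=t1rho, s0=s0, r_squared=r2, converged=conv,
                    fsl_hz=series.fsl_hz, grid=series.grid,
                    n_fitted=n_fitted, n_failed_qc=n_failed)
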