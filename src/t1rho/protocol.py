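"""Spin-lock acquisition protocol constants.

A T1rho-prepped multislice acquisition is described by the sampled
spin-lock durations (TSL, ms), the spin-lock amplitudes (FSL, Hz), the
per-slice recovery delay tau between excitations, and the slice geometry.
The defaults are the study protocol this package simulates: eight TSLs
from 1 to 105 ms, four FSLs from 100 to 2000 Hz, a 2000 ms recovery delay,
and ten interleaved 1 mm axial slices with a 0.2 mm gap.

Because tau is on the order of T1, longitudinal magnetisation does not
fully recover between slice excitations; the steady-state correction in
:mod:`t1rho.relaxation` undoes the resulting saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

DEFAULT_TSL_MS: tuple[float, ...] = (1.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0)
DEFAULT_FSL_HZ: tuple[float, ...] = (100.0, 500.0, 1000.0, 2000.0)
DEFAULT_TAU_MS: float = 2000.0
DEFAULT_TE_MS: float = 4.59


@dataclass(frozen=True)
class SpinLockProtocol:
    """Acquisition constants for a multislice spin-lock series.

    Parameters
    ----------
    tsl_ms:
        Spin-lock durations in ms, strictly increasing, all positive.
    fsl_hz:
        Spin-lock amplitudes in Hz, strictly increasing, all positive.
    tau_ms:
        Recovery delay per slice (ms).
    te_ms:
        Echo time of the readout (metadata only; it does not enter the
        relaxation model).
    """

    tsl_ms: tuple[float, ...] = DEFAULT_TSL_MS
    fsl_hz: tuple[float, ...] = DEFAULT_FSL_HZ
    tau_ms: float = DEFAULT_TAU_MS
    te_ms: float = DEFAULT_TE_MS
    n_slices: int = 10
    slice_thickness_mm: float = 1.0
    slice_gap_mm: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "tsl_ms", tuple(float(t) for t in self.tsl_ms))
        object.__setattr__(self, "fsl_hz", tuple(float(f) for f in self.fsl_hz))
        tsl = np.asarray(self.tsl_ms)
        fsl = np.asarray(self.fsl_hz)
        if tsl.size == 0 or np.any(tsl <= 0) or np.any(np.diff(tsl) <= 0):
            raise InvalidParameterError("TSLs must be positive and strictly increasing")
        if fsl.size == 0 or np.any(fsl <= 0) or np.any(np.diff(fsl) <= 0):
            raise InvalidParameterError("FSLs must be positive and strictly increasing")
        if self.tau_ms <= 0:
            raise InvalidParameterError("tau must be positive")
        if self.n_slices < 1:
            raise InvalidParameterError("need at least one slice")

    @property
    def n_tsl(self) -> int:
        return len(self.tsl_ms)

    @property
    def n_fsl(self) -> int:
        return len(self.fsl_hz)

    def tsl_array(self) -> np.ndarray:
        return np.asarray(self.tsl_ms, dtype=float)
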