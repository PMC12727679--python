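"""In-memory container for an observed 4-D spin-lock image series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .grid import GridSpec
from .protocol import SpinLockProtocol


@dataclass
class SpinLockSeries:
    """Magnitude images over TSL at one spin-lock amplitude.

    ``data`` is indexed ``(row, col, slice, tsl_index)`` — the same axis
    order used when the series is written to NIfTI — and the TSL axis must
    match ``protocol.tsl_ms``.  Magnitude data are non-negative.
    """

    data: np.ndarray
    fsl_hz: float
    protocol: SpinLockProtocol
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidParameterError("series data must be 4-D (x, y, z, tsl)")
        if self.data.shape[:3] != self.grid.shape:
            raise InvalidParameterError(
                f"data shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.data.shape[3] != self.protocol.n_tsl:
            raise InvalidParameterError(
                f"TSL axis has length {self.data.shape[3]}, protocol has "
                f"{self.protocol.n_tsl} TSLs"
            )
        if self.fsl_hz <= 0:
            raise InvalidParameterError("FSL must be positive")
        if np.any(self.data < 0):
            raise InvalidParameterError("magnitude data must be non-negative")
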