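"""CGM time-series container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

GLUCOSE_RANGE = (20.0, 600.0)


@dataclass
class CGMSeries:
    """Sampled sensor glucose.

    ``t`` are times in minutes (strictly increasing), ``g`` glucose in mg/dL,
    ``imputed`` flags samples filled by interpolation rather than measured.
    ``m`` is the nominal sampling interval in minutes; after gap imputation
    the series lies on the regular ``m``-min grid.
    """

    t: np.ndarray
    g: np.ndarray
    imputed: Optional[np.ndarray] = None
    m: int = 5

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.imputed is None:
            self.imputed = np.zeros(self.t.shape, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.t.ndim != 1 or self.t.shape != self.g.shape or self.t.shape != self.imputed.shape:
            raise ValueError("t, g and imputed must be 1-D arrays of equal length")
        if self.t.size == 0:
            raise ValueError("empty CGM series")
        if self.m < 1:
            raise ValueError("sampling interval m must be >= 1 min")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        bad = (self.g < GLUCOSE_RANGE[0]) | (self.g > GLUCOSE_RANGE[1])
        if np.any(bad):
            rows = np.flatnonzero(bad)[:5].tolist()
            raise ValueError(
                f"glucose outside {GLUCOSE_RANGE} mg/dL at sample rows {rows}"
            )

    def __len__(self) -> int:
        return self.t.size

    @property
    def is_regular(self) -> bool:
        return bool(np.all(np.diff(self.t) == self.m))

    def window(self, t_start: float, t_end: float) -> "CGMSeries":
        """Sub-series with ``t_start <= t < t_end``."""
        sel = (self.t >= t_start) & (self.t < t_end)
        if not np.any(sel):
            raise ValueError(f"no samples in window [{t_start}, {t_end})")
        return CGMSeries(self.t[sel], self.g[sel], self.imputed[sel], self.m)
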