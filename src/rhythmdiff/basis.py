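"""Periodic decomposition of time into cosinor covariates.

Cosinor regression represents a rhythm of known period as the first
harmonic of a Fourier series: time ``t`` (hours) maps to the angle
``theta = 2*pi*t / period`` and enters the linear model through
``cos(theta)`` and ``sin(theta)``.  Higher harmonics ``(cos(k*theta),
sin(k*theta))`` can be requested for non-sinusoidal waveforms, and a raw
linear time term can be appended to absorb drift across several cycles in
free-running conditions.

Ordering convention: cosine before sine, harmonics in increasing ``k``,
drift term last.  Downstream hypothesis index sets rely on this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError


@dataclass(frozen=True)
class TimeBasis:
    """Specification of the periodic time decomposition.

    Parameters
    ----------
    period
        Rhythm period in hours (default 24, the circadian/zeitgeber cycle).
    n_harmonics
        Number of Fourier harmonics; 1 gives the plain cosinor pair.
    include_linear_drift
        Append raw time as a final covariate to model linear drift.
    """

    period: float = 24.0
    n_harmonics: int = 1
    include_linear_drift: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.period) and self.period > 0):
            raise ConfigError(f"period must be positive and finite, got {self.period}")
        if int(self.n_harmonics) != self.n_harmonics or self.n_harmonics < 1:
            raise ConfigError(f"n_harmonics must be an integer >= 1, got {self.n_harmonics}")

    @property
    def n_columns(self) -> int:
        return 2 * self.n_harmonics + int(self.include_linear_drift)

    @property
    def column_names(self) -> list[str]:
        names: list[str] = []
        for k in range(1, self.n_harmonics + 1):
            suffix = "" if k == 1 else str(k)
            names += [f"time_cos{suffix}", f"time_sin{suffix}"]
        if self.include_linear_drift:
            names.append("time_linear")
        return names


def decompose_time(t, basis: TimeBasis) -> np.ndarray:
    """Map time(s) in hours onto the periodic basis columns.

    Accepts a scalar or 1-D array; returns an array whose trailing axis has
    ``basis.n_columns`` entries ordered ``[cos(k*theta), sin(k*theta) for
    k=1..n_harmonics]`` (+ raw ``t`` if drift is enabled), with
    ``theta = 2*pi*t / period``.
    """
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("time values must be finite")
    theta = 2.0 * np.pi * arr / basis.period
    cols = []
    for k in range(1, basis.n_harmonics + 1):
        cols.append(np.cos(k * theta))
        cols.append(np.sin(k * theta))
    if basis.include_linear_drift:
        cols.append(arr)
    return np.stack(cols, axis=-1)
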