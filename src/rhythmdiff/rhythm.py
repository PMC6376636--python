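"""Rhythm amplitude and acrophase from first-harmonic cosinor coefficients.

A fitted cosinor pair satisfies the identity

    beta_cos * cos(theta) + beta_sin * sin(theta) = A * cos(theta - theta_peak)

with amplitude ``A = sqrt(beta_cos^2 + beta_sin^2)`` (half the
peak-to-trough of the fitted curve) and acrophase — the clock time of peak
expression — ``(period / 2*pi) * atan2(beta_sin, beta_cos)`` wrapped into
``[0, period)``.  Between-condition changes are the arithmetic amplitude
difference and the circular acrophase difference constrained to
``(-period/2, +period/2]``, signed so that a positive value means the
alternate condition peaks earlier (a phase advance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError


@dataclass
class RhythmParams:
    """Amplitude (log-expression units) and acrophase (hours) of one fitted rhythm.

    A zero-amplitude fit has no defined peak time; its acrophase is set to
    0 by convention and ``defined`` is False.
    """

    amplitude: float
    acrophase: float
    defined: bool = True


def amplitude_acrophase(beta_cos: float, beta_sin: float,
                        period: float = 24.0) -> RhythmParams:
    """Convert a cosinor coefficient pair to amplitude and acrophase."""
    if not period > 0:
        raise DomainError(f"period must be positive, got {period}")
    amplitude = math.hypot(beta_cos, beta_sin)
    if amplitude == 0.0:
        return RhythmParams(0.0, 0.0, defined=False)
    acro = (period / (2.0 * math.pi)) * math.atan2(beta_sin, beta_cos)
    return RhythmParams(amplitude, acro % period)


def wrap_half_period(delta_hours: float, period: float = 24.0) -> float:
    """Wrap an hour difference into the half-open interval ``(-period/2, period/2]``."""
    w = delta_hours % period
    if w > period / 2.0:
        w -= period
    return w


def delta_params(ref: RhythmParams, alt: RhythmParams,
                 period: float = 24.0) -> tuple[Optional[float], Optional[float]]:
    """Between-condition changes: ``(delta_amplitude, delta_acrophase)``.

    ``delta_amplitude = amplitude_alt - amplitude_ref`` (negative = lower
    amplitude in the alternate condition).  ``delta_acrophase`` is
    ``acro_ref - acro_alt`` wrapped to ``(-period/2, period/2]``, so a
    positive value is a phase advance in the alternate condition.  If
    either acrophase is undefined (zero amplitude) the acrophase delta is
    ``None``.
    """
    d_amp = alt.amplitude - ref.amplitude
    if not (ref.defined and alt.defined):
        return d_amp, None
    return d_amp, wrap_half_period(ref.acrophase - alt.acrophase, period)


def amplitude_acrophase_arrays(beta_cos: np.ndarray, beta_sin: np.ndarray,
                               period: float = 24.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized variant: returns (amplitude, acrophase, defined) arrays."""
    if not period > 0:
        raise DomainError(f"period must be positive, got {period}")
    bc = np.asarray(beta_cos, dtype=float)
    bs = np.asarray(beta_sin, dtype=float)
    amp = np.hypot(bc, bs)
    defined = amp > 0
    acro = np.where(defined, (period / (2.0 * np.pi)) * np.arctan2(bs, bc) % period, 0.0)
    return amp, acro, defined
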