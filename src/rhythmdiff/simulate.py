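"""Synthetic two-condition circadian expression datasets with known truth.

The generator emulates a standard entrained time-course experiment: 2
replicates drawn every 2 h for 24 h (time points 0-22 h) from each of 2
conditions, 48 samples in all.  Each dataset holds 10,080 genes by
default, 75% non-rhythmic and 25% rhythmic, with a configurable number of
the rhythmic genes differentially rhythmic (DR) between conditions.
Rhythmic expression is a sinusoid of period 24 h; expression is centered
around zero (baseline 0) and noise is additive i.i.d. Gaussian with
standard deviation 1.

A DR gene set is parameterized by its mean amplitude (in units of the
noise SD), an amplitude difference ``delta_amp`` split symmetrically
(+-delta/2) between conditions, and a phase difference ``delta_phase``
(hours) split the same way, with condition 2 peaking earlier when
``delta_phase`` is positive.  ``delta_amp`` may reach at most twice the
mean amplitude, at which point the gene is non-rhythmic in condition 1 and
the phase difference is undefined (``delta_phase=None``).

Truth labels are returned alongside every dataset, enabling ROC/TPR
evaluation without circular dependence on the rhythm detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, SampleMetadata

LABEL_NONRHYTHMIC = "non-rhythmic"
LABEL_RHYTHMIC = "rhythmic"
LABEL_DR = "differentially-rhythmic"


class GridPoint(NamedTuple):
    """One DR parameter combination: (mean amplitude, delta amp, delta phase)."""

    mean_amplitude: float
    delta_amp: float
    delta_phase: Optional[float]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset.

    Defaults reproduce the standard evaluation conditions: 10,080 genes,
    75% non-rhythmic, 504 DR genes, 12 x 2 x 2 sample layout, unit noise.
    """

    n_genes: int = 10080
    frac_nonrhythmic: float = 0.75
    n_dr: int = 504
    mean_amplitude: float = 1.0
    delta_amp: float = 1.0
    delta_phase: Optional[float] = 6.0
    noise_sd: float = 1.0
    baseline: float = 0.0
    period: float = 24.0
    interval_hours: float = 2.0
    n_timepoints: int = 12
    replicates: int = 2
    condition_labels: tuple[str, str] = ("cond1", "cond2")

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_nonrhythmic <= 1.0:
            raise ConfigError("frac_nonrhythmic must lie in [0, 1]")
        if self.n_genes < 1 or self.n_timepoints < 1 or self.replicates < 1:
            raise ConfigError("n_genes, n_timepoints and replicates must be positive")
        if self.noise_sd < 0 or self.mean_amplitude < 0 or self.delta_amp < 0:
            raise ConfigError("noise_sd, mean_amplitude and delta_amp must be non-negative")
        if self.n_dr > self.n_rhythmic:
            raise ConfigError(
                f"n_dr={self.n_dr} exceeds the number of rhythmic genes ({self.n_rhythmic})"
            )
        if self.delta_amp > 2.0 * self.mean_amplitude + 1e-12:
            raise ConfigError("delta_amp may not exceed twice the mean amplitude")
        at_max = math.isclose(self.delta_amp, 2.0 * self.mean_amplitude)
        if self.n_dr > 0:
            if at_max and self.delta_phase is not None:
                raise ConfigError(
                    "at delta_amp = 2 x mean amplitude the gene is non-rhythmic in one "
                    "condition, so delta_phase must be None"
                )
            if not at_max and self.delta_amp == 0.0 and not self.delta_phase:
                raise ConfigError("DR genes must differ between conditions: "
                                  "delta_amp and delta_phase are both zero")

    @property
    def n_nonrhythmic(self) -> int:
        return round(self.n_genes * self.frac_nonrhythmic)

    @property
    def n_rhythmic(self) -> int:
        return self.n_genes - self.n_nonrhythmic

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.interval_hours

    @property
    def n_samples(self) -> int:
        return 2 * self.n_timepoints * self.replicates

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["condition_labels"] = list(self.condition_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        if "condition_labels" in d:
            d["condition_labels"] = tuple(d["condition_labels"])
        return cls(**d)


def _sample_layout(spec: SimulationSpec) -> pd.DataFrame:
    rows = []
    for cond in spec.condition_labels:
        for t in spec.times:
            for rep in range(1, spec.replicates + 1):
                rows.append((f"{cond}_t{int(round(t)):02d}_r{rep}", float(t), cond))
    frame = pd.DataFrame(rows, columns=["sample_id", "time", "condition"])
    return frame.set_index("sample_id")


def generate_dataset(spec: SimulationSpec, seed) -> tuple[ExpressionMatrix,
                                                          SampleMetadata,
                                                          pd.DataFrame]:
    """Simulate one dataset; returns (expression, metadata, truth table).

    The truth table has one row per gene with its class label and the
    per-condition sinusoid parameters (amplitude, peak phase in hours,
    baseline).
    """
    rng = np.random.default_rng(seed)
    layout = _sample_layout(spec)
    n = len(layout)
    n_non, n_rhy, n_dr = spec.n_nonrhythmic, spec.n_rhythmic, spec.n_dr

    digits = len(str(spec.n_genes))
    gene_ids = [f"gene_{i + 1:0{digits}d}" for i in range(spec.n_genes)]
    labels = np.array([LABEL_NONRHYTHMIC] * n_non
                      + [LABEL_RHYTHMIC] * (n_rhy - n_dr)
                      + [LABEL_DR] * n_dr)

    phases = rng.uniform(0.0, spec.period, spec.n_genes)
    amp = np.zeros((spec.n_genes, 2))
    phase = np.tile(phases[:, None], (1, 2))
    rhythmic = labels != LABEL_NONRHYTHMIC
    amp[rhythmic] = spec.mean_amplitude
    dr = labels == LABEL_DR
    if n_dr:
        amp[dr, 0] = spec.mean_amplitude - spec.delta_amp / 2.0
        amp[dr, 1] = spec.mean_amplitude + spec.delta_amp / 2.0
        dphi = spec.delta_phase or 0.0
        phase[dr, 0] = phases[dr] + dphi / 2.0
        phase[dr, 1] = phases[dr] - dphi / 2.0
    phase %= spec.period

    cond_idx = (layout["condition"] == spec.condition_labels[1]).to_numpy().astype(int)
    t = layout["time"].to_numpy()
    amp_gi = amp[:, cond_idx]
    phase_gi = phase[:, cond_idx]
    signal = spec.baseline + amp_gi * np.cos(
        2.0 * np.pi * (t[None, :] - phase_gi) / spec.period)
    values = signal + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))

    expr = ExpressionMatrix(gene_ids, list(layout.index), values)
    meta = SampleMetadata(layout)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "label": labels,
        "amplitude_cond1": amp[:, 0],
        "amplitude_cond2": amp[:, 1],
        "phase_cond1": phase[:, 0],
        "phase_cond2": phase[:, 1],
        "baseline": spec.baseline,
    })
    return expr, meta, truth


def generate_null_dataset(spec: SimulationSpec, seed) -> tuple[ExpressionMatrix,
                                                               SampleMetadata,
                                                               pd.DataFrame]:
    """Simulate a dataset with rhythmic genes but no differential rhythmicity.

    Both conditions share identical per-gene sinusoid parameters; intended
    for type-I-error calibration of the differential-rhythmicity test.
    """
    null_spec = replace(spec, n_dr=0, delta_amp=0.0, delta_phase=0.0)
    return generate_dataset(null_spec, seed)


def default_grid() -> list[GridPoint]:
    """The default sweep of 56 DR parameter combinations (one dataset each).

    At mean amplitude 1 (in units of the noise SD): amplitude differences
    {0, 0.25, ..., 1.75} crossed with phase differences {0, 2, ..., 12} h,
    excluding the no-difference point, plus the boundary combination
    (delta_amp = 2, phase undefined) at which one condition is
    non-rhythmic.  The exact grid is a documented package default and is
    fully overridable.
    """
    a = 1.0
    combos: list[GridPoint] = []
    for damp in np.arange(0.0, 2.0, 0.25):
        for dphase in np.arange(0.0, 14.0, 2.0):
            if damp == 0.0 and dphase == 0.0:
                continue
            combos.append(GridPoint(a, float(damp), float(dphase)))
    combos.append(GridPoint(a, 2.0 * a, None))
    return combos
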