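"""Build numeric design matrices from declarative model specifications.

A :class:`ModelSpec` names the experimental factor of interest (a
categorical indicator such as genotype, or a continuous moderator such as
age), any additional covariates (brain region, subject, ...), the periodic
time basis, and whether the factor interacts with time.  The realized
:class:`DesignMatrix` carries, besides the numeric matrix, the coefficient
index sets for the three hypotheses of interest:

* ``time_indices`` — the periodic time terms (rhythmicity);
* ``factor_indices`` — the factor main effect (differential expression);
* ``interaction_indices`` — factor x time terms (differential rhythmicity).

Row layout per sample: ``[1, factor terms, other covariates, time-basis
terms, factor x time terms]``.  Categorical variables use reference-level
indicator coding with the alphabetically first level as reference, so with
a wild-type/knockout factor the main-effect coefficient is the
knockout-vs-wild-type contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .basis import TimeBasis, decompose_time
from .errors import ConfigError, DesignError
from .io import SampleMetadata

RANK_TOL = 1e-10  # singular-value ratio below which the design is deemed deficient


@dataclass
class ModelSpec:
    """Declarative description of a per-gene linear model."""

    time_basis: TimeBasis = field(default_factory=TimeBasis)
    factor: Optional[str] = None
    other_covariates: Sequence[str] = ()
    interact_factor_with_time: bool = False
    categorical: Sequence[str] = ()  # force these covariates to be treated as categorical
    center_continuous: bool = False

    def __post_init__(self) -> None:
        if self.interact_factor_with_time and self.factor is None:
            raise ConfigError("a factor is required to form a factor x time interaction")

    def to_dict(self) -> dict:
        return {
            "period": self.time_basis.period,
            "n_harmonics": self.time_basis.n_harmonics,
            "include_linear_drift": self.time_basis.include_linear_drift,
            "factor": self.factor,
            "other_covariates": list(self.other_covariates),
            "interact_factor_with_time": self.interact_factor_with_time,
            "categorical": list(self.categorical),
            "center_continuous": self.center_continuous,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        basis = TimeBasis(
            period=d.get("period", 24.0),
            n_harmonics=d.get("n_harmonics", 1),
            include_linear_drift=d.get("include_linear_drift", False),
        )
        return cls(
            time_basis=basis,
            factor=d.get("factor"),
            other_covariates=tuple(d.get("other_covariates", ())),
            interact_factor_with_time=d.get("interact_factor_with_time", False),
            categorical=tuple(d.get("categorical", ())),
            center_continuous=d.get("center_continuous", False),
        )


@dataclass
class DesignMatrix:
    """Realized numeric design with named columns and hypothesis index sets."""

    matrix: np.ndarray  # samples x coefficients
    column_names: list[str]
    sample_ids: list[str]
    time_indices: list[int]
    factor_indices: list[int]
    interaction_indices: list[int]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.column_names)


def _is_categorical(series: pd.Series, name: str, spec: ModelSpec) -> bool:
    if name in spec.categorical:
        return True
    return not pd.api.types.is_numeric_dtype(series)


def _encode(series: pd.Series, name: str, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Encode one covariate as columns; categorical -> L-1 reference-coded indicators."""
    if _is_categorical(series, name, spec):
        levels = sorted(map(str, pd.unique(series.astype(str))))
        if len(levels) < 2:
            raise DesignError(f"covariate {name!r} has a single level {levels!r} "
                              "and is collinear with the intercept")
        cols = np.column_stack([
            (series.astype(str).to_numpy() == lev).astype(float) for lev in levels[1:]
        ])
        return cols, [f"{name}[{lev}]" for lev in levels[1:]]
    vals = series.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ConfigError(f"covariate {name!r} contains missing or non-finite values")
    if np.ptp(vals) == 0:
        raise DesignError(f"covariate {name!r} is constant across samples "
                          "and is collinear with the intercept")
    if spec.center_continuous:
        vals = vals - vals.mean()
    return vals[:, None], [name]


def check_full_rank(matrix: np.ndarray, column_names: Sequence[str]) -> None:
    """Raise :class:`DesignError` naming suspect columns if the design is deficient."""
    sv = np.linalg.svd(matrix, compute_uv=False)
    if sv[-1] < RANK_TOL * sv[0]:
        from scipy.linalg import qr

        _, _, piv = qr(matrix, pivoting=True)
        rank = int(np.sum(sv >= RANK_TOL * sv[0]))
        bad = [column_names[j] for j in piv[rank:]]
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} of {matrix.shape[1]}); "
            f"collinear column(s): {bad}"
        )


def build_design(meta: SampleMetadata, spec: ModelSpec) -> DesignMatrix:
    """Realize a :class:`ModelSpec` against sample metadata.

    Raises :class:`DesignError` if the resulting matrix is rank deficient
    (e.g., a subject term confounded with the factor) and
    :class:`ConfigError` if a named covariate is absent from the metadata.
    """
    n = len(meta.sample_ids)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    factor_idx: list[int] = []
    time_idx: list[int] = []
    inter_idx: list[int] = []

    factor_block = None
    factor_names: list[str] = []
    if spec.factor is not None:
        factor_block, factor_names = _encode(meta.column(spec.factor), spec.factor, spec)
        start = sum(b.shape[1] for b in blocks)
        factor_idx = list(range(start, start + factor_block.shape[1]))
        blocks.append(factor_block)
        names += factor_names

    for cov in spec.other_covariates:
        block, cov_names = _encode(meta.column(cov), cov, spec)
        blocks.append(block)
        names += cov_names

    time_block = decompose_time(meta.time, spec.time_basis)
    start = sum(b.shape[1] for b in blocks)
    time_idx = list(range(start, start + time_block.shape[1]))
    blocks.append(time_block)
    names += spec.time_basis.column_names

    if spec.interact_factor_with_time:
        assert factor_block is not None
        start = sum(b.shape[1] for b in blocks)
        inter_cols = []
        inter_names = []
        for j, fname in enumerate(factor_names):
            for k, tname in enumerate(spec.time_basis.column_names):
                inter_cols.append(factor_block[:, j] * time_block[:, k])
                inter_names.append(f"{fname}:{tname}")
        inter_block = np.column_stack(inter_cols)
        inter_idx = list(range(start, start + inter_block.shape[1]))
        blocks.append(inter_block)
        names += inter_names

    matrix = np.hstack(blocks)
    check_full_rank(matrix, names)
    return DesignMatrix(matrix, names, meta.sample_ids, time_idx, factor_idx, inter_idx)


@dataclass
class WorkflowStep:
    """One analysis step: the model to fit and which coefficient set to test."""

    spec: ModelSpec
    tested: str  # 'time' | 'factor' | 'interaction'


def make_workflow_specs(kind: str, time_basis: TimeBasis, factor: Optional[str] = None,
                        covariates: Sequence[str] = ()) -> dict[str, WorkflowStep]:
    """Return the model specs for the standard three-step workflow.

    ``two_condition``
        Step 1 tests the time terms of the additive model, step 2 the
        factor x time interaction among rhythmic genes, step 3 the factor
        main effect (additive model) among non-differentially-rhythmic
        genes.
    ``continuous_moderator``
        Same shape, with a continuous factor (e.g., age) and optional
        adjustment covariates (e.g., brain region).
    ``time_only_blocked``
        A single rhythmicity step adjusting for a blocking covariate such
        as subject; no factor, hence no interaction or main-effect step.
    """
    if kind == "time_only_blocked":
        spec = ModelSpec(time_basis=time_basis, factor=None,
                         other_covariates=tuple(covariates))
        return {"rhythmicity": WorkflowStep(spec, "time")}
    if kind not in ("two_condition", "continuous_moderator"):
        raise ConfigError(f"unsupported workflow kind {kind!r}")
    if factor is None:
        raise ConfigError(f"workflow kind {kind!r} requires a factor")
    additive = ModelSpec(time_basis=time_basis, factor=factor,
                         other_covariates=tuple(covariates))
    interaction = ModelSpec(time_basis=time_basis, factor=factor,
                            other_covariates=tuple(covariates),
                            interact_factor_with_time=True)
    return {
        "rhythmicity": WorkflowStep(additive, "time"),
        "differential_rhythmicity": WorkflowStep(interaction, "interaction"),
        "differential_expression": WorkflowStep(additive, "factor"),
    }
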