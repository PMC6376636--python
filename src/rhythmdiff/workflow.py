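"""The three-step differential analysis workflow and its permutation null.

Step 1 (rhythmicity) assigns each gene a q-value of being rhythmic in at
least one condition.  For two-condition designs the default detector fits
a cosinor model within each condition and combines the per-condition
moderated-F p-values: the minimum feeds ``q_rhy`` (rhythmic in at least
one condition), the maximum feeds ``q_rhy_max`` (rhythmic in both, the
prerequisite for comparing acrophases).  An externally computed
per-condition p-value table can be slotted in instead, so detectors
operating outside the linear-model family remain usable.

Step 2 (differential rhythmicity) applies the moderated F test to the
factor x time interaction coefficients, restricted to the rhythmic genes.
Step 3 (differential expression) applies the moderated t test to the
factor main effect of the additive model, restricted to genes without
strong evidence of differential rhythmicity (q_DR above cutoff) or for
which differential rhythmicity was not examined (q_rhy above cutoff).

The permutation null re-runs step 2 after shuffling condition labels
within samples sharing a time point, which preserves rhythmic patterns
while destroying genuine between-condition differences; the mean count of
DR genes across permutations estimates the false-positive tendency at each
q-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .basis import TimeBasis
from .design import ModelSpec, build_design
from .errors import ConfigError, DesignError
from .io import ExpressionMatrix, SampleMetadata
from .moderated import GeneFits, estimate_prior, fit_linear_models, moderated_F, moderated_t
from .multitest import PROCEDURE, bh_adjust
from .rhythm import amplitude_acrophase_arrays, wrap_half_period

CLASS_NONRHYTHMIC = "non-rhythmic"
CLASS_RHYTHMIC_ONLY = "rhythmic-only"
CLASS_DR = "differentially-rhythmic"
CLASS_DE = "differentially-expressed"
CLASS_RHYTHMIC_DE = "rhythmic-and-DE"
CLASS_UNTESTED = "untested"


@dataclass
class WorkflowConfig:
    """Cutoffs and knobs for the three-step workflow.

    ``q_rhy=0.01`` suits densely sampled two-condition designs; sparser
    designs typically relax it to 0.1.  The detector is the within-
    condition cosinor moderated F unless an external per-condition p-value
    table is supplied.
    """

    q_rhy: float = 0.01
    q_dr: float = 0.1
    q_de: float = 0.01
    amplitude_cutoff: Optional[float] = None
    detector: str = "cosinor_F"  # or 'external'
    external_p: Optional[pd.DataFrame] = None  # genes x condition levels
    n_permutations: int = 50
    period: float = 24.0
    n_harmonics: int = 1
    trend: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("q_rhy", "q_dr", "q_de"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} cutoff must lie in (0, 1], got {v}")
        if self.detector not in ("cosinor_F", "external"):
            raise ConfigError(f"unknown rhythm detector {self.detector!r}")
        if self.detector == "external" and self.external_p is None:
            raise ConfigError("the external detector requires an external_p table")

    @property
    def time_basis(self) -> TimeBasis:
        return TimeBasis(period=self.period, n_harmonics=self.n_harmonics)

    def to_dict(self) -> dict:
        return {
            "q_rhy": self.q_rhy, "q_dr": self.q_dr, "q_de": self.q_de,
            "amplitude_cutoff": self.amplitude_cutoff, "detector": self.detector,
            "n_permutations": self.n_permutations, "period": self.period,
            "n_harmonics": self.n_harmonics, "trend": self.trend, "seed": self.seed,
            "fdr_procedure": PROCEDURE,
        }


@dataclass
class WorkflowResult:
    """Per-gene result table plus provenance metadata.

    The table has one row per gene: class label, the workflow q-values,
    the log2 fold-change where step 3 applied, and rhythm parameters where
    step 1 deemed the gene rhythmic.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def class_counts(self) -> pd.Series:
        return self.table["label"].value_counts()


def _condition_levels(meta: SampleMetadata, condition_col: str) -> list[str]:
    return sorted(map(str, pd.unique(meta.column(condition_col).astype(str))))


def _fit_cosinor(expr: ExpressionMatrix, meta: SampleMetadata,
                 basis: TimeBasis) -> GeneFits:
    spec = ModelSpec(time_basis=basis)
    design = build_design(meta, spec)
    return fit_linear_models(expr, design)


def per_condition_cosinor_fits(expr: ExpressionMatrix, meta: SampleMetadata,
                               config: WorkflowConfig,
                               condition_col: str = "condition") -> dict[str, GeneFits]:
    """Fit the cosinor model separately within each condition's samples."""
    meta = meta.aligned_to(expr)
    basis = config.time_basis
    fits = {}
    for level in _condition_levels(meta, condition_col):
        in_level = meta.column(condition_col).astype(str) == level
        sample_ids = [s for s, keep in zip(meta.sample_ids, in_level) if keep]
        sub_expr = expr.subset_samples(sample_ids)
        sub_meta = SampleMetadata(meta.table.loc[sample_ids], meta.time_col)
        n_coef = 1 + basis.n_columns
        if len(sample_ids) <= n_coef:
            raise DesignError(
                f"condition {level!r} has {len(sample_ids)} samples but the cosinor "
                f"model needs more than {n_coef} for a residual degree of freedom"
            )
        fits[level] = fit_linear_models(sub_expr, build_design(sub_meta, ModelSpec(basis)))
    return fits


def per_condition_rhythmicity(expr: ExpressionMatrix, meta: SampleMetadata,
                              config: WorkflowConfig,
                              condition_col: str = "condition") -> pd.DataFrame:
    """Per-gene rhythmicity p-values per condition, combined via min/max.

    Returns a table indexed by gene with one ``p_<level>`` column per
    condition, the combined ``p_min``/``p_max``, and their FDR-adjusted
    ``q_rhy``/``q_rhy_max``.
    """
    meta = meta.aligned_to(expr)
    levels = _condition_levels(meta, condition_col)
    if len(levels) < 2:
        raise ConfigError("per-condition rhythmicity needs at least 2 conditions")
    if config.detector == "external":
        table = config.external_p
        absent = [lev for lev in levels if lev not in table.columns]
        if absent:
            raise ConfigError(f"external p table lacks condition column(s) {absent}")
        missing = [g for g in expr.gene_ids if g not in table.index]
        if missing:
            raise ConfigError(f"external p table lacks {len(missing)} genes, "
                              f"e.g. {missing[:3]}")
        pcols = {f"p_{lev}": table.loc[expr.gene_ids, lev].to_numpy(dtype=float)
                 for lev in levels}
    else:
        fits = per_condition_cosinor_fits(expr, meta, config, condition_col)
        pcols = {}
        for lev in levels:
            fit = fits[lev]
            prior = estimate_prior(fit, trend=config.trend)
            test = moderated_F(fit, prior, fit.design.time_indices)
            pcols[f"p_{lev}"] = test.p_value
    out = pd.DataFrame(pcols, index=pd.Index(expr.gene_ids, name="gene_id"))
    pmat = out.to_numpy()
    out["p_min"] = pmat.min(axis=1)
    out["p_max"] = pmat.max(axis=1)
    out["q_rhy"] = bh_adjust(out["p_min"])
    out["q_rhy_max"] = bh_adjust(out["p_max"])
    return out


def differential_rhythmicity_pvalues(expr: ExpressionMatrix, meta: SampleMetadata,
                                     config: WorkflowConfig,
                                     genes: Optional[Sequence[str]] = None,
                                     condition_col: str = "condition",
                                     factor: Optional[str] = None,
                                     covariates: Sequence[str] = ()) -> pd.Series:
    """Moderated-F p-values for the factor x time interaction.

    Fits the interaction model on the given gene subset (default: all
    genes); the variance prior is estimated on the same subset, so each
    workflow step has its own prior.
    """
    meta = meta.aligned_to(expr)
    if genes is not None:
        expr = expr.subset_genes(list(genes))
    spec = ModelSpec(time_basis=config.time_basis, factor=factor or condition_col,
                     other_covariates=tuple(covariates), interact_factor_with_time=True)
    design = build_design(meta, spec)
    fits = fit_linear_models(expr, design)
    prior = estimate_prior(fits, trend=config.trend)
    test = moderated_F(fits, prior, design.interaction_indices)
    return pd.Series(test.p_value, index=pd.Index(fits.gene_ids, name="gene_id"),
                     name="p_dr")


def _assign_classes(n_genes: int, rhythmic: np.ndarray, dr: np.ndarray,
                    de: np.ndarray, tested_de: np.ndarray) -> np.ndarray:
    labels = np.full(n_genes, CLASS_UNTESTED, dtype=object)
    labels[dr] = CLASS_DR
    rest = ~dr
    labels[rest & rhythmic & de] = CLASS_RHYTHMIC_DE
    labels[rest & rhythmic & ~de] = CLASS_RHYTHMIC_ONLY
    labels[rest & ~rhythmic & de] = CLASS_DE
    labels[rest & ~rhythmic & ~de] = CLASS_NONRHYTHMIC
    return labels


def run_two_condition_workflow(expr: ExpressionMatrix, meta: SampleMetadata,
                               config: WorkflowConfig,
                               condition_col: str = "condition") -> WorkflowResult:
    """Full three-step analysis for a two-condition (e.g., genotype) design."""
    meta = meta.aligned_to(expr)
    levels = _condition_levels(meta, condition_col)
    if len(levels) != 2:
        raise ConfigError(
            f"the two-condition workflow needs exactly 2 condition levels, found "
            f"{levels}; use the generic design builder for richer designs"
        )
    n = expr.n_genes
    gene_index = pd.Index(expr.gene_ids, name="gene_id")

    # step 1: rhythmicity in at least one condition
    step1 = per_condition_rhythmicity(expr, meta, config, condition_col)
    rhythmic = (step1["q_rhy"] <= config.q_rhy).to_numpy()

    # rhythm parameters per condition for rhythmic genes
    cond_fits = per_condition_cosinor_fits(expr, meta, config, condition_col)
    params = {}
    for lev in levels:
        fit = cond_fits[lev]
        ci, si = fit.design.time_indices[0], fit.design.time_indices[1]
        amp, acro, defined = amplitude_acrophase_arrays(
            fit.coefficients[:, ci], fit.coefficients[:, si], config.period)
        params[lev] = (amp, acro, defined)
    amp_ref, acro_ref, def_ref = params[levels[0]]
    amp_alt, acro_alt, def_alt = params[levels[1]]
    delta_amp = amp_alt - amp_ref
    delta_acro = np.array([
        wrap_half_period(a - b, config.period) if (dr_ and db_) else np.nan
        for a, b, dr_, db_ in zip(acro_ref, acro_alt, def_ref, def_alt)
    ])

    # step 2: differential rhythmicity among rhythmic genes
    q_dr = np.full(n, np.nan)
    p_dr = np.full(n, np.nan)
    if rhythmic.any():
        rhythmic_genes = [g for g, r in zip(expr.gene_ids, rhythmic) if r]
        p = differential_rhythmicity_pvalues(expr, meta, config, genes=rhythmic_genes,
                                             condition_col=condition_col)
        p_dr[rhythmic] = p.to_numpy()
        q_dr[rhythmic] = bh_adjust(p.to_numpy())
    dr = rhythmic & (q_dr <= config.q_dr)

    # step 3: differential expression among non-differentially-rhythmic genes
    tested_de = ~dr
    q_de = np.full(n, np.nan)
    p_de = np.full(n, np.nan)
    lfc = np.full(n, np.nan)
    if tested_de.any():
        sub = expr.subset_genes(tested_de)
        spec = ModelSpec(time_basis=config.time_basis, factor=condition_col)
        design = build_design(meta, spec)
        fits = fit_linear_models(sub, design)
        prior = estimate_prior(fits, trend=config.trend)
        test = moderated_t(fits, prior, design.factor_indices[0])
        p_de[tested_de] = test.p_value
        q_de[tested_de] = bh_adjust(test.p_value)
        lfc[tested_de] = test.effect
    de = tested_de & (q_de <= config.q_de)

    labels = _assign_classes(n, rhythmic, dr, de, tested_de)
    table = pd.DataFrame({
        "label": labels,
        "q_rhy": step1["q_rhy"].to_numpy(),
        "q_rhy_max": step1["q_rhy_max"].to_numpy(),
        "p_dr": p_dr, "q_dr": q_dr,
        "p_de": p_de, "q_de": q_de,
        "log2_fold_change": lfc,
        f"amplitude_{levels[0]}": amp_ref, f"amplitude_{levels[1]}": amp_alt,
        f"acrophase_{levels[0]}": acro_ref, f"acrophase_{levels[1]}": acro_alt,
        "delta_amplitude": delta_amp, "delta_acrophase": delta_acro,
    }, index=gene_index).reset_index()
    meta_out = {
        "workflow": "two_condition", "condition_col": condition_col,
        "condition_levels": levels, "reference_level": levels[0],
        "config": config.to_dict(),
        "n_rhythmic": int(rhythmic.sum()), "n_dr": int(dr.sum()), "n_de": int(de.sum()),
    }
    return WorkflowResult(table, meta_out)


def residual_rhythm_amplitude(expr: ExpressionMatrix, meta: SampleMetadata,
                              config: WorkflowConfig, moderator: str,
                              covariates: Sequence[str] = ()) -> np.ndarray:
    """Overall rhythm amplitude from a cosinor fit to covariate-adjusted residuals.

    Expression is first adjusted for the moderator and covariates (a model
    without time terms would be ideal, but a plain intercept+covariate fit
    is exactly that), then the cosinor pair is fit to the residuals of all
    samples pooled.
    """
    meta = meta.aligned_to(expr)
    # adjust for moderator + covariates: the additive design minus its time columns
    adj_design = build_design(meta, ModelSpec(time_basis=config.time_basis,
                                              factor=moderator,
                                              other_covariates=tuple(covariates)))
    keep = [j for j in range(adj_design.n_coefficients)
            if j not in adj_design.time_indices]
    X = adj_design.matrix[:, keep]
    coefs, *_ = np.linalg.lstsq(X, expr.values.T, rcond=None)
    resid = expr.values - (X @ coefs).T
    resid_expr = ExpressionMatrix(expr.gene_ids, expr.sample_ids, resid)
    fit = _fit_cosinor(resid_expr, meta, config.time_basis)
    ci, si = fit.design.time_indices[0], fit.design.time_indices[1]
    amp, _, _ = amplitude_acrophase_arrays(fit.coefficients[:, ci],
                                           fit.coefficients[:, si], config.period)
    return amp


def run_continuous_workflow(expr: ExpressionMatrix, meta: SampleMetadata,
                            config: WorkflowConfig, moderator: str,
                            covariates: Sequence[str] = ()) -> WorkflowResult:
    """Three-step analysis with a continuous moderator (e.g., age in years).

    Step 1 tests the two time terms of the additive model (cosinor with
    covariate adjustment); step 2 the moderator x time interaction among
    rhythmic genes; step 3 the moderator main effect among genes without
    evidence of differential rhythmicity.
    """
    meta = meta.aligned_to(expr)
    if not pd.api.types.is_numeric_dtype(meta.column(moderator)):
        raise ConfigError(f"moderator {moderator!r} must be numeric; use the "
                          "two-condition workflow for categorical factors")
    n = expr.n_genes
    gene_index = pd.Index(expr.gene_ids, name="gene_id")
    additive = ModelSpec(time_basis=config.time_basis, factor=moderator,
                         other_covariates=tuple(covariates))
    design_add = build_design(meta, additive)

    # step 1: moderated F on the time pair of the additive model
    fits_add = fit_linear_models(expr, design_add)
    prior_add = estimate_prior(fits_add, trend=config.trend)
    rhy_test = moderated_F(fits_add, prior_add, design_add.time_indices)
    q_rhy = bh_adjust(rhy_test.p_value)
    rhythmic = q_rhy <= config.q_rhy
    amp = residual_rhythm_amplitude(expr, meta, config, moderator, covariates)
    if config.amplitude_cutoff is not None:
        rhythmic &= amp >= config.amplitude_cutoff

    # step 2: moderator x time interaction among rhythmic genes
    q_dr = np.full(n, np.nan)
    p_dr = np.full(n, np.nan)
    if rhythmic.any():
        rhythmic_genes = [g for g, r in zip(expr.gene_ids, rhythmic) if r]
        p = differential_rhythmicity_pvalues(expr, meta, config, genes=rhythmic_genes,
                                             factor=moderator, covariates=covariates)
        p_dr[rhythmic] = p.to_numpy()
        q_dr[rhythmic] = bh_adjust(p.to_numpy())
    dr = rhythmic & (q_dr <= config.q_dr)

    # step 3: moderator main effect among non-DR genes (additive model)
    tested_de = ~dr
    q_de = np.full(n, np.nan)
    p_de = np.full(n, np.nan)
    slope = np.full(n, np.nan)
    if tested_de.any():
        sub = expr.subset_genes(tested_de)
        fits = fit_linear_models(sub, design_add)
        prior = estimate_prior(fits, trend=config.trend)
        test = moderated_t(fits, prior, design_add.factor_indices[0])
        p_de[tested_de] = test.p_value
        q_de[tested_de] = bh_adjust(test.p_value)
        slope[tested_de] = test.effect
    de = tested_de & (q_de <= config.q_de)

    labels = _assign_classes(n, rhythmic, dr, de, tested_de)
    table = pd.DataFrame({
        "label": labels, "q_rhy": q_rhy, "rhythm_amplitude": amp,
        "p_dr": p_dr, "q_dr": q_dr, "p_de": p_de, "q_de": q_de,
        f"{moderator}_slope": slope,
    }, index=gene_index).reset_index()
    meta_out = {
        "workflow": "continuous_moderator", "moderator": moderator,
        "covariates": list(covariates), "config": config.to_dict(),
        "n_rhythmic": int(rhythmic.sum()), "n_dr": int(dr.sum()), "n_de": int(de.sum()),
    }
    return WorkflowResult(table, meta_out)


@dataclass
class PermutationResult:
    """DR counts per permutation and cutoff, with the unpermuted reference counts."""

    counts: pd.DataFrame  # permutations x cutoffs
    unpermuted: pd.Series  # counts per cutoff on the true labels
    n_rhythmic: int

    def mean_counts(self) -> pd.Series:
        return self.counts.mean(axis=0)


def permute_within_timepoints(condition: np.ndarray, time: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """Shuffle condition labels within blocks of samples sharing a time point.

    Blocks with a single sample cannot be permuted and are left fixed.
    """
    out = condition.copy()
    for t in np.unique(time):
        block = np.flatnonzero(time == t)
        if block.size < 2:
            import warnings

            warnings.warn(f"time point {t} has a single sample; its label is fixed",
                          stacklevel=2)
            continue
        out[block] = condition[block][rng.permutation(block.size)]
    return out


def permutation_null(expr: ExpressionMatrix, meta: SampleMetadata,
                     config: WorkflowConfig,
                     q_cutoffs: Sequence[float] = (0.01, 0.05, 0.1, 0.2),
                     condition_col: str = "condition") -> PermutationResult:
    """Estimate the DR false-positive tendency by within-timepoint label shuffles.

    The rhythmic gene set is fixed from the unpermuted labels; each of
    ``config.n_permutations`` permutations shuffles condition labels within
    time-point blocks, recomputes step-2 q-values on that fixed set, and
    counts genes at each cutoff.
    """
    meta = meta.aligned_to(expr)
    rng = np.random.default_rng(config.seed)
    step1 = per_condition_rhythmicity(expr, meta, config, condition_col)
    rhythmic = (step1["q_rhy"] <= config.q_rhy).to_numpy()
    if not rhythmic.any():
        raise ConfigError("no rhythmic genes at the configured q_rhy cutoff; "
                          "nothing to permute")
    rhythmic_genes = [g for g, r in zip(expr.gene_ids, rhythmic) if r]

    def dr_counts(meta_i: SampleMetadata) -> list[int]:
        p = differential_rhythmicity_pvalues(expr, meta_i, config, genes=rhythmic_genes,
                                             condition_col=condition_col)
        q = bh_adjust(p.to_numpy())
        return [int((q <= c).sum()) for c in q_cutoffs]

    cutoff_names = [f"q<={c}" for c in q_cutoffs]
    unpermuted = pd.Series(dr_counts(meta), index=cutoff_names)
    condition = meta.column(condition_col).astype(str).to_numpy()
    time = meta.time
    rows = []
    for _ in range(config.n_permutations):
        permuted = permute_within_timepoints(condition, time, rng)
        table = meta.table.copy()
        table[condition_col] = permuted
        rows.append(dr_counts(SampleMetadata(table, meta.time_col)))
    counts = pd.DataFrame(rows, columns=cutoff_names)
    return PermutationResult(counts, unpermuted, int(rhythmic.sum()))


def geometric_mean_counts(values, zero_offset: float = 1.0) -> tuple[float, float]:
    """Geometric mean of non-negative counts, returned with the offset used.

    Strictly positive inputs use the plain geometric mean (offset 0).  If
    any count is zero — where the geometric mean is undefined — the summary
    is computed as ``exp(mean(log(x + zero_offset))) - zero_offset`` and
    the applied offset is reported alongside the value.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ConfigError("geometric mean expects non-negative values")
    offset = zero_offset if np.any(arr == 0) else 0.0
    return float(np.exp(np.mean(np.log(arr + offset))) - offset), offset
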