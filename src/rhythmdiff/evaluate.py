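"""ROC/AUC and true-positive-rate evaluation of detection p-values.

Lower p-values mean stronger evidence.  The AUC is the probability that a
randomly chosen positive gene receives a smaller p-value than a randomly
chosen negative gene, with ties credited one half (the Mann-Whitney
convention), computed exactly via the rank formulation.  Negatives default
to truth genes that are rhythmic but not differentially rhythmic, so the
evaluation isolates the differential-rhythmicity test from the rhythm
detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .errors import EvaluationError
from .simulate import LABEL_DR, LABEL_RHYTHMIC, GridPoint, SimulationSpec


@dataclass
class RocResult:
    """AUC plus the full ROC step curve (FPR, TPR points)."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(p_values, is_positive) -> RocResult:
    """Exact ROC/AUC for separating positives (small p) from negatives."""
    p = np.asarray(p_values, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    if p.shape != pos.shape or p.ndim != 1:
        raise EvaluationError("p_values and is_positive must be 1-D and aligned")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC evaluation requires both classes to be non-empty")
    ranks = rankdata(p)  # midranks: ties contribute 1/2 per pair
    u = ranks[~pos].sum() - n_neg * (n_neg + 1) / 2.0
    auc = u / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(pos.astype(int), -p)
    return RocResult(float(auc), fpr, tpr)


def tpr_at_threshold(p_values_of_positives, threshold: float = 0.01) -> float:
    """Fraction of positive genes with nominal p <= threshold (unadjusted)."""
    p = np.asarray(p_values_of_positives, dtype=float)
    if p.size == 0:
        raise EvaluationError("TPR requires a non-empty positive set")
    return float(np.mean(p <= threshold))


def evaluate_dr_pvalues(p_values: pd.Series, truth: pd.DataFrame,
                        threshold: float = 0.01,
                        include_nonrhythmic_negatives: bool = False) -> dict:
    """Score differential-rhythmicity p-values against a truth table.

    Positives are the truth-DR genes; negatives the rhythmic-but-not-DR
    genes (optionally all non-DR genes).  Returns AUC and TPR at the
    nominal threshold.
    """
    truth = truth.set_index("gene_id") if "gene_id" in truth.columns else truth
    labels = truth.loc[p_values.index, "label"]
    pos_mask = (labels == LABEL_DR).to_numpy()
    if include_nonrhythmic_negatives:
        keep = np.ones(len(labels), dtype=bool)
    else:
        keep = pos_mask | (labels == LABEL_RHYTHMIC).to_numpy()
    roc = roc_auc(p_values.to_numpy()[keep], pos_mask[keep])
    return {
        "auc": roc.auc,
        "tpr": tpr_at_threshold(p_values.to_numpy()[pos_mask], threshold),
        "n_positive": int(pos_mask.sum()),
        "n_negative": int(keep.sum() - pos_mask.sum()),
    }


def run_grid_evaluation(grid: list[GridPoint], seed, base_spec: SimulationSpec | None = None,
                        threshold: float = 0.01, trend: bool = True) -> pd.DataFrame:
    """Simulate one dataset per grid point and score DR detection on each.

    Returns a table with columns (mean_amplitude, delta_amp, delta_phase,
    auc, tpr) suitable for heatmap rendering.  Per-dataset seeds are
    spawned deterministically from ``seed``.
    """
    from dataclasses import replace

    from .workflow import WorkflowConfig, differential_rhythmicity_pvalues

    base = base_spec or SimulationSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(grid)) % (2**31)
    rows = []
    for point, ds_seed in zip(grid, child_seeds):
        spec = replace(base, mean_amplitude=point.mean_amplitude,
                       delta_amp=point.delta_amp, delta_phase=point.delta_phase)
        from .simulate import generate_dataset

        expr, meta, truth = generate_dataset(spec, int(ds_seed))
        config = WorkflowConfig(period=spec.period, trend=trend)
        p = differential_rhythmicity_pvalues(expr, meta, config)
        score = evaluate_dr_pvalues(p, truth, threshold=threshold)
        rows.append({
            "mean_amplitude": point.mean_amplitude,
            "delta_amp": point.delta_amp,
            "delta_phase": np.nan if point.delta_phase is None else point.delta_phase,
            "auc": score["auc"],
            "tpr": score["tpr"],
        })
    return pd.DataFrame(rows)
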