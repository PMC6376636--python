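"""False-discovery-rate adjustment of p-values.

The default procedure is Benjamini-Hochberg step-up: with the p-values
sorted ascending, ``q_(i) = min_{j >= i} m * p_(j) / j`` mapped back to the
input order.  The procedure used is recorded in result metadata so runs
remain self-describing; the surface is pluggable should a pi0-adaptive
q-value method be preferred.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import DomainError

PROCEDURE = "benjamini-hochberg"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise DomainError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q
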