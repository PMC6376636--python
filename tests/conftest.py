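import numpy as np
import pandas as pd
import pytest

from rhythmdiff import ExpressionMatrix, SampleMetadata, SimulationSpec, TimeBasis


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_spec():
    """A small but otherwise default-layout simulation spec."""
    return SimulationSpec(n_genes=400, n_dr=30, delta_amp=1.0, delta_phase=6.0)


@pytest.fixture
def two_condition_meta():
    """12 samples: 2 conditions x 3 time points x 2 replicates."""
    rows = []
    for cond in ("ko", "wt"):
        for t in (0.0, 8.0, 16.0):
            for r in (1, 2):
                rows.append((f"{cond}_{int(t)}_{r}", t, cond))
    frame = pd.DataFrame(rows, columns=["sample_id", "time", "condition"]).set_index("sample_id")
    return SampleMetadata(frame)


@pytest.fixture
def tiny_expr(rng, two_condition_meta):
    ids = two_condition_meta.sample_ids
    vals = rng.normal(size=(5, len(ids)))
    return ExpressionMatrix([f"g{i}" for i in range(5)], ids, vals)


@pytest.fixture
def basis():
    return TimeBasis()
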