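import numpy as np
import pandas as pd
import pytest

import depscreen as ds


@pytest.fixture(scope="session")
def planted_bundle():
    """Small panel with one strongly planted mutant-sensitive pair."""
    cfg = ds.SyntheticConfig(
        n_panel=120,
        n_cohort=20,
        n_targets=60,
        n_biomarkers=10,
        planted=[
            ds.PlantedEffect("T0003", "B0002", -3.9, cohort_only=True, n_mut_cohort=6)
        ],
        seed=42,
    )
    bundle, truth = ds.generate_bundle(cfg)
    cohort = ds.select_cohort(bundle.annotation, tumor_type="cohort")
    return bundle, truth, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_matrix(values, rows=None, cols=None):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"G{i}" for i in range(values.shape[0])]
    cols = cols or [f"CL{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=rows, columns=cols)
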