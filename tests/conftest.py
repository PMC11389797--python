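import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import mucoseq as mq

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture(scope="session")
def fmt_design():
    """Four-group FMT design, 5 mice per group."""
    return mq.make_fmt_design(n_per_group=5)


@pytest.fixture(scope="session")
def effect_dataset(fmt_design):
    """Shared-effect simulation used across DEG/overlap tests (frozen seed)."""
    spec = mq.EffectSpec(
        n_genes=10_000, n_shared_effect=1_000, log2_effect_size=3.0, seed=1
    )
    counts, truth = mq.generate_counts(fmt_design, spec)
    filtered, _ = mq.filter_sparse_genes(counts)
    norm = mq.normalize_library_size(filtered)
    return norm, truth, fmt_design


@pytest.fixture(scope="session")
def cohort_deg(effect_dataset):
    """Per-cohort DEG results on the shared-effect dataset."""
    norm, truth, design = effect_dataset
    results = {}
    for cohort in ("SPF", "GF"):
        ctrl = design.index[(design.cohort == cohort) & (design.treatment == "PBS")]
        trt = design.index[(design.cohort == cohort) & (design.treatment == "Van")]
        results[cohort] = mq.DifferentialExpression(norm, ctrl, trt).fit()
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count matrix (4 samples)."""
    return pd.DataFrame(
        {
            "s1": [5, 0, 0, 2],
            "s2": [1, 0, 3, 3],
            "s3": [2, 7, 0, 5],
            "s4": [8, 1, 0, 0],
        },
        index=["dense", "two_zeros", "three_zeros", "one_zero"],
    )
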