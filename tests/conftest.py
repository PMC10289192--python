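import numpy as np
import pandas as pd
import pytest

from ambumetric.schema_io import (
    Dataset,
    default_feature_schema,
    default_label_schemas,
    default_trait_schema,
)
from ambumetric.synthetic_data import GeneratorConfig, generate_cohort


def make_frame(label_rows, construct="stress", seed=0):
    """Build a tiny valid cohort frame from {pid: [labels...]} mappings."""
    rng = np.random.default_rng(seed)
    fs, ts = default_feature_schema(), default_trait_schema()
    rows = []
    for pid, labels in label_rows.items():
        traits = rng.normal(size=ts.total_count)
        for day, label in enumerate(labels):
            row = {"participant_id": pid, "day_index": day}
            row.update({n: v for n, v in
                        zip(fs.names, rng.normal(size=fs.total_count))})
            row.update({n: v for n, v in zip(ts.names, traits)})
            row[construct] = label
            rows.append(row)
    return pd.DataFrame(rows)


def make_dataset(label_rows, construct="stress", seed=0):
    return Dataset(make_frame(label_rows, construct, seed),
                   default_feature_schema(), default_trait_schema(),
                   default_label_schemas())


@pytest.fixture
def tiny_dataset():
    return make_dataset({"a": [1, 2, 4], "b": [3, 3, 5, 2]})


@pytest.fixture(scope="session")
def signal_cohort():
    """Strong-signal cohort reused by slower model tests."""
    cfg = GeneratorConfig(n_participants=20, n_days=20, construct="stress",
                          signal_strength=3.0, subject_shift_scale=0.5,
                          label_skew=0.0, missing_rate=0.1, seed=7)
    ds, truth = generate_cohort(cfg)
    return ds, truth
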