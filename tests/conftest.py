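"""Shared fixtures: desk-scale synthetic datasets and trained models.

Everything is generated programmatically at test time; session scope keeps
the expensive pipeline artifacts (feature tables, trained boosters) shared
across the tests that exercise them.
"""

from __future__ import annotations

import numpy as np
import pytest

from beatguard.model import Hyperparams, LabeledFeatures, train
from beatguard.pipeline import features_from_records, table_to_labeled
from beatguard.synth import (
    CLASS_TEMPLATES,
    RhythmSpec,
    synth_record,
    two_class_benchmark,
)

#: Small-but-real hyperparameters used for desk-scale training in tests.
TEST_HP = Hyperparams(n_estimators=200, max_depth=6, num_leaves=31, seed=0)


@pytest.fixture(scope="session")
def two_class_data():
    """N-vs-V benchmark: feature table, split arrays and a trained model."""
    from sklearn.model_selection import train_test_split

    table = features_from_records(two_class_benchmark(n_records=10, seed=100))
    feats = table_to_labeled(table)
    y = np.array(feats.y)
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=0.3, random_state=0, stratify=y)
    bundle = train(LabeledFeatures(feats.X[tr], list(y[tr])), TEST_HP)
    return {
        "table": table,
        "X": feats.X,
        "y": y,
        "train_idx": tr,
        "test_idx": te,
        "bundle": bundle,
    }


@pytest.fixture(scope="session")
def five_class_table():
    """Feature table over all five beat morphologies (3 records each)."""
    records, labels = [], []
    for label, template in CLASS_TEMPLATES.items():
        for k in range(3):
            spec = RhythmSpec(
                duration=60.0,
                normal_template=template,
                pvc_probability=0.0,
                amplitude_jitter=0.1,
                seed=1000 + 10 * k + ord(label),
            )
            rec, _ = synth_record(spec)
            rec.annotations = [
                type(a)(a.sample_index, label) for a in rec.annotations
            ]
            records.append(rec)
            labels.append(label)
    table = features_from_records(records)
    return table


@pytest.fixture(scope="session")
def ids_setup():
    """Trained intrusion detector plus a held-out attack benchmark."""
    from beatguard.ids import build_attack_benchmark, train_ids

    train_bench = build_attack_benchmark(n_records=8, intensity=0.8, seed=0)
    test_bench = build_attack_benchmark(n_records=4, intensity=0.8, seed=50)
    bundle = train_ids(train_bench["clean"], train_bench["attacked"])
    return {"bundle": bundle, "train": train_bench, "test": test_bench}
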