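import numpy as np
import pytest

from hiascreen import make_record


@pytest.fixture(scope="session")
def small_records():
    """A handful of real drug-like molecules with assigned HIA values."""
    data = [
        ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", 100.0),
        ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 99.0),
        ("serotonin", "NCCc1c[nH]c2ccccc12", 75.0),
        ("paracetamol", "CC(=O)Nc1ccc(O)cc1", 88.0),
        ("sulpiride", "CCN1CCCC1CNC(=O)c1cc(S(N)(=O)=O)ccc1OC", 36.0),
        ("ethanol", "CCO", 100.0),
    ]
    return [make_record(n, s, h) for n, s, h in data]


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small synthetic train/test problem shared by slow model tests."""
    from hiascreen import (
        Preprocessor,
        compute_descriptors,
        labels_for,
        make_benchmark,
        subset,
    )

    dataset, assignment = make_benchmark(n_train=70, n_test=30, seed=7)
    matrix = compute_descriptors(dataset.records)
    train = subset(dataset, assignment.train_ids)
    test = subset(dataset, assignment.test_ids)
    pre = Preprocessor().fit(matrix.loc[list(assignment.train_ids)])
    return {
        "dataset": dataset,
        "assignment": assignment,
        "train": train,
        "test": test,
        "X_train": pre.transform(matrix.loc[list(assignment.train_ids)]),
        "X_test": pre.transform(matrix.loc[list(assignment.test_ids)]),
        "y_train": labels_for(train),
        "y_test": labels_for(test),
        "hia_train": train.hia_array(),
        "hia_test": test.hia_array(),
        "preprocessor": pre,
    }
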