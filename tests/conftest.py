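"""Shared fixtures: small synthetic records and a session-scoped cohort."""

import numpy as np
import pytest

from ifcprofiler.core_data import CellRecord
from ifcprofiler.features import extract_features, full_inventory
from ifcprofiler.synthetic import balanced_cohort_spec, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_record(
    record_id="rec",
    channels=("BF", "F-actin", "MHCII", "CD3", "P-CD3z"),
    size=32,
    seed=0,
    label=None,
    probs=None,
):
    """A small valid record with random content."""
    r = np.random.default_rng(seed)
    image = r.integers(0, 4000, size=(len(channels), size, size)).astype(np.uint16)
    masks = np.zeros((len(channels), size, size), dtype=bool)
    masks[:, 8:24, 8:24] = True
    return CellRecord(
        record_id=record_id,
        channels=channels,
        image=image,
        masks=masks,
        meta={"donor_id": "d1", "experiment_id": "e1", "condition": "ctrl"},
        label=label,
        probs=probs,
    )


@pytest.fixture()
def small_record():
    return make_record()


@pytest.fixture(scope="session")
def small_cohort():
    """270-record uniform 9-class cohort shared across tests."""
    spec = balanced_cohort_spec(n_donors=3, records_per_group=90, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    inv = full_inventory(list(small_cohort.records[0].channels))
    table = extract_features(small_cohort.records, inv)
    labels = small_cohort.index.labels.loc[table.df.index]
    return table, labels, inv
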