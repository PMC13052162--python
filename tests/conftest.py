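import logging

import numpy as np
import pandas as pd
import pytest

from edna_divide import asv_filtering as af
from edna_divide import synthetic_data as sd

logging.getLogger("edna_divide").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset: 10 basins, 6 species, full artefact load."""
    return sd.synthesize_dataset(seed=7)


@pytest.fixture(scope="session")
def filtered(dataset):
    matrix = af.ReadMatrix(counts=dataset.counts, is_control=dataset.is_control)
    records = af.records_from_tables(dataset.sequences, dataset.taxonomy)
    return af.run_filter_pipeline(
        matrix, records, dataset.metadata, dataset.reference_cds
    )


def random_distance_frame(rng, n, scale=1.0, labels=None):
    """Random symmetric zero-diagonal matrix (not necessarily metric)."""
    M = rng.uniform(0, scale, (n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    labels = labels or [f"s{i}" for i in range(n)]
    return pd.DataFrame(M, index=labels, columns=labels)
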