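import numpy as np
import pandas as pd
import pytest

from actampl.tables import CountTable


def make_table(counts, otu_ids=None, sample_ids=None, stations=None, libraries=None,
               require_integer=True):
    """Build a CountTable from a plain array with sensible defaults."""
    counts = np.asarray(counts)
    n_otus, n_samples = counts.shape
    otu_ids = otu_ids or [f"OTU{i+1}" for i in range(n_otus)]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(n_samples)]
    stations = stations or [f"st{j+1}" for j in range(n_samples)]
    libraries = libraries or ["DNA"] * n_samples
    meta = pd.DataFrame({"station": stations, "library": libraries}, index=sample_ids)
    data = pd.DataFrame(counts, index=otu_ids, columns=sample_ids)
    return CountTable(data, meta, require_integer=require_integer)


@pytest.fixture
def two_by_two():
    return make_table([[3, 0], [1, 4]])


@pytest.fixture
def paired_station_table():
    """Two stations x {DNA, RNA}, 3 OTUs."""
    counts = [[80, 60, 70, 50], [15, 30, 20, 40], [5, 10, 10, 10]]
    return make_table(
        counts,
        sample_ids=["A_DNA", "A_RNA", "B_DNA", "B_RNA"],
        stations=["A", "A", "B", "B"],
        libraries=["DNA", "RNA", "DNA", "RNA"],
    )
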