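import io as _io

import numpy as np
import pytest

import dendrotramp as dt


@pytest.fixture(scope="session")
def study_dataset():
    """Seeded study-design dataset: 90 trees across 2 plots, 15 flawed."""
    config = dt.study_shape()
    dataset, truth = dt.generate_dataset(config, seed=20150901)
    return dataset, truth


@pytest.fixture(scope="session")
def chronologies(study_dataset):
    """Normalized per plot/zone mean chronologies for the fixture dataset."""
    dataset, _ = study_dataset
    z, params = dt.normalize_global(dataset)
    return dt.build_chronology(z)


@pytest.fixture()
def tiny_csv():
    """3-year x 2-tree wide table, one track and one control tree."""
    text = "year,K_T_1,K_C_2\n2000,1.0,2.0\n2001,1.5,2.5\n2002,1.2,2.2\n"
    return _io.StringIO(text)


def make_series(tree_id="K_T_1", plot="K", zone="track", first_year=2000, widths=(1.0, 2.0, 3.0), flawed=False):
    return dt.RingSeries(tree_id, plot, zone, first_year, np.asarray(widths, float), flawed)
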