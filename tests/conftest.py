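import io

import numpy as np
import pytest

from fmtgraft.profile_io import FeatureTable, SampleRecord, read_newick
from fmtgraft.simulate import CohortParams, simulate_cohort


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — 3 tips, total branch length 5."""
    return read_newick(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def star_tree():
    return read_newick(io.StringIO("((A:1,B:1,C:1,D:1,E:1):0.0);"))


@pytest.fixture
def small_table():
    return FeatureTable(
        feature_ids=("f1", "f2", "f3", "f4"),
        sample_ids=("S1", "S2", "S3"),
        counts=np.array([[0, 5, 2], [3, 0, 2], [0, 1, 0], [1, 0, 2]]),
    )


@pytest.fixture
def toy_records():
    return (
        SampleRecord("S1", "DolphinA", "recipient", "baseline", 0, 0),
        SampleRecord("S2", "DolphinA", "recipient", "baseline", 2, 1),
        SampleRecord("S3", "DolphinA", "recipient", "post_fmt", 1, 2),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A fast full cohort for integration-style tests."""
    return simulate_cohort(CohortParams(n_taxa=150, seed=7))
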