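import numpy as np
import pytest

from lgtree.core_io import TaxonGroupMap, load_table1_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture(scope="session")
def fixture_records():
    return load_table1_fixture()


@pytest.fixture
def toy_groups():
    """Five-group map used across classifier tests; species = taxon name."""
    taxa = {
        **{f"IV_{i}": ("cluster_IV", ) for i in range(1, 6)},
        **{f"XIVa_{i}": ("cluster_XIVa", ) for i in range(1, 6)},
        **{f"other_{i}": ("other", ) for i in range(1, 4)},
    }
    entries = {t: (t, g[0]) for t, g in taxa.items()}
    entries["Q"] = ("Q", "cluster_IV")
    return TaxonGroupMap(
        entries=entries,
        vocabulary=("cluster_IV", "cluster_XIVa", "other"),
        focal_group="cluster_IV",
    )
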