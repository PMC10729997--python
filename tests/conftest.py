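import warnings

import numpy as np
import pandas as pd
import pytest

from middennet import (
    AssemblageMatrix,
    TaxonRecord,
    load_pineland,
    load_pineland_contexts,
    load_pineland_taxa,
)

# similarity helpers warn about empty presence sets etc.; tests assert the
# warnings they care about explicitly
warnings.filterwarnings("ignore", category=UserWarning, module="middennet")


@pytest.fixture(scope="session")
def pineland():
    return load_pineland()


@pytest.fixture(scope="session")
def pineland_taxa():
    return load_pineland_taxa()


@pytest.fixture(scope="session")
def pineland_contexts():
    return load_pineland_contexts()


@pytest.fixture
def toy_matrix():
    """3 taxa x 3 contexts with one all-zero column."""
    df = pd.DataFrame(
        [[2, 1, 0], [3, 0, 0], [5, 4, 0]],
        index=["ta", "tb", "tc"],
        columns=["c1", "c2", "c3"],
    )
    return AssemblageMatrix(df)


@pytest.fixture
def toy_taxa():
    return [
        TaxonRecord("ta", kingdom_class="invertebrate", habitats=frozenset({"oyster_bed"})),
        TaxonRecord(
            "tb",
            kingdom_class="invertebrate",
            habitats=frozenset({"oyster_bed", "seagrass_meadow"}),
        ),
        TaxonRecord("tc", kingdom_class="invertebrate", habitats=frozenset({"littoral"})),
    ]


def random_count_matrix(rng: np.random.Generator, n_taxa: int, n_ctx: int, density=0.5):
    counts = rng.integers(0, 9, size=(n_taxa, n_ctx))
    counts *= rng.random(size=counts.shape) < density
    df = pd.DataFrame(
        counts,
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"c{j}" for j in range(n_ctx)],
    )
    return AssemblageMatrix(df)
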