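import numpy as np
import pandas as pd
import pytest

from omicsconcord.io_model import FeatureTable, SampleDesign, TaxonomyMap


@pytest.fixture
def small_counts() -> FeatureTable:
    data = pd.DataFrame(
        {
            "s1": [3.0, 1.0, 6.0],
            "s2": [4.0, 2.0, 0.0],
        },
        index=["otu1", "otu2", "otu3"],
    )
    return FeatureTable(data, "counts")


@pytest.fixture
def small_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "otu1": {"kingdom": "Bacteria", "phylum": "Firmicutes",
                     "family": "Lachnospiraceae", "genus": "Blautia"},
            "otu2": {"kingdom": "Bacteria", "phylum": "Firmicutes",
                     "family": "Lachnospiraceae"},  # no genus
            "otu3": {"kingdom": "Bacteria", "phylum": "Bacteroidetes",
                     "family": "Rikenellaceae", "genus": "Alistipes"},
        }
    )


def make_design(n_subjects: int, methods=("gold", "alt"), gold: str = "gold") -> SampleDesign:
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    assignments = {
        f"{s}.{m}": (s, m) for s in subjects for m in methods
    }
    return SampleDesign(assignments, gold)


@pytest.fixture
def paired_design() -> SampleDesign:
    return make_design(8)
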