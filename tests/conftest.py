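import pandas as pd
import pytest

from enrichbench.io import GeneSetLibrary
from enrichbench.simulate import (
    SimulationSpec,
    simulate_counts,
    simulate_de_table,
    simulate_library,
)


@pytest.fixture
def tiny_library():
    """Three hand-built sets over a 12-gene universe."""
    return GeneSetLibrary(
        name="tiny",
        sets={
            "S1": frozenset({"G01", "G02", "G03"}),
            "S2": frozenset({"G04", "G05", "G06", "G07", "G08"}),
            "S3": frozenset({"G09", "G10", "G11", "G12"}),
        },
        descriptions={"S1": "a", "S2": "b", "S3": "c"},
    )


def make_de_table(genes, log2fc, p, fdr=None):
    df = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr if fdr is not None else p},
        index=pd.Index(genes, name="gene"),
    )
    return df


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down simulation spec so unit tests stay fast."""
    return SimulationSpec(
        seed=7,
        n_annotation_genes=4000,
        n_sets=80,
        n_planted_sets=10,
        set_size_range=(10, 40),
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    """One full synthetic study (counts, truth, DE table, library)."""
    counts, truth = simulate_counts(small_spec)
    de = simulate_de_table(counts, truth, small_spec)
    library = simulate_library(small_spec, truth)
    return counts, truth, de, library
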