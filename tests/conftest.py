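import pytest

from seenrec import OntologyDAG, SequentialDataset, SimilarityTable, information_content


@pytest.fixture
def toy_dag() -> OntologyDAG:
    """Root R with children A, B; A has child C."""
    return OntologyDAG(parents={"R": (), "A": ("R",), "B": ("R",), "C": ("A",)},
                       names={"R": "root", "A": "a", "B": "b", "C": "c"})


@pytest.fixture
def toy_ic(toy_dag):
    return information_content(toy_dag)


@pytest.fixture
def compound_table() -> SimilarityTable:
    """Neighbour table of the three-compound enrichment example."""
    return SimilarityTable({
        ("noradrenaline", "monoamine"): 0.836,
        ("bisdemethoxycurcumin", "clethodim"): 0.667,
        ("terretonin", "yanuthones"): 0.780,
    })


@pytest.fixture
def small_ds() -> SequentialDataset:
    return SequentialDataset(sequences={
        "u1": [("a", 2000), ("b", 2001), ("c", 2002), ("d", 2003)],
        "u2": [("b", 1999), ("c", 2000), ("e", 2005)],
    })
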