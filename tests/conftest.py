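import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from regset.data_model import AnnotationDatabase, Interactome, Universe


@pytest.fixture
def toy_db() -> AnnotationDatabase:
    """Three small gene terms over a 10-gene space."""
    return AnnotationDatabase(
        source_name="toy",
        terms={
            "T1": ("term one", frozenset({"g1", "g2", "g3"})),
            "T2": ("term two", frozenset({"g3", "g4", "g5", "g6"})),
            "T3": ("term three", frozenset({"g7", "g8"})),
        },
        element_kind="gene",
    )


@pytest.fixture
def toy_interactome() -> Interactome:
    return Interactome(
        kind="mirna",
        edges=frozenset({
            ("m1", "g1"), ("m2", "g1"), ("m2", "g2"),
            ("m3", "g3"), ("m3", "g4"), ("m1", "g3"),
        }),
    )


@pytest.fixture
def universe10() -> Universe:
    return Universe(scope="custom", elements=frozenset(f"g{i}" for i in range(1, 11)))
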