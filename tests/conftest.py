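import numpy as np
import pytest

from corticonet.anatomy import load_anatomy
from corticonet.archgen import (
    ArchitectureGraph,
    ClassifierSpec,
    EdgeSpec,
    RegionNode,
    build_graph,
)


@pytest.fixture(scope="session")
def anatomy():
    """The shipped (published-configuration) anatomy tables."""
    return load_anatomy()


@pytest.fixture(scope="session")
def graph(anatomy):
    """Published architecture with formula-derived interlaminar kernels."""
    return build_graph(anatomy)


@pytest.fixture(scope="session")
def graph_published(anatomy):
    """Published architecture with all kernels taken verbatim from the
    as-published table."""
    return build_graph(anatomy, interlaminar_kernels="published")


def make_toy_graph(size=16, n_classes=2, k=3, mask_seed=1):
    """A 2-region chain (input -> R1 -> R2 -> classifier) for runtime tests."""
    regions = {
        "R1": RegionNode("R1", "A", None, 0, (size, size), 4),
        "R2": RegionNode("R2", "B", None, 0, (size, size), 6),
    }
    edges = [
        EdgeSpec("input", "R1", k, 1, (k - 1) // 2, masked=False),
        EdgeSpec("R1", "R2", k, 1, (k - 1) // 2, dw_px=1.5, d_p=0.8),
    ]
    classifier = ClassifierSpec(
        pool=(4, 4), n_classes=n_classes, source_regions=("R2",)
    )
    return ArchitectureGraph(
        regions=regions,
        edges=edges,
        classifier=classifier,
        input_channels=3,
        input_grid=(size, size),
        mask_seed=mask_seed,
    )


def make_fanin_graph(size=8):
    """Two parallel regions feeding one target, to exercise summation."""
    regions = {
        "A": RegionNode("A", "A", None, 0, (size, size), 3),
        "B": RegionNode("B", "B", None, 0, (size, size), 3),
        "C": RegionNode("C", "C", None, 0, (size, size), 4),
    }
    edges = [
        EdgeSpec("input", "A", 3, 1, 1, masked=False),
        EdgeSpec("input", "B", 3, 1, 1, masked=False),
        EdgeSpec("A", "C", 3, 1, 1, masked=False),
        EdgeSpec("B", "C", 3, 1, 1, masked=False),
    ]
    classifier = ClassifierSpec(pool=(4, 4), n_classes=2, source_regions=("C",))
    return ArchitectureGraph(
        regions=regions,
        edges=edges,
        classifier=classifier,
        input_channels=2,
        input_grid=(size, size),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
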