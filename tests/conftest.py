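import networkx as nx
import pytest

from netformula import AnalysisConfig
from netformula.synth import FixtureSpec


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def small_spec():
    """A reduced synthetic world for fast end-to-end runs."""
    return FixtureSpec(
        seed=11,
        n_herbs=12,
        n_compounds=60,
        n_targets=20,
        n_genes=100,
        n_terms=10,
        n_patients=40,
        n_prescriptions=80,
        herbs_per_prescription=(6, 10),
        n_formula_compounds=20,
    )


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g
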