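import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mosqnet import SynthSpec, TaxaTable, default_planted_graph


@pytest.fixture
def tiny_table():
    """3 biological samples x 4 taxa plus one negative control."""
    counts = pd.DataFrame(
        [[10, 5, 0, 1],
         [8, 0, 2, 1],
         [12, 3, 1, 0],
         [0, 0, 0, 7]],
        index=["s1", "s2", "s3", "nc1"],
        columns=["t1", "t2", "t3", "conta"])
    group = pd.Series(["A", "A", "B", "control"], index=counts.index)
    ctrl = pd.Series([False, False, False, True], index=counts.index)
    return TaxaTable(counts, group, ctrl)


@pytest.fixture
def default_spec():
    spec = SynthSpec(seed=7)
    spec.planted_graph = default_planted_graph(spec)
    spec.__post_init__()
    return spec


@pytest.fixture
def small_spec():
    """Scaled-down two-group design for fast end-to-end tests."""
    spec = SynthSpec(n_samples_per_group=8, n_core_taxa=8,
                     n_accessory_taxa_per_group=(20, 12),
                     sequencing_depth=5000, seed=11)
    spec.planted_graph = default_planted_graph(spec)
    spec.__post_init__()
    return spec


def random_signed_graph(rng, n_max=12, p=0.35) -> nx.Graph:
    """Random signed weighted graph in the package's edge-attribute format."""
    n = int(rng.integers(4, n_max + 1))
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                r = float(rng.uniform(0.5, 1.0) * rng.choice([-1, 1]))
                g.add_edge(f"n{i:02d}", f"n{j:02d}",
                           r=r, sign=1 if r > 0 else -1, absweight=abs(r))
    return g


@pytest.fixture
def graph_factory():
    return random_signed_graph
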