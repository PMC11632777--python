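import numpy as np
import pytest

from aabbatools.graph_model import MolecularGraph, canonical_edge


def make_graph(nodes, edges, p=None, q=None, metal=None, atom_names=("p",), bond_names=("q",)):
    """Small-graph constructor with scalar shorthand: p/q may be dicts of
    single values keyed by node/edge, applied to the property name lists."""
    p = p or {}
    q = q or {}

    def vec(value, names):
        seq = value if isinstance(value, (list, tuple)) else [value] * len(names)
        return {name: float(seq[k]) for k, name in enumerate(names)}

    atom_props = {n: vec(p.get(n, 1.0), atom_names) for n in nodes}
    bond_props = {}
    for e in edges:
        key = canonical_edge(*e)
        value = q.get(key, q.get((key[1], key[0]), 1.0))
        bond_props[key] = vec(value, bond_names)
    return MolecularGraph(nodes, edges, atom_props, bond_props, metal)


@pytest.fixture
def path_abc():
    """A-B-C with atomic p = 1,2,3, bonds q(AB)=2, q(BC)=5, metal B."""
    return make_graph(
        ["A", "B", "C"],
        [("A", "B"), ("B", "C")],
        p={"A": 1, "B": 2, "C": 3},
        q={("A", "B"): 2, ("B", "C"): 5},
        metal="B",
    )


@pytest.fixture
def path_abcd():
    """A-B-C-D path, bonds q = 2, 5, 3; no metal."""
    return make_graph(
        ["A", "B", "C", "D"],
        [("A", "B"), ("B", "C"), ("C", "D")],
        p={"A": 1, "B": 1, "C": 1, "D": 1},
        q={("A", "B"): 2, ("B", "C"): 5, ("C", "D"): 3},
    )


@pytest.fixture
def single_edge():
    """A-B with q = 4 and p = 1, 2."""
    return make_graph(["A", "B"], [("A", "B")], p={"A": 1, "B": 2}, q={("A", "B"): 4})


def random_connected_graph(rng, n_max=10, with_metal=True, positive=True):
    """Random connected graph: spanning tree plus extra edges, random
    properties (positive by default so ratiometric terms are defined)."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(1, n):
        j = int(rng.integers(i))
        edges.append((nodes[j], nodes[i]))
    extra = int(rng.integers(0, max(n // 2, 1)))
    have = {canonical_edge(*e) for e in edges}
    for _ in range(extra):
        i, j = rng.choice(n, 2, replace=False)
        key = canonical_edge(nodes[int(i)], nodes[int(j)])
        if key not in have:
            have.add(key)
            edges.append(key)
    lo = 0.5 if positive else -2.0
    p = {nd: float(rng.uniform(lo, 3.0)) for nd in nodes}
    q = {canonical_edge(*e): float(rng.uniform(lo, 3.0)) for e in edges}
    metal = nodes[int(rng.integers(n))] if with_metal else None
    return make_graph(nodes, edges, p=p, q=q, metal=metal)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
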