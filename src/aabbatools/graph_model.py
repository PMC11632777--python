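"""Attributed molecular graphs and the three distance notions behind autocorrelation depth.

A :class:`MolecularGraph` is an undirected, connected graph whose nodes carry a
fixed set of real-valued atomic properties (e.g. atomic number, electronegativity)
and whose edges carry a fixed set of bond properties (e.g. bond distance, bond
order). At most one node may be flagged as the metal center of a transition-metal
complex; metal-centered autocorrelations require it.

Depth is a graph distance:

* atom-atom depth — number of bonds on a shortest path between two atoms;
* bond-bond depth — shortest-path distance between two bonds in the line graph
  (adjacent bonds, i.e. bonds sharing an atom, are at distance 1);
* bond-atom depth — minimum over the bond's two endpoints of the atom-atom
  distance to the target atom (an endpoint atom is at depth 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Edge",
    "GraphSchemaError",
    "MolecularGraph",
    "PropertyCatalog",
    "canonical_edge",
    "read_graph",
    "write_graph",
]


class GraphSchemaError(ValueError):
    """Raised when a graph file or graph construction violates the schema."""


Edge = tuple[str, str]


def canonical_edge(u: str, v: str) -> Edge:
    """Unordered edge key: endpoints sorted lexicographically."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class PropertyCatalog:
    """Ordered lists of the atomic and bond property names a graph must carry.

    The ordering is significant: it fixes the order of blocks in every feature
    vector built from the catalog. ``catalog_id`` tags the provenance of the
    list (``generic`` for composition-style properties, ``nbo`` for
    electronic-structure-derived ones, ``custom`` otherwise); it does not
    change any computation.
    """

    atom_property_names: tuple[str, ...]
    bond_property_names: tuple[str, ...]
    catalog_id: str = "custom"

    def __post_init__(self) -> None:
        if self.catalog_id not in {"generic", "nbo", "custom"}:
            raise ValueError(f"unknown catalog_id {self.catalog_id!r}")
        for names, kind in (
            (self.atom_property_names, "atom"),
            (self.bond_property_names, "bond"),
        ):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {kind} property names in catalog")
            for name in names:
                if "-" in name or "~" in name or "_" == name[:1]:
                    raise ValueError(
                        f"property name {name!r} may not contain '-' or '~' "
                        "(reserved by the feature-label grammar)"
                    )

    @classmethod
    def generic_default(cls) -> "PropertyCatalog":
        """A small composition-style catalog (atomic number, electronegativity,
        covalent radius; bond distance, bond order). Shipped as a documented
        assumption for fixtures and synthetic data, not as a literature fact."""
        return cls(("Z", "chi", "r_cov"), ("BD", "BO"), "generic")


class MolecularGraph:
    """Undirected attributed molecular graph.

    Parameters
    ----------
    nodes
        Node ids in a stable order (file order when read from disk). The order
        is the canonical order used to break ties for ordered operators.
    edges
        Unordered node-id pairs; no self-loops or duplicates.
    atom_props
        ``{node_id: {property_name: value}}``; every node must carry every
        declared atomic property.
    bond_props
        ``{canonical edge: {property_name: value}}``.
    metal_node
        Optional id of the (single) metal center.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str]],
        atom_props: Mapping[str, Mapping[str, float]],
        bond_props: Mapping[tuple[str, str], Mapping[str, float]],
        metal_node: str | None = None,
    ) -> None:
        self.nodes: list[str] = [str(n) for n in nodes]
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphSchemaError("duplicate node ids")
        node_set = set(self.nodes)

        self.edges: list[Edge] = []
        seen: set[Edge] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphSchemaError(f"self-loop on node {u!r}")
            for w in (u, v):
                if w not in node_set:
                    raise GraphSchemaError(f"edge ({u!r}, {v!r}) references unknown node {w!r}")
            key = canonical_edge(u, v)
            if key in seen:
                raise GraphSchemaError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)
            self.edges.append(key)

        self.atom_property_names: tuple[str, ...] = _common_keys(
            {n: atom_props.get(n, {}) for n in self.nodes}, "node"
        )
        self.bond_property_names: tuple[str, ...] = _common_keys(
            {e: _lookup_edge_props(bond_props, e) for e in self.edges}, "edge"
        )
        self.atom_props: dict[str, dict[str, float]] = {
            n: {k: _finite(atom_props[n][k], f"node {n!r}", k) for k in self.atom_property_names}
            for n in self.nodes
        }
        self.bond_props: dict[Edge, dict[str, float]] = {
            e: {
                k: _finite(_lookup_edge_props(bond_props, e)[k], f"edge {e!r}", k)
                for k in self.bond_property_names
            }
            for e in self.edges
        }

        if metal_node is not None:
            metal_node = str(metal_node)
            if metal_node not in node_set:
                raise GraphSchemaError(f"metal node {metal_node!r} is not a graph node")
        self.metal_node: str | None = metal_node

        self._nx = nx.Graph()
        self._nx.add_nodes_from(self.nodes)
        self._nx.add_edges_from(self.edges)
        if len(self.nodes) == 0:
            raise GraphSchemaError("empty graph")
        if not nx.is_connected(self._nx):
            raise GraphSchemaError("graph is disconnected; shortest-path depth is undefined")

        self._atom_dist: dict[str, dict[str, int]] | None = None
        self._line: nx.Graph | None = None
        self._bond_dist: dict[Edge, dict[Edge, int]] | None = None

    # -- structure ---------------------------------------------------------

    @property
    def nx_graph(self) -> nx.Graph:
        return self._nx

    def metal_ligand_edges(self) -> list[Edge]:
        """Edges incident to the metal node, in edge order."""
        if self.metal_node is None:
            raise GraphSchemaError("graph has no metal node")
        m = self.metal_node
        return [e for e in self.edges if m in e]

    def validate_catalog(self, catalog: PropertyCatalog) -> None:
        missing_a = set(catalog.atom_property_names) - set(self.atom_property_names)
        missing_b = set(catalog.bond_property_names) - set(self.bond_property_names)
        if missing_a or missing_b:
            raise GraphSchemaError(
                f"graph lacks catalog properties: atoms {sorted(missing_a)}, bonds {sorted(missing_b)}"
            )

    # -- distances ---------------------------------------------------------

    def atom_distance(self, i: str, j: str) -> int:
        """Number of bonds on a shortest path between atoms ``i`` and ``j``."""
        table = self._atom_distances()
        try:
            return table[i][j]
        except KeyError as exc:
            raise KeyError(f"unknown node id {exc.args[0]!r}") from None

    def bond_distance(self, e1: tuple[str, str], e2: tuple[str, str]) -> int:
        """Shortest-path distance between two bonds in the line graph."""
        k1, k2 = canonical_edge(*e1), canonical_edge(*e2)
        table = self._bond_distances()
        if k1 not in table:
            raise KeyError(f"unknown edge {e1!r}")
        if k2 not in table[k1]:
            raise KeyError(f"unknown edge {e2!r}")
        return table[k1][k2]

    def bond_atom_distance(self, e: tuple[str, str], j: str) -> int:
        """Min over the bond's endpoints of the atom distance to ``j``; 0 iff
        ``j`` is an endpoint."""
        key = canonical_edge(*e)
        if key not in self.bond_props:
            raise KeyError(f"unknown edge {e!r}")
        u, v = key
        return min(self.atom_distance(u, j), self.atom_distance(v, j))

    def diameter(self) -> int:
        return max(max(row.values()) for row in self._atom_distances().values())

    def _atom_distances(self) -> dict[str, dict[str, int]]:
        if self._atom_dist is None:
            self._atom_dist = {
                src: dict(lengths)
                for src, lengths in nx.all_pairs_shortest_path_length(self._nx)
            }
        return self._atom_dist

    def line_graph(self) -> nx.Graph:
        if self._line is None:
            line = nx.Graph()
            line.add_nodes_from(self.edges)
            for u, v in nx.line_graph(self._nx).edges():
                line.add_edge(canonical_edge(*u), canonical_edge(*v))
            self._line = line
        return self._line

    def _bond_distances(self) -> dict[Edge, dict[Edge, int]]:
        if self._bond_dist is None:
            self._bond_dist = {
                src: dict(lengths)
                for src, lengths in nx.all_pairs_shortest_path_length(self.line_graph())
            }
        return self._bond_dist

    # -- misc --------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.atom_props == other.atom_props
            and self.bond_props == other.bond_props
            and self.metal_node == other.metal_node
        )

    def __repr__(self) -> str:
        metal = f", metal={self.metal_node!r}" if self.metal_node else ""
        return (
            f"MolecularGraph({len(self.nodes)} nodes, {len(self.edges)} edges{metal}, "
            f"atom_props={list(self.atom_property_names)}, bond_props={list(self.bond_property_names)})"
        )


def _common_keys(table: Mapping[object, Mapping[str, float]], kind: str) -> tuple[str, ...]:
    """Property names shared by all elements; raises if any element lacks one."""
    items = list(table.items())
    if not items:
        return ()
    first_key, first = items[0]
    names = tuple(first.keys())
    name_set = set(names)
    for key, props in items[1:]:
        missing = name_set - set(props)
        extra = set(props) - name_set
        if missing or extra:
            raise GraphSchemaError(
                f"{kind} {key!r} property mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
    return names


def _lookup_edge_props(
    bond_props: Mapping[tuple[str, str], Mapping[str, float]], e: Edge
) -> Mapping[str, float]:
    if e in bond_props:
        return bond_props[e]
    rev = (e[1], e[0])
    if rev in bond_props:
        return bond_props[rev]
    raise GraphSchemaError(f"no bond properties for edge {e!r}")


def _finite(value: object, where: str, prop: str) -> float:
    try:
        x = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise GraphSchemaError(f"{where}: property {prop!r} is not a number: {value!r}") from None
    if not np.isfinite(x):
        raise GraphSchemaError(f"{where}: property {prop!r} is not finite: {x!r}")
    return x


# ---------------------------------------------------------------------------
# I/O
#
# JSON schema:
#   {"nodes": [{"id": str, "props": {name: value}}, ...],
#    "edges": [{"u": str, "v": str, "props": {name: value}}, ...],
#    "metal": str | null}
# GML stores the same attributes via networkx, with a boolean "is_metal" node
# flag; both round-trip losslessly.
# ---------------------------------------------------------------------------


def read_graph(path: str | Path, format: str | None = None) -> MolecularGraph:
    """Read a :class:`MolecularGraph` from JSON or GML.

    ``format`` defaults to the file extension. Node order is the file order.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        return _read_json(path)
    if fmt == "gml":
        return _read_gml(path)
    raise ValueError(f"unknown graph format {fmt!r} (expected 'json' or 'gml')")


def write_graph(g: MolecularGraph, path: str | Path, format: str | None = None) -> None:
    """Write ``g`` to JSON or GML; ``read_graph`` of the output returns an
    identical graph (node order, edge order, values, metal flag)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        doc = {
            "nodes": [{"id": n, "props": self_props} for n, self_props in g.atom_props.items()],
            "edges": [
                {"u": u, "v": v, "props": g.bond_props[(u, v)]} for (u, v) in g.edges
            ],
            "metal": g.metal_node,
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif fmt == "gml":
        h = nx.Graph()
        for n in g.nodes:
            h.add_node(n, is_metal=int(n == g.metal_node), **g.atom_props[n])
        for e in g.edges:
            h.add_edge(*e, **g.bond_props[e])
        nx.write_gml(h, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r} (expected 'json' or 'gml')")


def _read_json(path: Path) -> MolecularGraph:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GraphSchemaError(f"{path}: not valid JSON: {exc}") from exc
    try:
        nodes = [str(n["id"]) for n in doc["nodes"]]
        atom_props = {str(n["id"]): dict(n.get("props", {})) for n in doc["nodes"]}
        edges = [(str(e["u"]), str(e["v"])) for e in doc["edges"]]
        bond_props = {
            canonical_edge(str(e["u"]), str(e["v"])): dict(e.get("props", {}))
            for e in doc["edges"]
        }
    except (KeyError, TypeError) as exc:
        raise GraphSchemaError(f"{path}: malformed graph document ({exc!r})") from exc
    return MolecularGraph(nodes, edges, atom_props, bond_props, doc.get("metal"))


def _read_gml(path: Path) -> MolecularGraph:
    h = nx.read_gml(path)  # nodes keyed by their original string labels
    nodes = [str(n) for n in h.nodes()]
    metal = None
    atom_props: dict[str, dict[str, float]] = {}
    for n, data in h.nodes(data=True):
        data = dict(data)
        data.pop("label", None)  # networkx bookkeeping, not a property
        if data.pop("is_metal", 0):
            metal = str(n)
        atom_props[str(n)] = data
    edges = []
    bond_props: dict[Edge, dict[str, float]] = {}
    for u, v, data in h.edges(data=True):
        edges.append((str(u), str(v)))
        bond_props[canonical_edge(str(u), str(v))] = dict(data)
    return MolecularGraph(nodes, edges, atom_props, bond_props, metal)
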