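"""Elementary Moreau-Broto-style autocorrelation kernels on attributed graphs.

Four kernels over one property, one arithmetic operator, one origin and depths
``0..D``:

* ``aa_ac`` — atom-atom: combine the property values of atom pairs at each
  shortest-path distance (the classical Moreau-Broto autocorrelation);
* ``bb_ac`` — bond-bond: same over bond pairs at each line-graph distance; in
  metal-centered mode the origin is a "super-bond" merging all metal-ligand
  bonds by sum or mean;
* ``ba_ac`` — bond-atom: combine a bond property with an atom property over
  (bond, atom) pairs at each bond-atom distance.

Operators: product (the default autocorrelation), deltametric (difference),
ratiometric (ratio) and summetric (sum). Product and summetric are symmetric;
deltametric and ratiometric put the origin-side value first.

Full-scope conventions: each unordered pair contributes once, with the element
earlier in the graph's stored order on the origin side; depth 0 collects one
self-term per origin element. Depths beyond the last populated shell are empty
sums and contribute 0.0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .graph_model import Edge, MolecularGraph, canonical_edge

__all__ = [
    "AutocorrConfigError",
    "DepthProfile",
    "DivideByZeroError",
    "Operator",
    "Origin",
    "aa_ac",
    "apply_operator",
    "ba_ac",
    "bb_ac",
    "super_bond",
]


class AutocorrConfigError(ValueError):
    """Invalid kernel configuration (e.g. metal-centered mode without a metal)."""


class DivideByZeroError(ZeroDivisionError):
    """Ratiometric operator hit a zero divisor."""


class Operator(str, enum.Enum):
    """Arithmetic pair operator. ``code`` is the single letter used in feature
    labels (A = product/autocorrelation, D = deltametric, R = ratiometric,
    S = summetric)."""

    product = "product"
    deltametric = "deltametric"
    ratiometric = "ratiometric"
    summetric = "summetric"

    @property
    def code(self) -> str:
        return {"product": "A", "deltametric": "D", "ratiometric": "R", "summetric": "S"}[
            self.value
        ]

    @property
    def symmetric(self) -> bool:
        return self in (Operator.product, Operator.summetric)

    @classmethod
    def from_code(cls, code: str) -> "Operator":
        table = {"A": cls.product, "D": cls.deltametric, "R": cls.ratiometric, "S": cls.summetric}
        try:
            return table[code]
        except KeyError:
            raise ValueError(f"unknown operator code {code!r}") from None


class Origin(str, enum.Enum):
    """Origin scope of the walk: every element (full) or only the metal node /
    metal-ligand super-bond (metal_centered)."""

    full = "full"
    metal_centered = "metal_centered"

    @property
    def code(self) -> str:
        return "F" if self is Origin.full else "M"

    @classmethod
    def from_code(cls, code: str) -> "Origin":
        if code == "F":
            return cls.full
        if code == "M":
            return cls.metal_centered
        raise ValueError(f"unknown origin code {code!r}")


@dataclass(frozen=True)
class DepthProfile:
    """Per-depth autocorrelation sums, index = depth 0..D."""

    values: tuple[float, ...]

    @property
    def max_depth(self) -> int:
        return len(self.values) - 1

    def __getitem__(self, depth: int) -> float:
        return self.values[depth]

    def __len__(self) -> int:
        return len(self.values)


def apply_operator(
    op: Operator, a: float, b: float, *, skip_zero_division: bool = False, context: str = ""
) -> float:
    """Combine an origin-side value ``a`` with a partner value ``b``.

    ``ratiometric`` divides ``a / b``; a zero ``b`` raises
    :class:`DivideByZeroError` unless ``skip_zero_division`` is set, in which
    case the term contributes 0.0.
    """
    if op is Operator.product:
        return a * b
    if op is Operator.deltametric:
        return a - b
    if op is Operator.summetric:
        return a + b
    if op is Operator.ratiometric:
        if b == 0.0:
            if skip_zero_division:
                return 0.0
            where = f" in {context}" if context else ""
            raise DivideByZeroError(f"ratiometric divisor is zero{where}")
        return a / b
    raise TypeError(f"unknown operator {op!r}")


def _profile(bins: np.ndarray) -> DepthProfile:
    return DepthProfile(tuple(float(x) for x in bins))


def aa_ac(
    g: MolecularGraph,
    prop: str,
    op: Operator,
    origin: Origin,
    max_depth: int,
    *,
    skip_zero_division: bool = False,
) -> DepthProfile:
    """Atom-atom autocorrelation of atomic property ``prop`` to ``max_depth``.

    Full origin: depth 0 sums ``op(p_i, p_i)`` over all atoms; depth d >= 1
    sums ``op(p_i, p_j)`` once per unordered pair at distance d, the atom
    earlier in node order first. Metal-centered origin: the metal is the sole
    origin atom.
    """
    _check_depth(max_depth)
    if prop not in g.atom_property_names:
        raise AutocorrConfigError(f"atomic property {prop!r} not declared on graph")
    p = {n: g.atom_props[n][prop] for n in g.nodes}
    ctx = f"AA {op.value} of {prop!r}"
    bins = np.zeros(max_depth + 1)

    if origin is Origin.metal_centered:
        m = _require_metal(g)
        for j in g.nodes:
            d = g.atom_distance(m, j)
            if d <= max_depth:
                bins[d] += apply_operator(
                    op, p[m], p[j], skip_zero_division=skip_zero_division, context=ctx
                )
    else:
        nodes = g.nodes
        for a_idx, i in enumerate(nodes):
            bins[0] += apply_operator(
                op, p[i], p[i], skip_zero_division=skip_zero_division, context=ctx
            )
            for j in nodes[a_idx + 1 :]:
                d = g.atom_distance(i, j)
                if 1 <= d <= max_depth:
                    bins[d] += apply_operator(
                        op, p[i], p[j], skip_zero_division=skip_zero_division, context=ctx
                    )
    return _profile(bins)


def super_bond(g: MolecularGraph, merge: str) -> dict[str, float]:
    """Merged property vector of all metal-ligand bonds (``merge`` in
    {'sum', 'mean'})."""
    if merge not in {"sum", "mean"}:
        raise AutocorrConfigError(f"super-bond merge must be 'sum' or 'mean', got {merge!r}")
    ml = g.metal_ligand_edges()
    if not ml:
        raise AutocorrConfigError("metal-centered bond origin requires metal-ligand edges")
    out: dict[str, float] = {}
    for name in g.bond_property_names:
        total = sum(g.bond_props[e][name] for e in ml)
        out[name] = total / len(ml) if merge == "mean" else total
    return out


def metal_bond_depths(g: MolecularGraph) -> dict[Edge, int]:
    """Depth of every edge relative to the metal-ligand super-bond.

    Metal-ligand edges are depth 0 (they form the super-bond); any other edge
    sits at its line-graph distance to the nearest metal-ligand edge, so the
    first shell of ligand-internal bonds is depth 1.
    """
    ml = set(g.metal_ligand_edges())
    depths: dict[Edge, int] = {}
    for e in g.edges:
        if e in ml:
            depths[e] = 0
        else:
            depths[e] = min(g.bond_distance(e, m) for m in ml)
    return depths


def bb_ac(
    g: MolecularGraph,
    prop: str,
    op: Operator,
    origin: Origin,
    merge: str,
    max_depth: int,
    *,
    skip_zero_division: bool = False,
) -> DepthProfile:
    """Bond-bond autocorrelation of bond property ``prop``.

    Full origin (``merge='none'``): depth d sums ``op(q_e, q_f)`` over
    unordered bond pairs at line-graph distance d (depth 0 = self-terms).
    Metal-centered origin (``merge`` in {'sum', 'mean'}): the super-bond is
    the sole origin; depth 0 is its self-term and depth d >= 1 sums
    ``op(q_superbond, q_e)`` over non-metal bonds in the d-th shell.
    """
    _check_depth(max_depth)
    if prop not in g.bond_property_names:
        raise AutocorrConfigError(f"bond property {prop!r} not declared on graph")
    ctx = f"BB {op.value} of {prop!r}"
    q = {e: g.bond_props[e][prop] for e in g.edges}
    bins = np.zeros(max_depth + 1)

    if origin is Origin.metal_centered:
        _require_metal(g)
        if merge not in {"sum", "mean"}:
            raise AutocorrConfigError(
                "metal-centered bond-bond autocorrelation requires merge 'sum' or 'mean'"
            )
        sb = super_bond(g, merge)[prop]
        bins[0] = apply_operator(op, sb, sb, skip_zero_division=skip_zero_division, context=ctx)
        depths = metal_bond_depths(g)
        for e, d in depths.items():
            if 1 <= d <= max_depth:
                bins[d] += apply_operator(
                    op, sb, q[e], skip_zero_division=skip_zero_division, context=ctx
                )
    else:
        if merge != "none":
            raise AutocorrConfigError("full-origin bond-bond autocorrelation requires merge='none'")
        edges = g.edges
        for a_idx, e in enumerate(edges):
            bins[0] += apply_operator(
                op, q[e], q[e], skip_zero_division=skip_zero_division, context=ctx
            )
            for f in edges[a_idx + 1 :]:
                d = g.bond_distance(e, f)
                if 1 <= d <= max_depth:
                    bins[d] += apply_operator(
                        op, q[e], q[f], skip_zero_division=skip_zero_division, context=ctx
                    )
    return _profile(bins)


def ba_ac(
    g: MolecularGraph,
    bond_prop: str,
    atom_prop: str,
    op: Operator,
    origin: Origin,
    max_depth: int,
    *,
    skip_zero_division: bool = False,
) -> DepthProfile:
    """Bond-atom autocorrelation crossing ``bond_prop`` with ``atom_prop``.

    Depth d sums ``op(q_e, p_j)`` (bond side first) over all (bond e, atom j)
    pairs at bond-atom distance d; metal-centered mode restricts e to the
    metal-ligand bonds.
    """
    _check_depth(max_depth)
    if bond_prop not in g.bond_property_names:
        raise AutocorrConfigError(f"bond property {bond_prop!r} not declared on graph")
    if atom_prop not in g.atom_property_names:
        raise AutocorrConfigError(f"atomic property {atom_prop!r} not declared on graph")
    ctx = f"BA {op.value} of {bond_prop!r} x {atom_prop!r}"
    if origin is Origin.metal_centered:
        _require_metal(g)
        edges = g.metal_ligand_edges()
        if not edges:
            raise AutocorrConfigError("metal-centered bond-atom origin requires metal-ligand edges")
    else:
        edges = g.edges

    bins = np.zeros(max_depth + 1)
    for e in edges:
        q_e = g.bond_props[e][bond_prop]
        for j in g.nodes:
            d = g.bond_atom_distance(e, j)
            if d <= max_depth:
                bins[d] += apply_operator(
                    op,
                    q_e,
                    g.atom_props[j][atom_prop],
                    skip_zero_division=skip_zero_division,
                    context=ctx,
                )
    return _profile(bins)


def _require_metal(g: MolecularGraph) -> str:
    if g.metal_node is None:
        raise AutocorrConfigError("metal-centered origin requires a graph with a metal node")
    return g.metal_node


def _check_depth(max_depth: int) -> None:
    if max_depth < 0:
        raise AutocorrConfigError(f"max_depth must be >= 0, got {max_depth}")
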