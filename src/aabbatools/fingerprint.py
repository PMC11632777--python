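"""Assembly of labeled AABBA fingerprint vectors from elementary autocorrelations.

AABBA(I) concatenates atom-atom (AA), bond-bond (BB, and its averaged
super-bond flavor BBm), and bond-atom (BA) autocorrelation blocks into one
fixed-length labeled vector. AABBA(II) first merges the endpoint atomic
properties and the bond properties of every edge into a per-edge "atom-bond"
vector and then autocorrelates those vectors exactly like BB.

Every dimension carries a label with the grammar

    <prop>-<depth>_<origin><operator>_<kernel>

where origin is ``M`` (metal-centered) or ``F`` (full), operator is ``A``
(product), ``D`` (deltametric), ``R`` (ratiometric) or ``S`` (summetric), and
kernel is ``AA``, ``BB``, ``BBm`` (averaged super-bond; rendered BB̅ in
reports), ``BA``, ``II1``..``II5`` or ``WG`` (whole-graph extras). BA crosses
a bond property with an atomic property; its ``<prop>`` field is
``<bond>~<atom>``. Example: ``Z-2_FA_AA`` is the full atom-atom
autocorrelation of atomic number at depth 2.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .autocorr import (
    AutocorrConfigError,
    Operator,
    Origin,
    aa_ac,
    ba_ac,
    bb_ac,
)
from .graph_model import MolecularGraph, PropertyCatalog, canonical_edge

__all__ = [
    "AutocorrSpec",
    "FeatureVector",
    "LabelError",
    "MergeRecipe",
    "aabba_one",
    "aabba_two",
    "compute_block",
    "featurize_dataset",
    "format_label",
    "maximal_vector",
    "maximal_specs",
    "maximal_length",
    "merge_edge_properties",
    "merge_recipe",
    "parse_label",
    "read_feature_matrix",
    "remove_redundant",
    "whole_graph_block",
    "write_feature_matrix",
]

KERNELS = ("AA", "BB", "BBm", "BA")
_LABEL_KERNELS = KERNELS + ("II1", "II2", "II3", "II4", "II5", "WG")


class LabelError(ValueError):
    """Malformed feature label."""


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureDescriptor:
    prop: str
    depth: int
    origin: Origin
    operator: Operator
    kernel: str


def format_label(
    prop: str, depth: int, origin: Origin, operator: Operator, kernel: str
) -> str:
    if kernel not in _LABEL_KERNELS:
        raise LabelError(f"unknown kernel token {kernel!r}")
    return f"{prop}-{depth}_{origin.code}{operator.code}_{kernel}"


_LABEL_RE = re.compile(
    r"^(?P<prop>.+)-(?P<depth>\d+)_(?P<origin>[MF])(?P<op>[ADRS])_(?P<kernel>\w+)$"
)


def parse_label(label: str) -> FeatureDescriptor:
    m = _LABEL_RE.match(label)
    if m is None:
        # locate the first structurally broken separator for the error message
        pos = label.rfind("_")
        raise LabelError(f"cannot parse feature label {label!r} (near position {max(pos, 0)})")
    kernel = m.group("kernel")
    if kernel not in _LABEL_KERNELS:
        raise LabelError(f"unknown kernel token {kernel!r} in label {label!r}")
    return FeatureDescriptor(
        prop=m.group("prop"),
        depth=int(m.group("depth")),
        origin=Origin.from_code(m.group("origin")),
        operator=Operator.from_code(m.group("op")),
        kernel=kernel,
    )


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """Fixed-length labeled feature vector; labels are unique."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.labels):
            raise ValueError("values and labels must be 1-D and the same length")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise AutocorrConfigError(f"duplicate feature labels: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.labels)

    @staticmethod
    def concat(blocks: Sequence["FeatureVector"]) -> "FeatureVector":
        values = np.concatenate([b.values for b in blocks]) if blocks else np.empty(0)
        labels = [l for b in blocks for l in b.labels]
        return FeatureVector(values, labels)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.labels)


# ---------------------------------------------------------------------------
# AABBA(I)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AutocorrSpec:
    """One autocorrelation block: a kernel, the properties it runs over, an
    operator, an origin and a maximum depth.

    ``properties`` holds atomic property names for AA, bond property names for
    BB/BBm, and ``(bond_prop, atom_prop)`` pairs for BA. BBm (averaged
    super-bond) exists only metal-centered; metal-centered BB uses the summed
    super-bond.
    """

    kernel: str
    properties: tuple
    operator: Operator
    origin: Origin
    max_depth: int

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise AutocorrConfigError(f"unknown kernel {self.kernel!r}")
        if not self.properties:
            raise AutocorrConfigError("spec has an empty property list")
        if self.kernel == "BBm" and self.origin is not Origin.metal_centered:
            raise AutocorrConfigError("BBm (averaged super-bond) requires the metal-centered origin")
        if self.max_depth < 0:
            raise AutocorrConfigError("max_depth must be >= 0")
        if self.kernel == "BA":
            for p in self.properties:
                if not (isinstance(p, tuple) and len(p) == 2):
                    raise AutocorrConfigError(
                        "BA properties must be (bond_prop, atom_prop) pairs"
                    )


def _block_label_prop(kernel: str, prop) -> str:
    return f"{prop[0]}~{prop[1]}" if kernel == "BA" else str(prop)


def compute_block(
    g: MolecularGraph, spec: AutocorrSpec, *, skip_zero_division: bool = False
) -> FeatureVector:
    """Depth profiles of one spec, concatenated property-major and labeled."""
    values: list[float] = []
    labels: list[str] = []
    for prop in spec.properties:
        if spec.kernel == "AA":
            profile = aa_ac(
                g, prop, spec.operator, spec.origin, spec.max_depth,
                skip_zero_division=skip_zero_division,
            )
        elif spec.kernel in ("BB", "BBm"):
            if spec.origin is Origin.metal_centered:
                merge = "mean" if spec.kernel == "BBm" else "sum"
            else:
                merge = "none"
            profile = bb_ac(
                g, prop, spec.operator, spec.origin, merge, spec.max_depth,
                skip_zero_division=skip_zero_division,
            )
        else:  # BA
            bond_prop, atom_prop = prop
            profile = ba_ac(
                g, bond_prop, atom_prop, spec.operator, spec.origin, spec.max_depth,
                skip_zero_division=skip_zero_division,
            )
        name = _block_label_prop(spec.kernel, prop)
        for depth, value in enumerate(profile.values):
            values.append(value)
            labels.append(format_label(name, depth, spec.origin, spec.operator, spec.kernel))
    return FeatureVector(np.array(values), labels)


def aabba_one(
    g: MolecularGraph, specs: Sequence[AutocorrSpec], *, skip_zero_division: bool = False
) -> FeatureVector:
    """AABBA(I): the concatenation of every spec's block, in spec order."""
    if not specs:
        raise AutocorrConfigError("aabba_one requires at least one spec")
    return FeatureVector.concat(
        [compute_block(g, s, skip_zero_division=skip_zero_division) for s in specs]
    )


# ---------------------------------------------------------------------------
# AABBA(II)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MergeRecipe:
    """How to merge each edge's endpoint atomic properties with its bond
    properties into one per-edge vector.

    * ``atom_means`` — combined by the endpoint mean, component name kept;
    * ``atom_absdiffs`` — combined by |p_i - p_j| (polarity-style component),
      component named ``<prop>.d``;
    * ``geometry`` — optional geometry component named ``geom``: either
      ``('bond_prop', name)`` (a bond property such as the bond distance) or
      ``('radius_sum', name)`` (the sum of an atomic radius-like property over
      the endpoints, geometry-agnostic);
    * ``bond_props`` — bond properties appended as-is.
    """

    atom_means: tuple[str, ...] = ()
    atom_absdiffs: tuple[str, ...] = ()
    geometry: tuple[str, str] | None = None
    bond_props: tuple[str, ...] = ()

    def component_names(self) -> list[str]:
        names = [*self.atom_means, *(f"{p}.d" for p in self.atom_absdiffs)]
        if self.geometry is not None:
            names.append("geom")
        names.extend(self.bond_props)
        if len(set(names)) != len(names):
            raise AutocorrConfigError(f"merge recipe yields duplicate component names: {names}")
        if not names:
            raise AutocorrConfigError("merge recipe selects no components")
        return names


VARIANTS = ("II1", "II2", "II3", "II4", "II5")


def merge_recipe(
    variant: str,
    catalog: PropertyCatalog,
    *,
    electronegativity: str | None = "chi",
    radius: str | None = "r_cov",
    distance_bond_prop: str | None = "BD",
) -> MergeRecipe:
    """Shipped default recipe for an AABBA(II) variant against a catalog.

    The five variants differ in their electronegativity and geometry
    components: II1 keeps the endpoint-mean electronegativity and uses the
    bond distance as geometry; II2 drops the geometry component; II3 replaces
    it with the covalent-radius sum (geometry-agnostic); II4 and II5 are
    subset variants intended for electronic-structure catalogs — their
    defaults here take all atomic properties (means) with, respectively, all
    or none of the bond properties. All recipes are plain configuration
    objects; callers with specific property sets should build their own
    :class:`MergeRecipe`.
    """
    if variant not in VARIANTS:
        raise AutocorrConfigError(f"unknown AABBA(II) variant {variant!r}")
    atoms = list(catalog.atom_property_names)
    bonds = list(catalog.bond_property_names)

    def present(name: str | None, pool: list[str]) -> str | None:
        return name if name is not None and name in pool else None

    chi = present(electronegativity, atoms)
    rad = present(radius, atoms)
    dist = present(distance_bond_prop, bonds)

    if variant in ("II1", "II2", "II3"):
        means = tuple(a for a in atoms if a != chi)
        absdiffs = (chi,) if chi else ()
        means = ((chi,) if chi else ()) + tuple(a for a in means if a != rad or variant != "II3")
        # II1/II2 keep the mean electronegativity; the absolute difference is
        # the polarity component added alongside it.
        geometry: tuple[str, str] | None
        if variant == "II1":
            geometry = ("bond_prop", dist) if dist else None
        elif variant == "II2":
            geometry = None
        else:
            geometry = ("radius_sum", rad) if rad else None
        bond_sel = tuple(b for b in bonds if b != dist)
        return MergeRecipe(means, absdiffs, geometry, bond_sel)
    if variant == "II4":
        return MergeRecipe(tuple(atoms), (), None, tuple(bonds))
    return MergeRecipe(tuple(atoms), (), None, ())


def merge_edge_properties(
    g: MolecularGraph, recipe: MergeRecipe
) -> dict[tuple[str, str], dict[str, float]]:
    """Per-edge merged atom-bond property vectors (same components for every
    edge)."""
    for p in (*recipe.atom_means, *recipe.atom_absdiffs):
        if p not in g.atom_property_names:
            raise AutocorrConfigError(f"merge recipe references unknown atomic property {p!r}")
    for b in recipe.bond_props:
        if b not in g.bond_property_names:
            raise AutocorrConfigError(f"merge recipe references unknown bond property {b!r}")
    if recipe.geometry is not None:
        mode, name = recipe.geometry
        if mode == "bond_prop" and name not in g.bond_property_names:
            raise AutocorrConfigError(f"geometry bond property {name!r} not on graph")
        if mode == "radius_sum" and name not in g.atom_property_names:
            raise AutocorrConfigError(f"geometry radius property {name!r} not on graph")
        if mode not in ("bond_prop", "radius_sum"):
            raise AutocorrConfigError(f"unknown geometry mode {mode!r}")
    recipe.component_names()

    merged: dict[tuple[str, str], dict[str, float]] = {}
    for (u, v) in g.edges:
        pi, pj = g.atom_props[u], g.atom_props[v]
        vec: dict[str, float] = {}
        for p in recipe.atom_means:
            vec[p] = 0.5 * (pi[p] + pj[p])
        for p in recipe.atom_absdiffs:
            vec[f"{p}.d"] = abs(pi[p] - pj[p])
        if recipe.geometry is not None:
            mode, name = recipe.geometry
            if mode == "bond_prop":
                vec["geom"] = g.bond_props[(u, v)][name]
            else:
                vec["geom"] = pi[name] + pj[name]
        for b in recipe.bond_props:
            vec[b] = g.bond_props[(u, v)][b]
        merged[(u, v)] = vec
    return merged


def _with_merged_bond_table(
    g: MolecularGraph, merged: dict[tuple[str, str], dict[str, float]]
) -> MolecularGraph:
    return MolecularGraph(g.nodes, g.edges, g.atom_props, merged, g.metal_node)


def aabba_two(
    g: MolecularGraph,
    variant: str,
    recipe: MergeRecipe,
    operator: Operator,
    origin: Origin,
    max_depth: int,
    *,
    merge: str | None = None,
    skip_zero_division: bool = False,
) -> FeatureVector:
    """AABBA(II): bond-bond autocorrelation of the merged per-edge vectors.

    Component-wise identical to running ``bb_ac`` on a graph whose bond table
    is replaced by the merged vectors. Metal-centered origin merges the
    metal-ligand edges into a super-bond (``merge`` defaults to 'sum').
    """
    if variant not in VARIANTS:
        raise AutocorrConfigError(f"unknown AABBA(II) variant {variant!r}")
    merged = merge_edge_properties(g, recipe)
    h = _with_merged_bond_table(g, merged)
    if merge is None:
        merge = "sum" if origin is Origin.metal_centered else "none"
    values: list[float] = []
    labels: list[str] = []
    for comp in recipe.component_names():
        profile = bb_ac(
            h, comp, operator, origin, merge, max_depth,
            skip_zero_division=skip_zero_division,
        )
        for depth, value in enumerate(profile.values):
            values.append(value)
            labels.append(format_label(comp, depth, origin, operator, variant))
    return FeatureVector(np.array(values), labels)


# ---------------------------------------------------------------------------
# Maximal-dimensionality vector
# ---------------------------------------------------------------------------

MAXIMAL_DEPTH = 6


def maximal_specs(
    catalog: PropertyCatalog, *, with_metal: bool = True, max_depth: int = MAXIMAL_DEPTH
) -> list[AutocorrSpec]:
    """The deterministic spec list behind the maximal-dimensionality vector:
    every kernel x origin x operator combination at depths 0..``max_depth``.

    Without a metal only the full-origin AA/BB/BA blocks exist (BBm and all
    metal-centered blocks require the metal flag).
    """
    atoms = tuple(catalog.atom_property_names)
    bonds = tuple(catalog.bond_property_names)
    ba_pairs = tuple((b, a) for b in bonds for a in atoms)
    origins = [Origin.full] + ([Origin.metal_centered] if with_metal else [])
    specs: list[AutocorrSpec] = []
    for kernel, props in (("AA", atoms), ("BB", bonds), ("BBm", bonds), ("BA", ba_pairs)):
        if not props:
            continue
        for origin in origins:
            if kernel == "BBm" and origin is not Origin.metal_centered:
                continue
            for op in Operator:
                specs.append(AutocorrSpec(kernel, props, op, origin, max_depth))
    return specs


def maximal_length(
    catalog: PropertyCatalog, *, with_metal: bool = True, max_depth: int = MAXIMAL_DEPTH
) -> int:
    """Closed-form length of the maximal vector: 4 operators x (depth+1) x
    (2a + 3b + 2ab) with a metal, or x (a + b + ab) without, for a atomic and
    b bond properties."""
    a = len(catalog.atom_property_names)
    b = len(catalog.bond_property_names)
    d = max_depth + 1
    per_op = (2 * a + 3 * b + 2 * a * b) if with_metal else (a + b + a * b)
    return 4 * d * per_op


def maximal_vector(
    g: MolecularGraph, catalog: PropertyCatalog, *, max_depth: int = MAXIMAL_DEPTH,
    skip_zero_division: bool = False,
) -> FeatureVector:
    """The maximal-dimensionality AABBA(I) vector (before redundancy removal):
    all kernels, both origins, all four operators, depths 0..6."""
    g.validate_catalog(catalog)
    specs = maximal_specs(catalog, with_metal=g.metal_node is not None, max_depth=max_depth)
    return aabba_one(g, specs, skip_zero_division=skip_zero_division)


def whole_graph_block(g: MolecularGraph, catalog: PropertyCatalog) -> FeatureVector:
    """Optional whole-graph extras: node count, edge count and per-property
    sums, labeled under the ``WG`` kernel token."""
    g.validate_catalog(catalog)
    values = [float(len(g.nodes)), float(len(g.edges))]
    labels = [
        format_label("natoms", 0, Origin.full, Operator.product, "WG"),
        format_label("nbonds", 0, Origin.full, Operator.product, "WG"),
    ]
    for p in catalog.atom_property_names:
        values.append(sum(g.atom_props[n][p] for n in g.nodes))
        labels.append(format_label(f"sum.{p}", 0, Origin.full, Operator.summetric, "WG"))
    for b in catalog.bond_property_names:
        values.append(sum(g.bond_props[e][b] for e in g.edges))
        labels.append(format_label(f"sum.{b}", 0, Origin.full, Operator.summetric, "WG"))
    return FeatureVector(np.array(values), labels)


# ---------------------------------------------------------------------------
# Dataset-level features
# ---------------------------------------------------------------------------


def featurize_dataset(
    graphs: Sequence[MolecularGraph],
    specs: Sequence[AutocorrSpec],
    *,
    ids: Sequence[str] | None = None,
    skip_zero_division: bool = False,
) -> pd.DataFrame:
    """Feature matrix: one row per graph, columns labeled per the grammar."""
    rows = [aabba_one(g, specs, skip_zero_division=skip_zero_division) for g in graphs]
    labels = rows[0].labels if rows else []
    for fv in rows[1:]:
        if fv.labels != labels:
            raise AutocorrConfigError("graphs produced inconsistent feature labels")
    index = list(ids) if ids is not None else [f"g{i:05d}" for i in range(len(rows))]
    return pd.DataFrame([fv.values for fv in rows], index=index, columns=labels)


def remove_redundant(
    features: pd.DataFrame, *, sig_digits: int = 12
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Drop columns that are constant across the dataset or exact duplicates
    of an earlier column (first occurrence kept; order otherwise preserved).

    Equality is exact after canonical rounding to ``sig_digits`` significant
    digits, which makes the reduction reproducible across writers/readers.
    Returns (reduced matrix, kept labels, dropped labels).
    """
    if len(features) < 2:
        raise ValueError("redundancy removal needs at least 2 rows")

    def canonical(col: np.ndarray) -> tuple:
        out = []
        for x in col:
            if x == 0.0 or not np.isfinite(x):
                out.append(float(x) if np.isfinite(x) else x)
            else:
                out.append(float(np.format_float_scientific(x, precision=sig_digits - 1)))
        return tuple(out)

    kept: list[str] = []
    dropped: list[str] = []
    seen: dict[tuple, str] = {}
    for label in features.columns:
        key = canonical(features[label].to_numpy())
        if len(set(key)) == 1:  # constant across the dataset
            dropped.append(label)
            continue
        if key in seen:
            dropped.append(label)
            continue
        seen[key] = label
        kept.append(label)
    return features[kept], kept, dropped


def write_feature_matrix(
    features: pd.DataFrame,
    path: str | Path,
    *,
    metadata: dict | None = None,
) -> None:
    """Write features as CSV plus a ``<path>.meta.json`` sidecar holding the
    labels and any run metadata (catalog, specs, kept/dropped columns)."""
    path = Path(path)
    features.to_csv(path, index_label="graph_id", float_format="%.17g")
    sidecar = {"labels": list(features.columns), "n_rows": int(len(features))}
    if metadata:
        sidecar.update(metadata)
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="graph_id").rename_axis(None)
    return df.astype(float)
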