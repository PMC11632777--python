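import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aabbatools.autocorr import AutocorrConfigError, Operator, Origin, bb_ac
from aabbatools.fingerprint import (
    AutocorrSpec,
    FeatureVector,
    LabelError,
    MergeRecipe,
    aabba_one,
    aabba_two,
    compute_block,
    featurize_dataset,
    format_label,
    maximal_length,
    maximal_specs,
    maximal_vector,
    merge_edge_properties,
    merge_recipe,
    parse_label,
    read_feature_matrix,
    remove_redundant,
    whole_graph_block,
    write_feature_matrix,
)
from aabbatools.graph_model import MolecularGraph, PropertyCatalog
from conftest import make_graph, random_connected_graph


@pytest.fixture
def toy_catalog():
    return PropertyCatalog(("Z", "chi"), ("BO",), "custom")


def rich_graph(metal="B"):
    """A-B-C with a two-atom, one-bond catalog."""
    return make_graph(
        ["A", "B", "C"], [("A", "B"), ("B", "C")],
        p={"A": [1.0, 2.1], "B": [3.0, 0.9], "C": [2.0, 3.3]},
        q={("A", "B"): [1.5], ("B", "C"): [0.5]},
        metal=metal, atom_names=("Z", "chi"), bond_names=("BO",),
    )


class TestLabels:
    @pytest.mark.parametrize(
        "args,expected",
        [
            (("Z", 2, Origin.full, Operator.product, "AA"), "Z-2_FA_AA"),
            (("q_Nat", 1, Origin.metal_centered, Operator.ratiometric, "BA"), "q_Nat-1_MR_BA"),
            (("BD", 0, Origin.metal_centered, Operator.summetric, "BBm"), "BD-0_MS_BBm"),
        ],
    )
    def test_format(self, args, expected):
        assert format_label(*args) == expected

    @given(
        prop=st.from_regex(r"[A-Za-z][A-Za-z0-9_.]{0,8}", fullmatch=True),
        depth=st.integers(0, 9),
        origin=st.sampled_from(list(Origin)),
        op=st.sampled_from(list(Operator)),
        kernel=st.sampled_from(["AA", "BB", "BBm", "BA", "II3", "WG"]),
    )
    def test_round_trip(self, prop, depth, origin, op, kernel):
        d = parse_label(format_label(prop, depth, origin, op, kernel))
        assert (d.prop, d.depth, d.origin, d.operator, d.kernel) == (prop, depth, origin, op, kernel)

    @pytest.mark.parametrize("bad", ["Z_FA_AA", "Z-1_XA_AA", "Z-1_FA_QQ", "", "Z-x_FA_AA"])
    def test_malformed(self, bad):
        with pytest.raises(LabelError):
            parse_label(bad)


class TestComputeBlock:
    def test_aa_block_values_and_labels(self, path_abc):
        spec = AutocorrSpec("AA", ("p",), Operator.product, Origin.full, 1)
        fv = compute_block(path_abc, spec)
        assert fv.labels == ["p-0_FA_AA", "p-1_FA_AA"]
        np.testing.assert_allclose(fv.values, [14.0, 8.0])

    def test_empty_property_list_rejected(self):
        with pytest.raises(AutocorrConfigError, match="empty"):
            AutocorrSpec("AA", (), Operator.product, Origin.full, 1)

    def test_metal_self_term(self, path_abc):
        spec = AutocorrSpec("AA", ("p",), Operator.product, Origin.metal_centered, 0)
        fv = compute_block(path_abc, spec)
        assert fv.values.tolist() == [4.0] and fv.labels == ["p-0_MA_AA"]

    def test_bbm_requires_metal_centered(self):
        with pytest.raises(AutocorrConfigError, match="metal-centered"):
            AutocorrSpec("BBm", ("q",), Operator.product, Origin.full, 1)


class TestAabbaOne:
    def test_concatenation_of_blocks(self, path_abc):
        specs = [
            AutocorrSpec("AA", ("p",), Operator.product, Origin.full, 1),
            AutocorrSpec("BBm", ("q",), Operator.product, Origin.metal_centered, 1),
            AutocorrSpec("BA", (("q", "p"),), Operator.product, Origin.metal_centered, 0),
        ]
        fv = aabba_one(path_abc, specs)
        blocks = [compute_block(path_abc, s) for s in specs]
        assert len(fv) == sum(len(b) for b in blocks)
        np.testing.assert_array_equal(fv.values, np.concatenate([b.values for b in blocks]))
        assert fv.labels == [l for b in blocks for l in b.labels]

    def test_duplicate_labels_rejected(self, path_abc):
        spec = AutocorrSpec("AA", ("p",), Operator.product, Origin.full, 1)
        with pytest.raises(AutocorrConfigError, match="duplicate"):
            aabba_one(path_abc, [spec, spec])

    def test_node_order_permutation_invariance(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, n_max=8)
            perm = rng.permutation(len(g.nodes))
            h = MolecularGraph(
                [g.nodes[i] for i in perm], g.edges, g.atom_props, g.bond_props, g.metal_node
            )
            specs = [
                AutocorrSpec("AA", ("p",), Operator.product, Origin.full, 3),
                AutocorrSpec("BB", ("q",), Operator.summetric, Origin.full, 3),
                AutocorrSpec("BA", (("q", "p"),), Operator.product, Origin.metal_centered, 2),
            ]
            np.testing.assert_allclose(
                aabba_one(g, specs).values, aabba_one(h, specs).values, rtol=1e-12
            )


class TestMergeEdgeProperties:
    def test_mean_combine(self):
        g = make_graph(
            ["A", "B"], [("A", "B")],
            p={"A": [1.0], "B": [3.0]}, q={("A", "B"): [2.0]},
            atom_names=("Z",), bond_names=("order",),
        )
        merged = merge_edge_properties(g, MergeRecipe(atom_means=("Z",), bond_props=("order",)))
        assert merged[("A", "B")] == {"Z": 2.0, "order": 2.0}

    def test_identical_endpoints_zero_polarity(self):
        g = make_graph(["A", "B"], [("A", "B")], p={"A": [1.7], "B": [1.7]},
                       q={("A", "B"): [1.0]}, atom_names=("chi",), bond_names=("q",))
        merged = merge_edge_properties(g, MergeRecipe(atom_absdiffs=("chi",)))
        assert merged[("A", "B")]["chi.d"] == 0.0

    def test_covalent_radius_sum_geometry(self):
        g = make_graph(["A", "B"], [("A", "B")], p={"A": [0.7], "B": [0.3]},
                       q={("A", "B"): [1.0]}, atom_names=("r_cov",), bond_names=("q",))
        recipe = merge_recipe("II3", PropertyCatalog(("r_cov",), ("q",)),
                              electronegativity=None, radius="r_cov", distance_bond_prop=None)
        merged = merge_edge_properties(g, recipe)
        assert merged[("A", "B")]["geom"] == pytest.approx(1.0)

    def test_missing_property_rejected(self, path_abc):
        with pytest.raises(AutocorrConfigError, match="unknown atomic property"):
            merge_edge_properties(path_abc, MergeRecipe(atom_means=("zzz",)))


class TestAabbaTwo:
    def test_single_edge_full_product_is_squares(self):
        g = make_graph(["A", "B"], [("A", "B")], p={"A": [1.0], "B": [3.0]},
                       q={("A", "B"): [2.0]}, atom_names=("Z",), bond_names=("BO",))
        recipe = MergeRecipe(atom_means=("Z",), bond_props=("BO",))
        fv = aabba_two(g, "II1", recipe, Operator.product, Origin.full, 0)
        # merged vector (Z=2, BO=2); one self-term per component
        assert fv.labels == ["Z-0_FA_II1", "BO-0_FA_II1"]
        np.testing.assert_allclose(fv.values, [4.0, 4.0])

    def test_equals_bb_on_merged_bond_table(self, rng):
        """Strict equivalence: AABBA(II) == bond-bond autocorrelation on a
        graph whose bond table holds the merged vectors."""
        for _ in range(10):
            g = random_connected_graph(rng, n_max=8)
            recipe = MergeRecipe(atom_means=("p",), atom_absdiffs=("p",), bond_props=("q",))
            merged = merge_edge_properties(g, recipe)
            h = MolecularGraph(g.nodes, g.edges, g.atom_props, merged, g.metal_node)
            for origin, merge in [(Origin.full, "none"), (Origin.metal_centered, "sum")]:
                fv = aabba_two(g, "II2", recipe, Operator.summetric, origin, 3, merge=merge)
                direct = []
                for comp in recipe.component_names():
                    direct.extend(bb_ac(h, comp, Operator.summetric, origin, merge, 3).values)
                np.testing.assert_array_equal(fv.values, np.array(direct))

    def test_permutation_invariance(self, rng):
        g = random_connected_graph(rng, n_max=8)
        perm = rng.permutation(len(g.nodes))
        h = MolecularGraph([g.nodes[i] for i in perm], g.edges, g.atom_props,
                           g.bond_props, g.metal_node)
        recipe = MergeRecipe(atom_means=("p",), bond_props=("q",))
        a = aabba_two(g, "II1", recipe, Operator.product, Origin.full, 3)
        b = aabba_two(h, "II1", recipe, Operator.product, Origin.full, 3)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestMaximalVector:
    def test_length_matches_closed_form(self, toy_catalog):
        g = rich_graph()
        fv = maximal_vector(g, toy_catalog, skip_zero_division=True)
        a, b = 2, 1
        assert len(fv) == maximal_length(toy_catalog) == 4 * 7 * (2 * a + 3 * b + 2 * a * b)
        assert len(set(fv.labels)) == len(fv)

    def test_metal_less_graph_gets_reduced_length(self, toy_catalog):
        g = rich_graph(metal=None)
        fv = maximal_vector(g, toy_catalog, skip_zero_division=True)
        a, b = 2, 1
        assert len(fv) == maximal_length(toy_catalog, with_metal=False) == 4 * 7 * (a + b + a * b)

    def test_isomorphic_graphs_equal_vectors(self, toy_catalog):
        # order-preserving relabeling A->x, B->y, C->z: identical properties
        # at identical distances, so every block must match exactly (ordered
        # operators pin the canonical order to the stored node order)
        g = rich_graph()
        h = make_graph(
            ["x", "y", "z"], [("x", "y"), ("y", "z")],
            p={"x": [1.0, 2.1], "y": [3.0, 0.9], "z": [2.0, 3.3]},
            q={("x", "y"): [1.5], ("y", "z"): [0.5]},
            metal="y", atom_names=("Z", "chi"), bond_names=("BO",),
        )
        a = maximal_vector(g, toy_catalog, skip_zero_division=True)
        b = maximal_vector(h, toy_catalog, skip_zero_division=True)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12, atol=1e-12)

    def test_missing_catalog_property_rejected(self, path_abc, toy_catalog):
        with pytest.raises(Exception, match="lacks catalog"):
            maximal_vector(path_abc, toy_catalog)


class TestWholeGraphBlock:
    def test_counts_and_sums(self, toy_catalog):
        g = rich_graph()
        fv = whole_graph_block(g, toy_catalog)
        s = fv.to_series()
        assert s["natoms-0_FA_WG"] == 3 and s["nbonds-0_FA_WG"] == 2
        assert s["sum.Z-0_FS_WG"] == pytest.approx(6.0)
        assert s["sum.BO-0_FS_WG"] == pytest.approx(2.0)


class TestRemoveRedundant:
    def test_constant_dropped_scaled_copy_kept(self):
        X = pd.DataFrame([[1, 1, 2], [1, 3, 6]], columns=["c0", "c1", "c2"])
        reduced, kept, dropped = remove_redundant(X)
        assert kept == ["c1", "c2"] and dropped == ["c0"]

    def test_all_distinct_is_identity(self):
        X = pd.DataFrame([[1, 2], [3, 5]], columns=["a", "b"])
        reduced, kept, dropped = remove_redundant(X)
        assert kept == ["a", "b"] and dropped == []
        pd.testing.assert_frame_equal(reduced, X)

    def test_bit_identical_duplicate_dropped_and_recoverable(self):
        col = np.array([0.1, 0.2, 0.7])
        X = pd.DataFrame({"a": col, "b": col.copy(), "c": [1.0, 2.0, 3.0]})
        reduced, kept, dropped = remove_redundant(X)
        assert dropped == ["b"] and kept == ["a", "c"]
        np.testing.assert_array_equal(X["b"], reduced["a"])  # exactly recoverable

    def test_idempotent(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 8)))
        X[8] = X[0]
        X[9] = 2.5
        X.columns = [f"c{i}" for i in range(10)]
        r1, k1, d1 = remove_redundant(X)
        r2, k2, d2 = remove_redundant(r1)
        assert k2 == k1 and d2 == []
        pd.testing.assert_frame_equal(r1, r2)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError, match="2 rows"):
            remove_redundant(pd.DataFrame([[1, 2]]))


class TestFeatureMatrixIO:
    def test_round_trip_with_sidecar(self, tmp_path, toy_catalog):
        graphs = [rich_graph(), rich_graph()]
        specs = maximal_specs(toy_catalog, max_depth=2)
        X = featurize_dataset(graphs, specs, ids=["g0", "g1"], skip_zero_division=True)
        out = tmp_path / "features.csv"
        write_feature_matrix(X, out, metadata={"note": "fixture"})
        again = read_feature_matrix(out)
        pd.testing.assert_frame_equal(X, again)
        assert (tmp_path / "features.csv.meta.json").exists()
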