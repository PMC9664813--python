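import numpy as np
import pytest

from bdhns import AssociationMatrix
from bdhns.io import AnnotationBundle
from bdhns import similarity as sim
from .conftest import random_association_matrix


def gip_oracle(profiles, scale):
    """Direct double-loop Gaussian profile kernel."""
    n = profiles.shape[0]
    rate = scale / np.mean([np.dot(p, p) for p in profiles])
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = profiles[i] - profiles[j]
            out[i, j] = np.exp(-rate * np.dot(diff, diff))
    return out


class TestGip:
    def test_identity_association_hand_value(self):
        A = AssociationMatrix(np.eye(2), ("d1", "d2"), ("m1", "m2"))
        GM = sim.gip_similarity(A, "microbe")
        assert GM.values[0, 0] == 1.0
        assert GM.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_identical_profiles_similarity_one(self):
        values = np.array([[1, 1, 0], [0, 0, 1]], dtype=float)
        A = AssociationMatrix(values, ("d1", "d2"), ("m1", "m2", "m3"))
        GM = sim.gip_similarity(A, "microbe", bandwidth_scale=3.7)
        assert GM.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("axis", ["disease", "microbe"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_oracle(self, axis, seed):
        rng = np.random.default_rng(seed)
        A = random_association_matrix(rng, rng.integers(2, 20), rng.integers(2, 20))
        got = sim.gip_similarity(A, axis).values
        profiles = A.values if axis == "disease" else A.values.T
        np.testing.assert_allclose(got, gip_oracle(profiles, 1.0), atol=1e-10)

    def test_all_zero_matrix_rejected(self):
        A = AssociationMatrix(np.zeros((2, 2)), ("d1", "d2"), ("m1", "m2"))
        with pytest.raises(ValueError, match="bandwidth"):
            sim.gip_similarity(A, "microbe")


class TestMinmax:
    def test_endpoints_and_interior(self):
        M = np.array([[2.0, 4.0], [6.0, 8.0]])
        out = sim.minmax_normalize(M)
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[0, 1] == pytest.approx(1 / 3)

    def test_degenerate_modes(self):
        M = np.full((2, 2), 5.0)
        assert sim.minmax_normalize(M, "zeros").sum() == 0.0
        assert sim.minmax_normalize(M, "ones").sum() == 4.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sim.minmax_normalize(np.empty((0, 0)))


class TestMicrobeFunctional:
    def test_no_shared_pairs(self):
        bundle = AnnotationBundle(
            organ_annotations={("m1", "gut", "d1"), ("m2", "skin", "d2")}
        )
        FM = sim.microbe_functional_similarity(bundle, ("m1", "m2"))
        assert FM.values[0, 1] == 0.0

    def test_single_shared_pair_normalizes_to_one(self):
        bundle = AnnotationBundle(
            organ_annotations={("m1", "gut", "d1"), ("m2", "gut", "d1")}
        )
        FM = sim.microbe_functional_similarity(bundle, ("m1", "m2"))
        assert FM.values[0, 1] == 1.0

    def test_count_enumeration(self):
        bundle = AnnotationBundle(
            organ_annotations={
                ("m1", "gut", "d1"),
                ("m2", "gut", "d1"),
                ("m1", "gut", "d2"),
                ("m2", "gut", "d2"),
                ("m3", "gut", "d1"),
            }
        )
        FM = sim.microbe_functional_similarity(bundle, ("m1", "m2", "m3"))
        assert FM.values[0, 1] == 1.0  # raw count 2
        assert FM.values[0, 2] == 0.5  # raw count 1


class TestMicrobeFusion:
    def test_branches(self, toy_dataset):
        A = toy_dataset.associations
        GM = sim.gip_similarity(A, "microbe")
        FM = sim.microbe_functional_similarity(
            toy_dataset.annotations, A.microbe_ids
        )
        SM = sim.fuse_microbe_similarity(GM, FM)
        where_zero = FM.values == 0
        np.testing.assert_array_equal(SM.values[where_zero], GM.values[where_zero])
        np.testing.assert_allclose(
            SM.values[~where_zero],
            (GM.values[~where_zero] + FM.values[~where_zero]) / 2.0,
        )

    def test_empty_functional_channel_returns_gip(self):
        ids = ("m1", "m2")
        GM = sim.SimilarityMatrix(np.array([[1.0, 0.6], [0.6, 1.0]]), ids, "GM")
        FM = sim.SimilarityMatrix(np.zeros((2, 2)), ids, "FM")
        np.testing.assert_array_equal(
            sim.fuse_microbe_similarity(GM, FM).values, GM.values
        )


def semantic_oracle(dag_edges, disease_ids, delta):
    """Brute-force semantic similarity: materialize every ancestor set and
    contribution by explicit traversal."""
    parents = {}
    for child, parent in dag_edges:
        parents.setdefault(child, set()).add(parent)

    def closure(d):
        seen, stack = {d}, [d]
        while stack:
            for p in parents.get(stack.pop(), ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def contribution(focal, node, nodes):
        if node == focal:
            return 1.0
        kids = [c for c in nodes if node in parents.get(c, ())]
        return delta * max(contribution(focal, k, nodes) for k in kids)

    known = {c for e in dag_edges for c in e}
    n = len(disease_ids)
    out = np.eye(n)
    data = {}
    for d in disease_ids:
        if d in known:
            nodes = closure(d)
            data[d] = {t: contribution(d, t, nodes) for t in nodes}
    for i, di in enumerate(disease_ids):
        for j, dj in enumerate(disease_ids):
            if i == j or di not in data or dj not in data:
                continue
            shared = set(data[di]) & set(data[dj])
            if shared:
                out[i, j] = sum(data[di][t] + data[dj][t] for t in shared) / (
                    sum(data[di].values()) + sum(data[dj].values())
                )
    return out


class TestSemantic:
    def test_self_similarity_one(self):
        edges = {("d1", "root")}
        DSS = sim.disease_semantic_similarity(edges, ("d1",))
        assert DSS.values[0, 0] == 1.0

    def test_chain_semantic_value(self):
        # chain G -> P -> D: contributions 1, 0.5, 0.25
        edges = {("D", "P"), ("P", "G")}
        contrib = sim._semantic_contributions(
            "D", {"D": {"P"}, "P": {"G"}, "G": set()}, 0.5
        )
        assert sum(contrib.values()) == pytest.approx(1.75)

    def test_siblings_one_third(self):
        edges = {("X", "P"), ("Y", "P")}
        DSS = sim.disease_semantic_similarity(edges, ("X", "Y"))
        assert DSS.values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_absent_disease_gets_identity_row(self):
        edges = {("X", "P")}
        DSS = sim.disease_semantic_similarity(edges, ("X", "Z"))
        assert DSS.values[1, 1] == 1.0
        assert DSS.values[0, 1] == 0.0

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            sim.disease_semantic_similarity({("A", "B"), ("B", "A")}, ("A", "B"))

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_matches_brute_force_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        ids = tuple(f"n{i}" for i in range(n))
        edges = set()
        for i in range(1, n):  # parents have smaller index: acyclic
            for p in rng.choice(i, size=min(i, rng.integers(1, 3)), replace=False):
                edges.add((ids[i], ids[int(p)]))
        got = sim.disease_semantic_similarity(edges, ids).values
        np.testing.assert_allclose(got, semantic_oracle(edges, ids, 0.5), atol=1e-10)


class TestDiseaseFunctional:
    def test_identical_sets(self):
        DF = sim.disease_functional_similarity(
            {"d1": frozenset("ab"), "d2": frozenset("ab")}, set(), ("d1", "d2")
        )
        assert DF.values[0, 1] == 1.0

    def test_disjoint_unconnected_sets(self):
        DF = sim.disease_functional_similarity(
            {"d1": frozenset("a"), "d2": frozenset("b")}, set(), ("d1", "d2")
        )
        assert DF.values[0, 1] == 0.0

    def test_two_edge_network_hand_values(self):
        edges = {("a", "b", 2.0), ("c", "d", 4.0)}
        DF_hi = sim.disease_functional_similarity(
            {"d1": frozenset("c"), "d2": frozenset("d")}, edges, ("d1", "d2")
        )
        assert DF_hi.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        DF_lo = sim.disease_functional_similarity(
            {"d1": frozenset("a"), "d2": frozenset("b")}, edges, ("d1", "d2")
        )
        assert DF_lo.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_gene_set_identity_row(self):
        DF = sim.disease_functional_similarity(
            {"d1": frozenset("a")}, set(), ("d1", "d2")
        )
        assert DF.values[1, 1] == 1.0
        assert DF.values[0, 1] == 0.0


class TestSymptom:
    def test_hand_values(self):
        import pandas as pd

        table = pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [0, 0, 0]],
            index=["d1", "d2", "d3"],
            columns=["s1", "s2", "s3"],
            dtype=float,
        )
        TD = sim.symptom_similarity(table, ("d1", "d2", "d3"))
        assert TD.values[0, 1] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert TD.values[0, 2] == 0.0  # zero-profile disease
        assert TD.values[2, 2] == 1.0

    def test_orthogonal_and_identical(self):
        import pandas as pd

        table = pd.DataFrame(
            [[1, 0], [0, 1], [2, 0]], index=["a", "b", "c"], dtype=float
        )
        TD = sim.symptom_similarity(table, ("a", "b", "c"))
        assert TD.values[0, 1] == 0.0
        assert TD.values[0, 2] == pytest.approx(1.0, abs=1e-12)


class TestDiseaseFusion:
    def test_mean_of_four(self):
        ids = ("d1", "d2")
        mats = []
        for v, kind in [(1.0, "GD"), (1 / 3, "DSS"), (0.0, "TD"), (1.0, "DF")]:
            m = np.array([[1.0, v], [v, 1.0]])
            mats.append(sim.SimilarityMatrix(m, ids, kind))
        SD = sim.fuse_disease_similarity(*mats)
        assert SD.values[0, 1] == pytest.approx(7 / 12)
        assert SD.values[0, 0] == 1.0

    def test_label_mismatch_rejected(self):
        a = sim.SimilarityMatrix(np.eye(2), ("d1", "d2"), "GD")
        b = sim.SimilarityMatrix(np.eye(2), ("d1", "dX"), "DSS")
        with pytest.raises(ValueError, match="label"):
            sim.fuse_disease_similarity(a, b, a, a)


class TestInvariants:
    def test_all_outputs_symmetric_in_unit_range(self, toy_dataset):
        """Every similarity channel is symmetric with entries in [0, 1];
        the GIP kernels are strictly positive."""
        A = toy_dataset.associations
        bundle = toy_dataset.annotations
        channels = [
            sim.gip_similarity(A, "microbe"),
            sim.gip_similarity(A, "disease"),
            sim.microbe_functional_similarity(bundle, A.microbe_ids),
            sim.disease_semantic_similarity(bundle.dag_edges, A.disease_ids),
            sim.disease_functional_similarity(
                bundle.gene_sets, bundle.gene_edges, A.disease_ids
            ),
            sim.symptom_similarity(bundle.symptom_table, A.disease_ids),
        ]
        for channel in channels:
            M = channel.values
            assert np.abs(M - M.T).max() < 1e-12, channel.kind
            assert M.min() >= 0.0 and M.max() <= 1.0 + 1e-12, channel.kind
        assert channels[0].values.min() > 0
        assert channels[1].values.min() > 0

    def test_relabeling_permutes_consistently(self):
        """Entity order only permutes rows/columns of DSS and DF."""
        edges = {("X", "P"), ("Y", "P"), ("Z", "Q"), ("Q", "P")}
        ids = ("X", "Y", "Z")
        perm = ("Z", "X", "Y")
        a = sim.disease_semantic_similarity(edges, ids).values
        b = sim.disease_semantic_similarity(edges, perm).values
        order = [perm.index(d) for d in ids]
        np.testing.assert_allclose(a, b[np.ix_(order, order)], atol=1e-12)
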