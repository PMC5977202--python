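"""Nei distance, neighbor joining + bootstrap, DAPC, Mantel."""

import numpy as np
import pandas as pd
import pytest

from hostcline import clustering as cl


def dm(labels, values):
    return cl.DistanceMatrix(list(labels), np.asarray(values, float),
                             np.zeros((len(labels),) * 2, bool))


class TestNeiDistance:
    def test_identical_populations_have_zero_distance(self, rng):
        f = pd.DataFrame([rng.uniform(0.1, 0.9, 30)] * 2, index=["x", "y"])
        out = cl.nei_distance(f)
        assert out.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_single_locus_hand_value(self):
        f = pd.DataFrame([[1.0], [0.5]], index=["x", "y"])
        out = cl.nei_distance(f)
        # I = 0.5 / sqrt(1.0 * 0.5); D = -ln(I)
        assert out.values[0, 1] == pytest.approx(0.34657359, abs=1e-6)

    def test_opposite_fixation_is_infinite_and_flagged(self):
        f = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["x", "y"])
        out = cl.nei_distance(f)
        assert np.isinf(out.values[0, 1]) and out.infinite[0, 1]

    def test_symmetry_and_monotonicity(self, rng):
        base = rng.uniform(0.2, 0.8, 50)
        rows = []
        for shift in (0.0, 0.1, 0.2):
            y = base.copy()
            y[0] = min(base[0] + shift, 1.0)
            rows.append(y)
        f = pd.DataFrame([base] + rows, index=["x", "s0", "s1", "s2"])
        out = cl.nei_distance(f)
        np.testing.assert_allclose(out.values, out.values.T)
        d = [out.values[0, k] for k in (1, 2, 3)]
        assert d[0] < d[1] < d[2]

    def test_na_loci_dropped_pairwise(self):
        f = pd.DataFrame([[0.5, np.nan, 0.9], [0.5, 0.2, 0.9]], index=["x", "y"])
        out = cl.nei_distance(f)
        assert out.values[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = dm("ABC", [[0, 5, 9], [5, 0, 10], [9, 10, 0]])
        t = cl.nj_tree(d)
        assert t.branch_length("A", ("internal", 0)) == pytest.approx(2.0, abs=1e-10)
        assert t.branch_length("B", ("internal", 0)) == pytest.approx(3.0, abs=1e-10)
        assert t.branch_length("C", ("internal", 0)) == pytest.approx(7.0, abs=1e-10)

    def additive_tree_4(self):
        # ((A:2,B:3):1,(C:4,D:5))
        return dm("ABCD", [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]])

    def test_additive_four_taxon_recovery(self):
        t = cl.nj_tree(self.additive_tree_4())
        assert t.has_split({"C", "D"}) and t.has_split({"A", "B"})
        assert t.branch_length("A", t.adjacency["A"][0][0]) == pytest.approx(2.0, abs=1e-10)

    def test_additive_five_taxon_recovery(self):
        # caterpillar ((A:1,B:2):1,(C:3,(D:4,E:5):1):1) style metric
        import itertools
        leaf = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "E": 5.0}
        pathpos = {"A": 0, "B": 0, "C": 1, "D": 2, "E": 2}
        labels = list("ABCDE")
        vals = np.zeros((5, 5))
        for i, j in itertools.combinations(range(5), 2):
            a, b = labels[i], labels[j]
            vals[i, j] = vals[j, i] = leaf[a] + leaf[b] + abs(pathpos[a] - pathpos[b])
        t = cl.nj_tree(dm(labels, vals))
        assert t.has_split({"A", "B"}) and t.has_split({"D", "E"})
        for leaf_name, ln in leaf.items():
            nbr = t.adjacency[leaf_name][0]
            assert nbr[1] == pytest.approx(ln, abs=1e-10)

    def test_matches_dendropy_on_additive_metric(self):
        import io

        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import treecompare

        d = self.additive_tree_4()
        t = cl.nj_tree(d)
        csv = "," + ",".join(d.labels) + "\n" + "\n".join(
            d.labels[i] + "," + ",".join(str(v) for v in d.values[i]) for i in range(4)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=io.StringIO(csv))
        ref_newick = pdm.nj_tree().as_string(schema="newick")
        tns = dendropy.TaxonNamespace()
        mine = dendropy.Tree.get(data=t.newick(), schema="newick",
                                 taxon_namespace=tns)
        ref = dendropy.Tree.get(data=ref_newick, schema="newick",
                                taxon_namespace=tns)
        mine.encode_bipartitions()
        ref.encode_bipartitions()
        assert treecompare.symmetric_difference(mine, ref) == 0

    def test_ultrametric_tie_is_deterministic(self):
        vals = np.full((4, 4), 2.0)
        np.fill_diagonal(vals, 0.0)
        t1 = cl.nj_tree(dm("ABCD", vals))
        t2 = cl.nj_tree(dm("ABCD", vals))
        assert t1.newick() == t2.newick()

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            cl.nj_tree(dm("AB", [[0, 1], [1, 0]]))
        bad = dm("ABC", [[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="infinite"):
            cl.nj_tree(bad)

    def test_negative_branch_clamped_with_transfer(self):
        # a metric that forces a negative NJ branch length
        vals = np.array([
            [0, 1.0, 5.0, 5.0],
            [1.0, 0, 4.2, 4.2],
            [5.0, 4.2, 0, 1.0],
            [5.0, 4.2, 1.0, 0],
        ])
        t = cl.nj_tree(dm("ABCD", vals))
        for node, nbrs in t.adjacency.items():
            for _, ln in nbrs:
                assert ln >= 0.0


class TestBootstrapSupport:
    def test_single_replicate_supports_are_binary(self, rng):
        f = pd.DataFrame(rng.uniform(0.1, 0.9, (4, 60)),
                         index=["a", "b", "c", "d"])
        tree, skipped = cl.bootstrap_support(f, n_reps=1, seed=0)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_separated_clusters_get_high_support(self, rng):
        base = rng.uniform(0.3, 0.7, 2000)
        off = 0.25 * np.where(rng.random(2000) < 0.5, 1, -1)
        f = pd.DataFrame(
            [base + rng.normal(0, 0.01, 2000) for _ in range(2)]
            + [np.clip(base + off, 0.01, 0.99) + rng.normal(0, 0.01, 2000)
               for _ in range(2)],
            index=["a1", "a2", "b1", "b2"],
        ).clip(0.001, 0.999)
        tree, _ = cl.bootstrap_support(f, n_reps=200, seed=1)
        assert tree.support({"b1", "b2"}) >= 99.0

    def test_identical_populations_not_systematically_supported(self, rng):
        base = rng.uniform(0.3, 0.7, 300)
        f = pd.DataFrame(
            [base + rng.normal(0, 0.05, 300) for _ in range(6)],
            index=[f"p{i}" for i in range(6)],
        ).clip(0.01, 0.99)
        tree, _ = cl.bootstrap_support(f, n_reps=200, seed=2)
        assert np.median(list(tree.supports.values())) < 70.0


class TestDapc:
    def test_fixed_differences_give_certain_assignment(self, rng):
        X = np.vstack([np.zeros((20, 50)), np.full((20, 50), 2.0)])
        X += rng.normal(0, 0.05, X.shape)
        labels = ["a"] * 20 + ["b"] * 20
        m = cl.dapc_fit(X, labels, 3)
        assert m.mean_correct_prob > 0.99
        assert len(m.disc_eigvals) == 1  # k=2 -> exactly one function
        np.testing.assert_allclose(m.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_arbitrary_split_of_one_population_is_uninformative(self, rng):
        X = rng.binomial(2, 0.5, (60, 200)).astype(float)
        labels = ["a"] * 30 + ["b"] * 30
        m = cl.dapc_fit(X, labels, 1)
        assert abs(m.mean_correct_prob - 0.5) <= 0.1

    def test_label_permutation_equivariance(self, rng):
        X = rng.normal(0, 1, (40, 30))
        X[:20] += 1.0
        labels = np.array(["a"] * 20 + ["b"] * 20)
        m1 = cl.dapc_fit(X, labels, 2)
        swapped = np.where(labels == "a", "b", "a")
        m2 = cl.dapc_fit(X, swapped, 2)
        # renaming the groups relabels the columns but not the partition
        np.testing.assert_allclose(
            m1.memberships["a"].to_numpy(), m2.memberships["b"].to_numpy(), atol=1e-9
        )
        assert m1.mean_correct_prob == pytest.approx(m2.mean_correct_prob, abs=1e-12)

    def test_errors(self, rng):
        X = rng.normal(0, 1, (10, 5))
        with pytest.raises(ValueError, match="2 groups"):
            cl.dapc_fit(X, ["a"] * 10, 2)
        with pytest.raises(ValueError, match="at least 2 individuals"):
            cl.dapc_fit(X, ["a"] * 9 + ["b"], 2)
        with pytest.raises(ValueError, match="exceeds rank"):
            cl.dapc_fit(X, ["a"] * 5 + ["b"] * 5, 50)


class TestAScore:
    def test_separated_groups_score_high_at_small_m(self, rng):
        X = np.vstack([np.zeros((25, 40)), np.full((25, 40), 1.5)])
        X += rng.normal(0, 0.3, X.shape)
        labels = ["a"] * 25 + ["b"] * 25
        best, curve = cl.optimize_a_score(X, labels, range(1, 8), seed=0)
        assert curve[best] > 0.3
        assert best <= 3

    def test_null_data_scores_near_zero(self, rng):
        X = rng.normal(0, 1, (60, 80))
        labels = ["a"] * 30 + ["b"] * 30
        _, curve = cl.optimize_a_score(X, labels, range(1, 6), seed=1)
        assert abs(np.mean(list(curve.values()))) < 0.1

    def test_empty_grid(self, rng):
        with pytest.raises(ValueError, match="empty"):
            cl.optimize_a_score(rng.normal(0, 1, (10, 5)), ["a"] * 5 + ["b"] * 5, [])


class TestClusterSignificance:
    def test_planted_separation_minimal_p(self, rng):
        X = np.vstack([np.zeros((15, 30)), np.full((15, 30), 2.0)])
        X += rng.normal(0, 0.1, X.shape)
        labels = ["a"] * 15 + ["b"] * 15
        obs, p, null = cl.cluster_significance(X, labels, 2, n_reps=200, seed=0)
        assert p == pytest.approx(1.0 / 201.0)
        assert obs > np.max(null)

    def test_null_labels_give_large_p(self, rng):
        X = rng.normal(0, 1, (40, 60))
        labels = ["a"] * 20 + ["b"] * 20
        _, p, _ = cl.cluster_significance(X, labels, 2, n_reps=200, seed=1)
        assert p > 0.05


class TestPredictorMatrices:
    def test_coding(self):
        meta = pd.DataFrame(
            {"site_order": [1, 1, 4], "host": ["apple", "hawthorn", "hawthorn"]},
            index=["apple_Grant", "hawthorn_Grant", "hawthorn_Urbana"],
        )
        geo, eco = cl.build_predictor_matrices(meta)
        assert geo.loc["apple_Grant", "hawthorn_Grant"] == 0
        assert eco.loc["apple_Grant", "hawthorn_Grant"] == 1
        assert geo.loc["hawthorn_Grant", "hawthorn_Urbana"] == 3
        assert eco.loc["hawthorn_Grant", "hawthorn_Urbana"] == 0
        assert geo.loc["apple_Grant", "apple_Grant"] == 0

    def test_missing_site_order(self):
        meta = pd.DataFrame({"site_order": [1, np.nan], "host": ["a", "b"]},
                            index=["x", "y"])
        with pytest.raises(ValueError, match="site_order"):
            cl.build_predictor_matrices(meta)


class TestMantel:
    def make_geo(self, k=8):
        order = np.arange(k) // 2
        g = np.abs(order[:, None] - order[None, :]).astype(float)
        labels = [f"p{i}" for i in range(k)]
        return pd.DataFrame(g, index=labels, columns=labels)

    def test_perfect_linear_relation(self):
        g = self.make_geo()
        res = cl.mantel_test(2.0 * g, g, n_perm=300, seed=0)
        assert res.r == pytest.approx(1.0)
        # permutations that preserve the (tied) geographic structure also
        # reach r = 1, so p is small but not exactly minimal
        assert res.p < 0.05

    def test_errors(self, rng):
        g = self.make_geo(3)
        with pytest.raises(ValueError, match="at least 4"):
            cl.mantel_test(g, g, n_perm=10)
        g = self.make_geo()
        const = g * 0.0
        with pytest.raises(ValueError, match="constant"):
            cl.mantel_test(g, const, n_perm=10)

    def test_r_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM, mantel
        k = 6
        a = rng.random((k, k))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((k, k))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        labels = [f"p{i}" for i in range(k)]
        res = cl.mantel_test(pd.DataFrame(a, index=labels, columns=labels),
                             pd.DataFrame(b, index=labels, columns=labels),
                             n_perm=100, seed=0)
        r_ref, _, _ = mantel(SkDM(a, ids=labels), SkDM(b, ids=labels),
                             method="pearson", permutations=0)
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)
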