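"""Accumulation curves, Heaps' law fitting, PCA, distances, and NJ."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import flavopan as fp
from flavopan import simulate as sim
from flavopan.pangenome import AccumulationCurve, PresenceMatrix
from oracles import AdditiveTree, tree_bipartitions

QUARTET = pd.DataFrame(
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
    index=list("ABCD"), columns=list("ABCD"), dtype=float,
)


@pytest.fixture(scope="module")
def matrix():
    m, _ = sim.simulate_family_matrix(12, 40, 20, 0.6, seed=3)
    return m


class TestAccumulation:

    def test_first_point_is_median_genome_size(self, matrix):
        curve = fp.accumulation_curve(matrix, permutations=50, seed=1)
        sizes = (matrix.values > 0).sum(axis=1)
        assert curve.medians[0] <= sizes.max()
        assert curve.medians[0] >= sizes.min()

    def test_final_point_is_total_family_count_every_permutation(self, matrix):
        curve = fp.accumulation_curve(matrix, permutations=50, seed=1)
        assert (curve.sizes[:, -1] == len(matrix.families)).all()

    def test_medians_monotone_nondecreasing(self, matrix):
        curve = fp.accumulation_curve(matrix, permutations=50, seed=2)
        assert (np.diff(curve.medians) >= 0).all()

    def test_median_curve_tracks_closed_form(self):
        # permutation-median pan sizes follow the generator's cumulative
        # power-law sum
        kappa, alpha, core = 100, 0.5, 300
        m, _ = sim.simulate_family_matrix(40, core, kappa, alpha, seed=4)
        curve = fp.accumulation_curve(m, permutations=100, seed=5)
        closed = core + np.cumsum(
            [kappa * k**-alpha for k in range(1, 41)]
        )
        for N in range(5, 41):
            assert curve.medians[N - 1] == pytest.approx(closed[N - 1], rel=0.02)


class TestHeapsFit:
    def _curve_from_new(self, new):
        sizes = np.cumsum(np.concatenate([[500], new]))[None, :]
        return AccumulationCurve(sizes=sizes, medians=sizes[0].astype(float))

    def test_exact_power_law_recovered_to_machine_precision(self):
        N = np.arange(2, 31)
        curve = self._curve_from_new(100.0 * N**-0.5)
        fit = fp.fit_heaps(curve)
        assert fit.alpha == pytest.approx(0.5, abs=1e-12)
        assert fit.kappa == pytest.approx(100.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.openness

    def test_constant_new_genes_alpha_zero(self):
        curve = self._curve_from_new(np.full(20, 7.0))
        assert fp.fit_heaps(curve).alpha == pytest.approx(0.0, abs=1e-12)

    def test_recovery_on_simulated_matrix(self):
        m, truth = sim.simulate_family_matrix(40, 500, 100, 0.57, seed=6)
        curve = fp.accumulation_curve(m, permutations=100, seed=7)
        fit = fp.fit_heaps(curve)
        assert abs(fit.alpha - truth.true_alpha) < 0.05
        assert fit.openness

    def test_pan_mode_flag(self):
        N = np.arange(1, 21)
        sizes = (50.0 * N**0.4)[None, :]
        curve = AccumulationCurve(sizes=sizes, medians=sizes[0])
        fit = fp.fit_heaps(curve, mode="pan")
        assert fit.alpha == pytest.approx(-0.4, abs=1e-12)

    def test_too_few_points_rejected(self):
        sizes = np.array([[10, 12, 12]])
        with pytest.raises(ValueError):
            fp.fit_heaps(AccumulationCurve(sizes=sizes, medians=sizes[0].astype(float)))


class TestPca:
    def _two_clade_matrix(self):
        # 50 shared families plus 50 private to each 10-genome clade
        rows = []
        for i in range(10):
            rows.append([1] * 50 + [1] * 50 + [0] * 50)
        for i in range(10):
            rows.append([1] * 50 + [0] * 50 + [1] * 50)
        idx = [f"t{i}" for i in range(10)] + [f"a{i}" for i in range(10)]
        cols = [f"f{j}" for j in range(150)]
        return PresenceMatrix(pd.DataFrame(rows, index=idx, columns=cols))

    def test_pc1_separates_disjoint_clades(self):
        res = fp.pca(self._two_clade_matrix())
        pc1 = res.coordinates["PC1"]
        lo = pc1[[f"t{i}" for i in range(10)]]
        hi = pc1[[f"a{i}" for i in range(10)]]
        assert max(lo.min(), hi.min()) > min(lo.max(), hi.max()) or (
            lo.max() < hi.min() or hi.max() < lo.min()
        )

    def test_duplicated_genomes_identical_coordinates(self):
        m = self._two_clade_matrix()
        res = fp.pca(m)
        np.testing.assert_allclose(
            res.coordinates.loc["t0"].values, res.coordinates.loc["t1"].values,
            atol=1e-9,
        )

    def test_explained_sums_to_100(self):
        res = fp.pca(self._two_clade_matrix())
        assert res.explained_percent.sum() == pytest.approx(100.0)

    def test_column_order_invariance_up_to_sign(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 2, (8, 30)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"f{j}" for j in range(30)],
        )
        a = fp.pca(df)
        shuffled = df[list(rng.permutation(df.columns))]
        b = fp.pca(shuffled)
        for k in range(3):
            ca, cb = a.coordinates.iloc[:, k], b.coordinates.iloc[:, k]
            assert np.allclose(ca, cb, atol=1e-8) or np.allclose(ca, -cb, atol=1e-8)
        np.testing.assert_allclose(
            a.explained_percent, b.explained_percent, atol=1e-9
        )

    def test_matches_eigendecomposition_oracle(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 2, (10, 25)).astype(float),
            index=[f"g{i}" for i in range(10)],
        )
        res = fp.pca(df)
        X = df.values - df.values.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        evals = evals[: len(res.explained_percent)]
        np.testing.assert_allclose(
            res.explained_percent,
            100 * np.clip(evals, 0, None) / np.clip(evals, 0, None).sum(),
            atol=1e-8,
        )

    def test_zero_variance_rejected(self):
        df = pd.DataFrame(np.ones((4, 5)))
        with pytest.raises(ValueError, match="zero-variance"):
            fp.pca(df)


class TestBinaryDistance:
    def test_identical_rows_zero(self):
        df = pd.DataFrame(
            [[1, 0, 1], [1, 0, 1], [0, 1, 0]], index=["a", "b", "c"]
        )
        d = fp.binary_distance(PresenceMatrix(df))
        assert d.loc["a", "b"] == 0
        assert d.loc["a", "c"] == 1

    def test_disjoint_rows_jaccard_one(self):
        df = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"])
        d = fp.binary_distance(PresenceMatrix(df), metric="jaccard")
        assert d.loc["a", "b"] == 1

    def test_overlapping_rows_both_metrics(self):
        df = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["a", "b"])
        m = PresenceMatrix(df)
        assert fp.binary_distance(m, "hamming").loc["a", "b"] == pytest.approx(2 / 3)
        assert fp.binary_distance(m, "jaccard").loc["a", "b"] == pytest.approx(2 / 3)


class TestNeighborJoining:
    def test_worked_quartet_exact(self):
        res = fp.neighbor_joining(QUARTET)
        assert res.clamped_branches == 0
        splits = tree_bipartitions(res.tree)
        AB = frozenset(
            {frozenset({"A", "B"}), frozenset({"C", "D"})}
        )
        assert splits == {AB}
        terminal = {t.name: t.branch_length for t in res.tree.get_terminals()}
        assert terminal == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        (internal,) = [
            c.branch_length
            for c in res.tree.get_nonterminals()
            if c.branch_length is not None
        ]
        assert internal == pytest.approx(1.0)

    def test_three_taxa_solves_linear_system(self):
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("XYZ"), columns=list("XYZ"), dtype=float,
        )
        res = fp.neighbor_joining(D)
        lens = {t.name: t.branch_length for t in res.tree.get_terminals()}
        assert lens == pytest.approx({"X": 1.0, "Y": 2.0, "Z": 3.0})

    def test_equidistant_matrix_flagged_as_tie(self):
        D = pd.DataFrame(
            1.0 - np.eye(4), index=list("ABCD"), columns=list("ABCD")
        )
        res = fp.neighbor_joining(D)
        assert res.ties > 0
        for t in res.tree.get_terminals():
            assert t.branch_length == pytest.approx(0.5)

    def test_invalid_matrices_rejected(self):
        bad = QUARTET.copy()
        bad.iloc[0, 1] = np.nan
        with pytest.raises(ValueError):
            fp.neighbor_joining(bad)
        with pytest.raises(ValueError):
            fp.neighbor_joining(QUARTET.iloc[:2, :2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_taxa=st.integers(min_value=4, max_value=8),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_additive_matrix_recovers_generating_topology(self, n_taxa, seed):
        tree = AdditiveTree(n_taxa, np.random.default_rng(seed))
        D = pd.DataFrame(
            tree.distance_matrix(), index=tree.leaves, columns=tree.leaves
        )
        res = fp.neighbor_joining(D)
        assert tree_bipartitions(res.tree) == tree.bipartitions()

    def test_agrees_with_dendropy_on_additive_matrix(self):
        import dendropy

        tree = AdditiveTree(7, np.random.default_rng(123))
        D = pd.DataFrame(
            tree.distance_matrix(), index=tree.leaves, columns=tree.leaves
        )
        res = fp.neighbor_joining(D)

        csv = "," + ",".join(tree.leaves) + "\n"
        for leaf, row in zip(tree.leaves, tree.distance_matrix()):
            csv += leaf + "," + ",".join(map(str, row)) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dsplits = set()
        leaves_all = frozenset(tree.leaves)
        for edge in dtree.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf():
                side = frozenset(
                    t.taxon.label for t in edge.head_node.leaf_iter()
                )
                if 2 <= len(side) <= len(leaves_all) - 2:
                    dsplits.add(frozenset({side, leaves_all - side}))
        assert tree_bipartitions(res.tree) == dsplits
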