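"""IBS distances, neighbor joining, genotype PCA and LD decay."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from sweepscan.genotypes import MISSING
from sweepscan import pop_structure as pstr
from sweepscan.synthetic_data import SimulationConfig, simulate_cohort
from conftest import make_matrix


def _tip_distances(tree):
    """Tip-to-tip path lengths keyed by frozenset of tip names."""
    out = {}
    tips = list(tree.tips())
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[frozenset((a.name, b.name))] = a.distance(b)
    return out


def _random_additive_tree(rng, n_taxa=6):
    """Random binary topology with branch lengths in [0.1, 2]; returns
    (skbio tree, labels)."""
    nodes = [TreeNode(name=chr(ord("A") + i)) for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    for n in nodes:
        if n.length is None:
            n.length = float(rng.uniform(0.1, 2.0))
    return TreeNode(children=nodes)


class TestIbsDistance:
    def test_identical_samples_distance_zero(self):
        d = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (2, 1))
        g = make_matrix(d, populations=["p1", "p2"])
        dist = pstr.ibs_distance(g)
        assert dist.d[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        d = np.vstack([np.zeros(5), np.full(5, 2)]).astype(np.int8)
        g = make_matrix(d, populations=["p1", "p2"])
        assert pstr.ibs_distance(g).d[0, 1] == 1.0

    def test_hand_counted_grid(self):
        # 3 samples x 4 sites: distances counted by hand
        d = np.array([[0, 1, 2, 0],
                      [0, 1, 0, 2],
                      [2, MISSING, 2, 0]], dtype=np.int8)
        g = make_matrix(d, populations=["p1", "p1", "p2"])
        dist = pstr.ibs_distance(g)
        # pair (0,1): diffs |0|,|0|,|2|,|2| /2 -> mean 1.0 over 4 sites = 0.5
        assert dist.d[0, 1] == pytest.approx(0.5)
        # pair (0,2): co-called sites 0,2,3: |2|,|0|,|0| /2 -> 1/3
        assert dist.d[0, 2] == pytest.approx(1 / 3)
        # pair (1,2): co-called 0,2,3: |2|,|2|,|2| /2 -> 1.0
        assert dist.d[1, 2] == pytest.approx(1.0)

    def test_no_cocalled_sites_is_error(self):
        d = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        g = make_matrix(d, populations=["p1", "p2"])
        with pytest.raises(ValueError, match="co-called"):
            pstr.ibs_distance(g)

    def test_triangle_inequality_on_random_input(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        dist = pstr.ibs_distance(make_matrix(d)).d
        n = dist.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dist[i, j] <= dist[i, k] + dist[k, j] + 1e-12


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) with C,D joined via internal edge:
        # pairwise path lengths written out by hand
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0]], dtype=float)
        tree = pstr.neighbor_joining(pstr.DistanceMatrix(labels, d))
        got = _tip_distances(tree)
        for i, a in enumerate(labels):
            for j in range(i + 1, 4):
                assert got[frozenset((a, labels[j]))] == pytest.approx(
                    d[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = pstr.neighbor_joining(pstr.DistanceMatrix(labels, d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((2 + 3 - 5) / 2)
        assert lengths["B"] == pytest.approx((2 + 5 - 3) / 2)
        assert lengths["C"] == pytest.approx((3 + 5 - 2) / 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_additive_metrics_recovered(self, seed):
        rng = np.random.default_rng(seed)
        true_tree = _random_additive_tree(rng)
        want = _tip_distances(true_tree)
        labels = sorted({n for pair in want for n in pair})
        d = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = want[frozenset((a, b))]
        tree = pstr.neighbor_joining(pstr.DistanceMatrix(labels, d))
        got = _tip_distances(tree)
        for pair, dist in want.items():
            assert got[pair] == pytest.approx(dist, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        d = pstr.DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            pstr.neighbor_joining(d)

    def test_population_monophyly_on_cohort(self, small_cohort):
        g, _ = small_cohort
        dist = pstr.ibs_distance(g)
        tree = pstr.neighbor_joining(dist)
        domestic = {sid for sid, pop in zip(g.sample_ids, g.populations)
                    if pop == "domestic"}
        assert pstr.is_monophyletic(tree, domestic)

    def test_newick_round_trip(self):
        rng = np.random.default_rng(42)
        true_tree = _random_additive_tree(rng)
        want = _tip_distances(true_tree)
        labels = sorted({n for pair in want for n in pair})
        d = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = want[frozenset((a, b))]
        tree = pstr.neighbor_joining(pstr.DistanceMatrix(labels, d))
        back = TreeNode.read(io.StringIO(pstr.to_newick(tree)))
        got = _tip_distances(back)
        for pair, dist in _tip_distances(tree).items():
            assert got[pair] == pytest.approx(dist, abs=1e-9)


class TestGenotypePca:
    def test_duplicate_samples_identical_coordinates(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        d[5] = d[0]
        g = make_matrix(d)
        coords, _ = pstr.genotype_pca(g, n_components=3)
        np.testing.assert_allclose(coords[0], coords[5], atol=1e-9)

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(10, 100)).astype(np.int8)
        _, var = pstr.genotype_pca(make_matrix(d))
        assert var.sum() == pytest.approx(1.0)
        assert (var >= 0).all()
        assert (np.diff(var) <= 1e-12).all()

    def test_pc1_separates_populations(self, small_cohort):
        g, _ = small_cohort
        coords, _ = pstr.genotype_pca(g, n_components=2)
        dom = coords[g.populations == "domestic", 0]
        wild = coords[g.populations == "wild", 0]
        gap = abs(dom.mean() - wild.mean())
        assert gap > 3 * max(dom.std(), wild.std())

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(9, 70)).astype(np.int8)
        g = make_matrix(d)
        coords, var = pstr.genotype_pca(g, n_components=3)
        perm = rng.permutation(9)
        coords_p, var_p = pstr.genotype_pca(g.take_samples(perm), 3)
        np.testing.assert_allclose(var_p, var, atol=1e-9)
        # same coordinates up to a global sign per component
        for k in range(3):
            col = coords[perm, k]
            assert (np.allclose(coords_p[:, k], col, atol=1e-9)
                    or np.allclose(coords_p[:, k], -col, atol=1e-9))

    def test_single_sample_rejected(self):
        g = make_matrix(np.array([[0, 1, 2]], dtype=np.int8),
                        populations=["p1"])
        with pytest.raises(ValueError):
            pstr.genotype_pca(g)


class TestLdDecay:
    def test_duplicated_adjacent_sites_bin_is_one(self):
        rng = np.random.default_rng(8)
        col = rng.integers(0, 3, size=30).astype(np.int8)
        g = make_matrix(np.column_stack([col, col]), positions=[1000, 1200])
        curve = pstr.ld_decay(g, max_dist=2000, bin_width=500)
        hit = curve[(curve["bin_start"] < 200) & (curve["bin_end"] >= 200)]
        assert hit.iloc[0]["mean_r2"] == pytest.approx(1.0)
        assert hit.iloc[0]["n_pairs"] == 1

    def test_independent_sites_low_r2(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.4, size=(20, 300)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 200_000), 300, replace=False))
        g = make_matrix(d, positions=pos)
        curve = pstr.ld_decay(g, max_dist=100_000, bin_width=100_000)
        total = (curve["mean_r2"] * curve["n_pairs"]).sum() / curve["n_pairs"].sum()
        assert total < 0.1

    def test_pair_counts_match_brute_force(self):
        rng = np.random.default_rng(10)
        n_sites = 150
        d = rng.binomial(2, 0.4, size=(15, n_sites)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        pos = np.sort(rng.choice(np.arange(1, 50_000), n_sites,
                                 replace=False))
        g = make_matrix(d, positions=pos)
        max_dist, bw = 10_000, 1_000
        curve = pstr.ld_decay(g, max_dist=max_dist, bin_width=bw)
        brute = np.zeros(max_dist // bw, dtype=int)
        dd = d.astype(float)
        dd[d == MISSING] = np.nan
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                sep = pos[j] - pos[i]
                if sep > max_dist:
                    continue
                both = ~np.isnan(dd[:, i]) & ~np.isnan(dd[:, j])
                if both.sum() < 2:
                    continue
                x, y = dd[both, i], dd[both, j]
                if x.std() == 0 or y.std() == 0:
                    continue
                brute[min((sep - 1) // bw, len(brute) - 1)] += 1
        np.testing.assert_array_equal(curve["n_pairs"].to_numpy(), brute)

    def test_population_restriction(self, small_cohort):
        g, _ = small_cohort
        sub = g.take_sites(np.arange(200))
        curve = pstr.ld_decay(sub, "wild", max_dist=50_000, bin_width=10_000)
        assert (curve["n_pairs"] >= 0).all()
        ok = curve["mean_r2"].dropna()
        assert ((ok >= 0) & (ok <= 1 + 1e-12)).all()
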