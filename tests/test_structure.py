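"""PCA, K selection, DAPC and bootstrap UPGMA."""

import numpy as np
import pytest

from radpop import simdata, structure
from radpop.structure import (
    choose_k,
    dapc,
    discriminant_snps,
    find_clusters,
    impute_missing_by_locus_mean,
    pca,
    pca_matrix,
    upgma_from_distances,
    upgma_tree,
)
from radpop.vcfio import MISSING

from conftest import make_matrix


class TestImpute:
    def test_locus_mean_fills_missing(self):
        x = np.array([[0.0, 1.0], [2.0, 1.0], [np.nan, 1.0]])
        out = impute_missing_by_locus_mean(x)
        assert out[2, 0] == pytest.approx(1.0)

    def test_complete_matrix_identity_and_mean_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=(10, 20)).astype(float)
        np.testing.assert_array_equal(impute_missing_by_locus_mean(x), x)
        x[rng.random(x.shape) < 0.2] = np.nan
        out = impute_missing_by_locus_mean(x)
        np.testing.assert_allclose(out.mean(axis=0), np.nanmean(x, axis=0))

    def test_all_missing_locus_rejected(self):
        x = np.array([[1.0, np.nan], [0.0, np.nan]])
        with pytest.raises(ValueError, match="call-rate"):
            impute_missing_by_locus_mean(x)


class TestPca:
    def test_duplicated_samples_identical_scores(self):
        dos = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1], [0, 0, 1]], dtype=np.int16)
        vm = make_matrix(dos)
        res = pca(vm, n_components=2)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-10)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 10))
        res = pca_matrix(x, n_components=4)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc / (5 - 1))
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order[:4]]
        brute = xc @ evecs
        for c in range(4):
            s = np.sign(np.dot(brute[:, c], res.scores[:, c]))
            np.testing.assert_allclose(res.scores[:, c], s * brute[:, c], atol=1e-8)

    def test_explained_variance_monotone_and_bounded(self, two_pop_cohort):
        vm, _ = two_pop_cohort
        res = pca(vm, n_components=5)
        ev = res.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1 + 1e-9

    def test_components_orthogonal(self, two_pop_cohort):
        vm, _ = two_pop_cohort
        res = pca(vm, n_components=4)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_sample_reorder_invariance(self, two_pop_cohort):
        vm, _ = two_pop_cohort
        res = pca(vm, n_components=3)
        perm = list(reversed(vm.samples))
        res2 = pca(vm.subset_samples(perm), n_components=3)
        back = [perm.index(s) for s in vm.samples]
        np.testing.assert_allclose(res.scores, res2.scores[back], atol=1e-8)

    def test_separated_populations_split_on_pc1(self):
        cfg = simdata.SimConfig(
            n_loci=500,
            populations=[
                simdata.PopulationConfig("A", 10, divergence=0.3),
                simdata.PopulationConfig("B", 10, divergence=0.3),
            ],
            seed=4,
        )
        vm, truth = simdata.simulate_cohort(cfg)
        res = pca(vm, n_components=2)
        pc1 = res.scores[:, 0]
        pm = truth.population_map()
        a = pc1[[vm.sample_index(s) for s in pm.samples_in("A")]]
        b = pc1[[vm.sample_index(s) for s in pm.samples_in("B")]]
        assert (a.max() < b.min()) or (b.max() < a.min())  # zero overlap

    def test_too_many_components_rejected(self, two_pop_cohort):
        vm, _ = two_pop_cohort
        with pytest.raises(ValueError):
            pca(vm, n_components=vm.n_samples + 1)


class TestFindClusters:
    def test_single_tight_cluster_prefers_k1(self):
        # scores span many axes, as PCA of genotype data produces
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=0.05, size=(30, 20))
        bic, _ = find_clusters(pts, k_max=4, seed=0)
        assert choose_k(bic) == 1

    def test_three_separated_clouds(self):
        rng = np.random.default_rng(1)
        centers = np.zeros((3, 10))
        centers[1, 0] = centers[2, 1] = 10.0
        pts = np.vstack(
            [c + rng.normal(scale=0.1, size=(12, 10)) for c in centers]
        )
        bic, assign = find_clusters(pts, k_max=6, seed=0)
        assert choose_k(bic) == 3
        labels = assign[3]
        for g in range(3):
            assert len(set(labels[g * 12 : (g + 1) * 12])) == 1

    def test_bic_curve_reproducible(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 3))
        b1, _ = find_clusters(pts, k_max=5, seed=7)
        b2, _ = find_clusters(pts, k_max=5, seed=7)
        assert b1 == b2

    def test_k_max_bound(self):
        with pytest.raises(ValueError):
            find_clusters(np.zeros((5, 2)), k_max=5)


class TestChooseK:
    def test_smallest_k_before_increase(self):
        assert choose_k({1: 100.0, 2: 80.0, 3: 85.0}) == 2

    def test_strictly_decreasing_returns_kmax_with_warning(self):
        with pytest.warns(UserWarning):
            assert choose_k({1: 100.0, 2: 90.0, 3: 80.0}) == 3

    @pytest.mark.parametrize("planted,seed", [(2, 51), (3, 52), (5, 53)])
    def test_recovers_planted_k(self, planted, seed):
        cfg = simdata.SimConfig(
            n_loci=1000,
            populations=[
                simdata.PopulationConfig(f"P{i}", 10, divergence=0.3)
                for i in range(planted)
            ],
            seed=seed,
        )
        vm, _ = simdata.simulate_cohort(cfg)
        res = pca(vm, n_components=min(40, vm.n_samples - 1))
        bic, _ = find_clusters(res.scores, k_max=8, seed=0)
        assert choose_k(bic) == planted


class TestDapc:
    def test_membership_rows_sum_to_one(self, two_pop_cohort):
        vm, truth = two_pop_cohort
        res = dapc(vm, truth.population_map().assignments)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_groups_reassigned_correctly(self, two_pop_cohort):
        vm, truth = two_pop_cohort
        res = dapc(vm, truth.population_map().assignments)
        predicted = [res.groups[i] for i in res.memberships.argmax(axis=1)]
        actual = [truth.populations[s] for s in res.group_assignments]
        agree = np.mean([p == a for p, a in zip(predicted, actual)])
        assert agree >= 0.99

    def test_null_groups_near_uniform_on_held_out(self):
        cfg = simdata.SimConfig(
            n_loci=800,
            populations=[simdata.PopulationConfig("A", 40, divergence=0.0)],
            seed=71,
        )
        vm, _ = simdata.simulate_cohort(cfg)
        train = vm.subset_samples(vm.samples[:24])
        held = vm.subset_samples(vm.samples[24:])
        labels = {s: ("g1" if i % 2 else "g2") for i, s in enumerate(train.samples)}
        res = dapc(train, labels)
        post = res.predict_memberships(held)
        assert abs(post[:, 0].mean() - 0.5) < 0.2

    def test_overfitting_guard(self, two_pop_cohort):
        vm, truth = two_pop_cohort
        with pytest.raises(ValueError, match="n_pca"):
            dapc(vm, truth.population_map().assignments, n_pca=vm.n_samples)

    def test_trait_loci_rank_in_top_decile(self):
        cfg = simdata.SimConfig(
            n_loci=1000,
            populations=[simdata.PopulationConfig("A", 40, divergence=0.0)],
            trait=simdata.TraitConfig(n_trait_loci=50, delta=0.6),
            seed=72,
        )
        vm, truth = simdata.simulate_cohort(cfg)
        res = dapc(vm, truth.phenotypes)
        load = res.snp_loadings.sum(axis=1)
        ranks = {i: r for r, i in enumerate(np.argsort(-load))}
        in_decile = sum(1 for i in truth.trait_loci if ranks[i] < 100)
        assert in_decile >= 0.8 * 50


class TestDiscriminantSnps:
    def test_obvious_changepoint(self):
        res = structure.DapcResult(
            k=2,
            group_assignments={},
            memberships=np.zeros((0, 2)),
            groups=["a", "b"],
            n_pca_retained=1,
            snp_loadings=np.array([[0.9], [0.8], [0.01], [0.02], [0.01]]),
        )
        assert sorted(discriminant_snps(res)) == [0, 1]

    def test_flat_loadings_empty_with_warning(self):
        res = structure.DapcResult(
            k=2,
            group_assignments={},
            memberships=np.zeros((0, 2)),
            groups=["a", "b"],
            n_pca_retained=1,
            snp_loadings=np.full((10, 1), 0.1),
        )
        with pytest.warns(UserWarning):
            assert discriminant_snps(res) == []

    def test_quantile_method(self):
        load = np.concatenate([np.full(95, 0.001), np.full(5, 0.5)])[:, None]
        res = structure.DapcResult(
            k=2,
            group_assignments={},
            memberships=np.zeros((0, 2)),
            groups=["a", "b"],
            n_pca_retained=1,
            snp_loadings=load,
        )
        sel = discriminant_snps(res, method="quantile", quantile=0.95)
        assert sorted(sel) == list(range(95, 100))


class TestUpgma:
    def test_hand_worked_four_taxon_example(self):
        # d(A,B)=2; d(A,C)=d(B,C)=4; d(·,D)=6 everywhere:
        # merges (A,B)@h=1, (AB,C)@h=2, (ABC,D)@h=3 -- worked by hand
        d = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            dtype=float,
        )
        clades, heights, newick = upgma_from_distances(d, ["A", "B", "C", "D"])
        assert clades == [
            frozenset({"A", "B"}),
            frozenset({"A", "B", "C"}),
            frozenset({"A", "B", "C", "D"}),
        ]
        assert heights[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert heights[frozenset({"A", "B", "C"})] == pytest.approx(2.0)
        assert heights[frozenset({"A", "B", "C", "D"})] == pytest.approx(3.0)
        assert newick == "(((A:1,B:1):1,C:2):1,D:3)"

    def test_equidistant_star_merges_at_equal_height(self):
        d = np.array([[0, 4, 4], [4, 0, 4], [4, 4, 0]], dtype=float)
        _, heights, _ = upgma_from_distances(d, ["x", "y", "z"])
        assert all(h == pytest.approx(2.0) for h in heights.values())

    def test_tree_is_ultrametric(self, two_pop_cohort):
        vm, _ = two_pop_cohort
        tree = upgma_tree(vm, n_boot=0)
        import dendropy

        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        depths = [leaf.distance_from_root() for leaf in t.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-6

    def test_leaf_order_permutation_invariance(self, two_pop_cohort):
        vm, _ = two_pop_cohort
        t1 = upgma_tree(vm, n_boot=0)
        t2 = upgma_tree(vm.subset_samples(list(reversed(vm.samples))), n_boot=0)
        assert set(t1.clades) == set(t2.clades)
        for c in t1.clades:
            assert t1.heights[c] == pytest.approx(t2.heights[c], abs=1e-9)

    def test_species_clades_full_bootstrap_support(self):
        cfg = simdata.SimConfig(
            n_loci=300,
            populations=[
                simdata.PopulationConfig(p, 6, divergence=0.8) for p in "ABC"
            ],
            seed=57,
        )
        vm, _ = simdata.simulate_cohort(cfg)
        tree = upgma_tree(vm, n_boot=50, seed=0)
        for p in "ABC":
            clade = frozenset(s for s in vm.samples if s.startswith(p))
            assert tree.supports[clade] == 100.0

    def test_too_few_samples_rejected(self, two_pop_cohort):
        vm, _ = two_pop_cohort
        with pytest.raises(ValueError):
            upgma_tree(vm.subset_samples(vm.samples[:2]))
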