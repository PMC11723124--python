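"""Diversity (Ho/Hs/FIS), pairwise Fst and method-of-moments IBD."""

import numpy as np
import pytest

from radpop import popgen, simdata
from radpop.popgen import allele_freqs, basic_stats, ibd_estimates, pairwise_fst
from radpop.vcfio import MISSING, PopulationMap, VariantMatrix

from conftest import make_matrix


def pm_for(vm, split=None):
    """All samples one population, or two halves A/B."""
    if split is None:
        return PopulationMap(assignments={s: "A" for s in vm.samples})
    return PopulationMap(
        assignments={
            s: ("A" if i < split else "B") for i, s in enumerate(vm.samples)
        }
    )


class TestAlleleFreqs:
    def test_hand_counts(self):
        vm = make_matrix([[0, 1, 2], [MISSING, MISSING, MISSING]])
        freqs = allele_freqs(vm, pm_for(vm))
        assert freqs["A"]["p"][0] == pytest.approx(0.5)
        assert np.isnan(freqs["A"]["p"][1])  # all-missing -> unavailable

    def test_matches_brute_force_recount(self, two_pop_cohort):
        vm, truth = two_pop_cohort
        pm = truth.population_map()
        freqs = allele_freqs(vm, pm)
        for pop in pm.populations():
            idx = [vm.sample_index(s) for s in pm.samples_in(pop)]
            for i in range(0, vm.n_loci, 11):
                num = den = 0
                for j in idx:
                    if vm.dosage[i, j] != MISSING:
                        num += int(vm.dosage[i, j])
                        den += int(vm.call_ploidy[i, j])
                expected = num / den if den else np.nan
                got = freqs[pop]["p"][i]
                if den:
                    assert got == pytest.approx(expected)
                else:
                    assert np.isnan(got)


class TestBasicStats:
    def test_all_homozygous_population_has_zero_ho(self):
        vm = make_matrix([[0, 2, 2], [2, 2, 0]])
        stats = basic_stats(vm, pm_for(vm))
        ho, hs, fis = stats.per_population["A"]
        assert ho == 0.0
        assert fis == pytest.approx(1.0)

    def test_hand_oracle_three_individuals_two_loci(self):
        # locus 1: 0/0, 0/1, 1/1 -> p=1/2, Ho=1/3, Hs = 3/2*(1/2 - 1/18) = 2/3
        # locus 2: 0/1, 0/1, 0/0 -> p=1/3, Ho=2/3, Hs = 3/2*(1/3)         = 1/2
        vm = make_matrix([[0, 1, 2], [1, 1, 0]])
        stats = basic_stats(vm, pm_for(vm))
        ho, hs, fis = stats.per_population["A"]
        assert ho == pytest.approx(1 / 2, abs=1e-12)
        assert hs == pytest.approx(7 / 12, abs=1e-12)
        assert fis == pytest.approx(1 / 7, abs=1e-12)

    def test_monomorphic_population_reports_undefined_fis(self):
        vm = make_matrix([[0, 0, 0], [2, 2, 2]])
        ho, hs, fis = basic_stats(vm, pm_for(vm)).per_population["A"]
        assert hs == 0.0
        assert np.isnan(fis)

    def test_fis_identity_holds_everywhere(self, two_pop_cohort):
        vm, truth = two_pop_cohort
        stats = basic_stats(vm, truth.population_map())
        for ho, hs, fis in stats.per_population.values():
            assert fis == pytest.approx(1 - ho / hs, abs=1e-9)

    def test_simulated_inbreeding_recovered(self):
        cfg = simdata.SimConfig(
            n_loci=5000,
            populations=[
                simdata.PopulationConfig("A", 30, divergence=0.05, inbreeding=0.15)
            ],
            seed=31,
        )
        vm, truth = simdata.simulate_cohort(cfg)
        _, _, fis = basic_stats(vm, truth.population_map()).per_population["A"]
        assert fis == pytest.approx(0.15, abs=0.03)


class TestPairwiseFst:
    def test_identical_populations_near_zero(self):
        block = np.array([[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 1]], dtype=np.int16)
        vm = make_matrix(np.hstack([block, block]))
        fst = pairwise_fst(vm, pm_for(vm, split=4))
        assert fst.get("A", "B") <= 0.01

    def test_opposite_fixation_gives_one(self):
        vm = make_matrix(
            np.hstack([np.zeros((5, 4), dtype=np.int16), np.full((5, 4), 2, np.int16)])
        )
        fst = pairwise_fst(vm, pm_for(vm, split=4))
        assert fst.get("A", "B") == pytest.approx(1.0)

    def test_matrix_symmetric_zero_diagonal(self, two_pop_cohort):
        vm, truth = two_pop_cohort
        fst = pairwise_fst(vm, truth.population_map())
        assert np.allclose(fst.values, fst.values.T)
        assert np.all(np.diag(fst.values) == 0)

    def test_balding_nichols_parameter_recovery(self):
        cfg = simdata.SimConfig(
            n_loci=5000,
            populations=[
                simdata.PopulationConfig("A", 30, divergence=0.1),
                simdata.PopulationConfig("B", 30, divergence=0.1),
            ],
            seed=21,
        )
        vm, truth = simdata.simulate_cohort(cfg)
        theta = pairwise_fst(vm, truth.population_map()).get("A", "B")
        assert theta == pytest.approx(0.1, abs=0.02)

    def test_estimators_agree_on_balanced_design(self):
        cfg = simdata.SimConfig(
            n_loci=3000,
            populations=[
                simdata.PopulationConfig("A", 30, divergence=0.1),
                simdata.PopulationConfig("B", 30, divergence=0.1),
            ],
            seed=23,
        )
        vm, truth = simdata.simulate_cohort(cfg)
        pm = truth.population_map()
        wc = pairwise_fst(vm, pm, estimator="weir_cockerham").get("A", "B")
        nei = pairwise_fst(vm, pm, estimator="nei87").get("A", "B")
        assert abs(wc - nei) < 0.03

    def test_theta_monotone_in_divergence(self):
        thetas = []
        for f in (0.02, 0.1, 0.3):
            cfg = simdata.SimConfig(
                n_loci=2000,
                populations=[
                    simdata.PopulationConfig("A", 25, divergence=f),
                    simdata.PopulationConfig("B", 25, divergence=f),
                ],
                seed=29,
            )
            vm, truth = simdata.simulate_cohort(cfg)
            thetas.append(pairwise_fst(vm, truth.population_map()).get("A", "B"))
        assert thetas[0] < thetas[1] < thetas[2]

    def test_unknown_estimator_rejected(self, two_pop_cohort):
        vm, truth = two_pop_cohort
        with pytest.raises(ValueError):
            pairwise_fst(vm, truth.population_map(), estimator="hudson")


@pytest.fixture(scope="module")
def family_cohort():
    cfg = simdata.SimConfig(
        n_loci=2000,
        populations=[simdata.PopulationConfig("A", 30, divergence=0.0)],
        families=[simdata.FamilyConfig("A", 0, n_offspring=4)],
        seed=41,
    )
    return simdata.simulate_cohort(cfg)


class TestIbd:
    def test_duplicate_sample_pi_hat_near_one(self, family_cohort):
        vm, _ = family_cohort
        j = vm.sample_index("A_001")
        dup = VariantMatrix(
            loci=vm.loci,
            samples=vm.samples + ["dup"],
            dosage=np.hstack([vm.dosage, vm.dosage[:, [j]]]),
            call_ploidy=np.hstack([vm.call_ploidy, vm.call_ploidy[:, [j]]]),
            dp=np.hstack([vm.dp, vm.dp[:, [j]]]),
            gq=np.hstack([vm.gq, vm.gq[:, [j]]]),
            ad_ref=np.hstack([vm.ad_ref, vm.ad_ref[:, [j]]]),
            ad_alt=np.hstack([vm.ad_alt, vm.ad_alt[:, [j]]]),
        )
        ibd = ibd_estimates(dup)
        assert ibd.get("A_001", "dup") >= 0.95

    def test_parent_offspring_pi_hat_half_k1_one(self, family_cohort):
        vm, truth = family_cohort
        ibd = ibd_estimates(vm)
        for child, mother in truth.pedigree.items():
            pi = ibd.get(mother, child)
            assert pi == pytest.approx(0.5, abs=0.05)
            i, j = ibd.samples.index(mother), ibd.samples.index(child)
            assert ibd.k1[i, j] > 0.85

    def test_unrelated_pairs_low(self, family_cohort):
        vm, _ = family_cohort
        ibd = ibd_estimates(vm)
        vals = [
            ibd.get(f"A_{i:03d}", f"A_{j:03d}")
            for i in range(1, 12)
            for j in range(i + 1, 12)
        ]
        assert float(np.mean(vals)) <= 0.1

    def test_half_sib_pairs_quarter(self, family_cohort):
        vm, truth = family_cohort
        ibd = ibd_estimates(vm)
        kids = list(truth.pedigree)
        vals = [
            ibd.get(kids[i], kids[j])
            for i in range(len(kids))
            for j in range(i + 1, len(kids))
        ]
        assert np.mean(vals) == pytest.approx(0.25, abs=0.08)

    def test_k_probabilities_sum_to_one(self, family_cohort):
        vm, _ = family_cohort
        ibd = ibd_estimates(vm)
        total = ibd.k0 + ibd.k1 + ibd.k2
        off = ~np.eye(len(ibd.samples), dtype=bool)
        assert np.allclose(total[off], 1.0, atol=1e-6)
        assert np.allclose(ibd.pi_hat[off], ibd.k1[off] / 2 + ibd.k2[off], atol=1e-9)

    def test_polyploid_samples_excluded(self, mixed_ploidy_cohort):
        vm, truth = mixed_ploidy_cohort
        ibd = ibd_estimates(vm)
        assert all(truth.ploidies[s] == 2 for s in ibd.samples)

    def test_low_locus_pairs_flagged(self, family_cohort):
        vm, _ = family_cohort
        ibd = ibd_estimates(vm.subset_loci(np.arange(30)), min_loci=50)
        off = ~np.eye(len(ibd.samples), dtype=bool)
        assert ibd.low_confidence[off].all()
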