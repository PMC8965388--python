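import numpy as np
import pytest
from scipy.special import logsumexp

from broodnb.gtable import GenotypeTable
from broodnb.simulate import SimConfig, simulate_genotypes, truth_from_families
from broodnb.sibship import (K_COEFFS, FamilyLikelihoodModel, cluster_support,
                             family_clusters, genotype_priors, link_halfsibs,
                             mendel_tables, pairwise_llr, partition_fullsib,
                             reconstruct_parents, reconstruct_pedigree,
                             relationship_tables)

from conftest import fs_pairs, true_families


def table_from_matrix(G, freqs=None):
    G = np.asarray(G, dtype=np.int8)
    n, L = G.shape
    return GenotypeTable(
        individuals=np.array([f"i{k}" for k in range(n)], dtype=object),
        loci=np.array([f"l{k}" for k in range(L)], dtype=object),
        chrom=np.array(["chr1"] * L, dtype=object),
        pos=np.arange(1, L + 1, dtype=np.int64),
        genotypes=G)


class TestPairTables:
    def test_k_coefficients_sum_to_one(self):
        for k in K_COEFFS.values():
            assert sum(k) == pytest.approx(1.0)

    def test_pair_tables_are_distributions(self):
        freqs = np.array([0.1, 0.3, 0.5])
        tables = relationship_tables(freqs, eps=0.01)
        for R, T in tables.items():
            total = np.exp(T[:, :3, :3]).sum(axis=(1, 2))
            np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_hand_computed_both_aa_p_half(self):
        # alt freq 0.5, both genotypes hom-alt, eps=0:
        # P(U) = p^4 = 0.0625; P(FS) = p^4/4 + p^3/2 + p^2/4 = 0.140625
        tables = relationship_tables(np.array([0.5]), eps=0.0)
        assert np.exp(tables["U"][0, 2, 2]) == pytest.approx(0.0625)
        assert np.exp(tables["FS"][0, 2, 2]) == pytest.approx(0.140625)
        assert np.exp(tables["HS"][0, 2, 2]) == pytest.approx(
            0.5 * 0.0625 + 0.5 * 0.125)

    def test_duplicate_genotypes_classified_fs(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.2, 0.5, 200)
        g = rng.binomial(2, freqs).astype(np.int8)
        t = table_from_matrix(np.stack([g, g]))
        rel = pairwise_llr(t, freqs=freqs, eps=0.001)
        assert rel.ll["FS"][0, 1] > rel.ll["HS"][0, 1] > rel.ll["U"][0, 1]

    def test_unrelated_pairs_negative_fs_ratio(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.2, 0.5, 200)
        G = rng.binomial(2, np.broadcast_to(freqs, (10, 200))).astype(np.int8)
        rel = pairwise_llr(table_from_matrix(G), freqs=freqs, eps=0.001)
        iu = np.triu_indices(10, 1)
        assert (rel.ll["FS"] - rel.ll["U"])[iu].mean() < 0

    def test_min_loci_unclassifiable(self):
        G = np.zeros((2, 30), dtype=np.int8)
        rel = pairwise_llr(table_from_matrix(G),
                           freqs=np.full(30, 0.3), eps=0.001, min_loci=50)
        assert not rel.classifiable()[0, 1]


class TestPartition:
    def test_exact_recovery_ten_families(self):
        specs = [(f"A{i}", f"B{i}", 5) for i in range(10)]
        cfg = SimConfig(n_loci=300, genotyping_error=0.001, seed=30)
        truth = truth_from_families(specs, cfg)
        geno = simulate_genotypes(truth, cfg, seed=31)
        rel = pairwise_llr(geno, eps=0.001)
        model = FamilyLikelihoodModel.build(geno, eps=0.001)
        fams = partition_fullsib(rel, model)
        assert fs_pairs(fams) == fs_pairs(true_families(truth))

    def test_infinite_threshold_all_singletons(self):
        specs = [("A", "B", 6)]
        cfg = SimConfig(n_loci=100, seed=32)
        truth = truth_from_families(specs, cfg)
        geno = simulate_genotypes(truth, cfg, seed=33)
        rel = pairwise_llr(geno, eps=0.001)
        model = FamilyLikelihoodModel.build(geno, eps=0.001)
        fams = partition_fullsib(rel, model, threshold=np.inf, max_passes=0)
        assert all(len(f) == 1 for f in fams)

    def test_halfsibs_not_absorbed_into_families(self):
        # two families sharing a parent must stay separate FS families
        specs = [("X", "B0", 8), ("X", "B1", 8)]
        cfg = SimConfig(n_loci=300, genotyping_error=0.001, seed=34)
        truth = truth_from_families(specs, cfg)
        geno = simulate_genotypes(truth, cfg, seed=35)
        # sample allele-freq estimates are useless for 2 families: use truth
        rel = pairwise_llr(geno, freqs=truth.allele_freqs, eps=0.001)
        model = FamilyLikelihoodModel.build(geno, freqs=truth.allele_freqs,
                                            eps=0.001)
        fams = partition_fullsib(rel, model)
        assert fs_pairs(fams) == fs_pairs(true_families(truth))


class TestReconstructParents:
    def test_all_homozygous_family(self):
        # family of 6 all hom-ref at a locus with alt freq 0.5
        G = np.zeros((6, 1), dtype=np.int8)
        model = FamilyLikelihoodModel.build(table_from_matrix(G),
                                            freqs=np.array([0.5]), eps=0.0)
        rec = reconstruct_parents(model, [f"i{k}" for k in range(6)])
        assert rec["argmax_pair"][0] == (0, 0)
        # enumeration oracle for the posterior ratio (0,0) vs (0,1):
        # prior(0,0) * 1 vs prior(0,1) * (1/2)^6
        prior = genotype_priors(np.array([0.5]))[0]
        p00 = prior[0] ** 2
        p01 = 2 * prior[0] * prior[1] * 0.5 ** 6
        p11 = prior[1] ** 2 * 0.25 ** 6
        post = rec["posterior"][0]
        want = p00 / (p00 + p01 + p11)
        # remaining pairs have zero likelihood
        assert post[0, 0] == pytest.approx(want, abs=1e-9)

    def test_three_genotype_classes_force_double_het(self):
        G = np.array([[0], [1], [2]], dtype=np.int8)
        model = FamilyLikelihoodModel.build(table_from_matrix(G),
                                            freqs=np.array([0.4]), eps=0.0)
        rec = reconstruct_parents(model, ["i0", "i1", "i2"])
        assert rec["argmax_pair"][0] == (1, 1)
        assert rec["argmax_mass"][0] == pytest.approx(1.0)

    def test_posterior_entropy_grows_with_error(self):
        G = np.zeros((5, 1), dtype=np.int8)
        ents = []
        for eps in (0.001, 0.05, 0.2):
            model = FamilyLikelihoodModel.build(table_from_matrix(G),
                                                freqs=np.array([0.5]),
                                                eps=eps)
            post = reconstruct_parents(model, [f"i{k}" for k in range(5)]
                                       )["posterior"][0]
            p = post.ravel()
            p = p[p > 0]
            ents.append(-(p * np.log(p)).sum())
        assert ents[0] < ents[1] < ents[2]

    def test_all_missing_locus_flagged(self):
        G = np.full((3, 2), -1, dtype=np.int8)
        G[:, 0] = 1
        model = FamilyLikelihoodModel.build(table_from_matrix(G),
                                            freqs=np.array([0.4, 0.4]),
                                            eps=0.001)
        rec = reconstruct_parents(model, ["i0", "i1", "i2"])
        assert not rec["uninformative"][0]
        assert rec["uninformative"][1]


class TestHalfsibLinking:
    def build(self, specs, seed, n_loci=300):
        cfg = SimConfig(n_loci=n_loci, genotyping_error=0.001, seed=seed)
        truth = truth_from_families(specs, cfg)
        geno = simulate_genotypes(truth, cfg, seed=seed + 100)
        return truth, geno

    def test_shared_parent_recovered(self):
        truth, geno = self.build([("X", "B0", 8), ("X", "B1", 8)], seed=40)
        ped = reconstruct_pedigree(geno, eps=0.001,
                                   freqs=truth.allele_freqs)
        # the two families end up sharing exactly one inferred parent id
        fams = [set(ped.parents[o] for o in fam) for fam in ped.families]
        assert len(ped.families) == 2
        pair_sets = [set(next(iter(f))) for f in fams]
        assert len(pair_sets[0] & pair_sets[1]) == 1

    def test_disjoint_families_rarely_linked(self):
        linked = 0
        reps = 15
        for seed in range(reps):
            truth, geno = self.build(
                [("A", "B", 6), ("C", "D", 6), ("E", "F", 6)],
                seed=50 + seed, n_loci=200)
            ped = reconstruct_pedigree(geno, eps=0.001,
                                       freqs=truth.allele_freqs)
            parent_ids = [ped.parents[fam[0]] for fam in ped.families]
            flat = [p for pair in parent_ids for p in pair]
            if len(set(flat)) < len(flat):
                linked += 1
        assert linked <= max(1, int(0.05 * reps) + 1)

    def test_single_family_two_parents(self):
        truth, geno = self.build([("A", "B", 6)], seed=60)
        ped = reconstruct_pedigree(geno, eps=0.001,
                                   freqs=truth.allele_freqs)
        assert len(ped.parent_ids) == 2

    def test_pedigree_identity_two_slots_per_offspring(self):
        truth, geno = self.build([("X", "B0", 5), ("X", "B1", 5),
                                  ("C", "D", 5)], seed=70)
        ped = reconstruct_pedigree(geno, eps=0.001)
        counts = {}
        for off, (p1, p2) in ped.parents.items():
            counts[p1] = counts.get(p1, 0) + 1
            counts[p2] = counts.get(p2, 0) + 1
        assert sum(counts.values()) == 2 * len(ped.parents)


class TestClusters:
    def test_halfsib_chain_single_cluster(self):
        # o1-o2 share X, o2-o3 share Y -> all three in one cluster
        specs = [("X", "A", 4), ("X", "Y", 4), ("Y", "B", 4)]
        cfg = SimConfig(n_loci=300, genotyping_error=0.001, seed=80)
        truth = truth_from_families(specs, cfg)
        geno = simulate_genotypes(truth, cfg, seed=81)
        ped = reconstruct_pedigree(geno, eps=0.001,
                                   freqs=truth.allele_freqs)
        assert len(ped.clusters) == 1
        assert len(ped.clusters[0]) == 12

    def test_disjoint_families_two_clusters(self):
        specs = [("A", "B", 5), ("C", "D", 5)]
        cfg = SimConfig(n_loci=300, genotyping_error=0.001, seed=82)
        truth = truth_from_families(specs, cfg)
        geno = simulate_genotypes(truth, cfg, seed=83)
        ped = reconstruct_pedigree(geno, eps=0.001)
        assert len(ped.clusters) == 2

    def test_bootstrap_support_strong_signal(self):
        specs = [("X", "B0", 8), ("X", "B1", 8)]
        cfg = SimConfig(n_loci=300, genotyping_error=0.001, seed=84)
        truth = truth_from_families(specs, cfg)
        geno = simulate_genotypes(truth, cfg, seed=85)
        ped = reconstruct_pedigree(geno, eps=0.001)
        clusters, supports = cluster_support(ped, geno, eps=0.001, B=20,
                                             seed=1)
        big = max(range(len(clusters)), key=lambda k: len(clusters[k]))
        assert supports[big] >= 0.9

    def test_singleton_support_is_one(self):
        G = np.random.default_rng(0).binomial(
            2, 0.3, size=(1, 60)).astype(np.int8)
        t = table_from_matrix(G)
        ped = reconstruct_pedigree(t, eps=0.001, min_loci=10)
        clusters, supports = cluster_support(ped, t, eps=0.001, B=5, seed=0)
        assert supports == [1.0]

    def test_bootstrap_b_zero_rejected(self):
        G = np.zeros((2, 10), dtype=np.int8)
        t = table_from_matrix(G)
        ped = reconstruct_pedigree(t, eps=0.001, min_loci=1)
        with pytest.raises(ValueError):
            cluster_support(ped, t, B=0)


def test_mendel_tables_are_distributions():
    freqs = np.array([0.2, 0.5])
    M = mendel_tables(freqs, eps=0.01)
    total = np.exp(M[:, :, :, :3]).sum(axis=3)
    np.testing.assert_allclose(total, 1.0, atol=1e-9)
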