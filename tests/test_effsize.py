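import math

import numpy as np
import pandas as pd
import pytest

from broodnb.effsize import (NbEstimate, ReproSuccess, burrows_r2, chao2,
                             expected_r2, jackknife1, nb_from_r2prime, nb_ld,
                             nb_sibship, parent_accumulation, repro_summary,
                             richness_estimates, sf_point)
from broodnb.gtable import MISSING, GenotypeTable


def pedigree_n_over_p(n, p, rng=None):
    """Any pedigree with n offspring, each 2 parents, all p parents used."""
    rng = rng or np.random.default_rng(0)
    parents = [f"P{k}" for k in range(p)]
    out = {}
    for i in range(n):
        if i < p // 2:  # guarantee every parent contributes
            pair = (parents[2 * i], parents[2 * i + 1])
        else:
            a, b = rng.choice(p, size=2, replace=False)
            pair = (parents[a], parents[b])
        out[f"O{i}"] = pair
    return out


class TestReproSummary:
    @pytest.mark.parametrize("n,p,kbar", [(1011, 100, 20.22), (19, 12, 3.17),
                                          (389, 76, 10.24), (34, 13, 5.23),
                                          (29, 14, 4.14)])
    def test_kbar_identity(self, n, p, kbar):
        ped = pedigree_n_over_p(n, p)
        rs = repro_summary(ped, list(ped))
        assert rs.ns == p
        assert round(rs.kbar, 2) == kbar

    def test_uniform_counts_zero_variance(self):
        ped = {f"O{i}": (f"P{2*i}", f"P{2*i+1}") for i in range(6)}
        rs = repro_summary(ped, list(ped))
        assert rs.vk == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            repro_summary({}, [])

    def test_identity_sum_counts(self):
        ped = pedigree_n_over_p(50, 20)
        rs = repro_summary(ped, list(ped))
        assert sum(rs.counts.values()) == 100
        assert rs.kbar * rs.ns == pytest.approx(2 * 50)


class TestSibshipNb:
    @pytest.mark.parametrize("ns,kbar,vk,want", [
        (100, 20.22, 918.39, 31),
        (14, 4.14, 26.55, 6),
        (13, 5.23, 24.02, 7),
        (76, 10.24, 799.50, 9),
        (12, 3.17, 4.81, 10),
    ])
    def test_published_sf_values(self, ns, kbar, vk, want):
        rs = ReproSuccess(cohort="", n_offspring=0, ns=ns, kbar=kbar, vk=vk)
        est = nb_sibship(rs, B=0)
        assert round(est.point) == want

    def test_poisson_like_algebraic_oracle(self):
        # V_k = k-bar -> point = (k N - 2)/k = N - 2/k
        ns, kbar = 40, 6.0
        assert sf_point(ns, kbar, kbar) == pytest.approx(ns - 2 / kbar)

    def test_invalid_inputs_rejected(self):
        rs = ReproSuccess("", 0, ns=1, kbar=5.0, vk=1.0)
        with pytest.raises(ValueError):
            nb_sibship(rs)

    def test_bootstrap_ci_brackets_point(self):
        ped = pedigree_n_over_p(200, 30, rng=np.random.default_rng(4))
        members = list(ped)
        rs = repro_summary(ped, members)
        est = nb_sibship(rs, ped, members, B=200, seed=1)
        assert est.ci_low <= est.point <= est.ci_high


class TestBurrowsR2:
    def test_perfect_correlation_toy(self):
        # 8 individuals, p = q = 0.5, HWE proportions, identical vectors
        x = np.array([0, 0, 1, 1, 1, 1, 2, 2], dtype=np.int8)
        assert burrows_r2(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_skipped(self):
        x = np.zeros(10, dtype=np.int8)
        y = np.array([0, 1] * 5, dtype=np.int8)
        assert math.isnan(burrows_r2(x, y))

    def test_missing_handled(self):
        x = np.array([0, 0, 1, 1, 1, 1, 2, 2, MISSING], dtype=np.int8)
        y = np.array([0, 0, 1, 1, 1, 1, 2, 2, 2], dtype=np.int8)
        assert burrows_r2(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_independence_mean_near_1_over_s(self):
        rng = np.random.default_rng(5)
        S = 50
        vals = []
        for _ in range(2000):
            x = rng.binomial(2, 0.3, S).astype(np.int8)
            y = rng.binomial(2, 0.4, S).astype(np.int8)
            r = burrows_r2(x, y)
            if not math.isnan(r):
                vals.append(r)
        assert np.mean(vals) == pytest.approx(1 / S, rel=0.15)


class TestLDNb:
    def make_table(self, G, chroms):
        G = np.asarray(G, dtype=np.int8)
        n, L = G.shape
        return GenotypeTable(
            individuals=np.array([f"i{k}" for k in range(n)], dtype=object),
            loci=np.array([f"l{k}" for k in range(L)], dtype=object),
            chrom=np.array(chroms, dtype=object),
            pos=np.arange(1, L + 1, dtype=np.int64),
            genotypes=G)

    def test_single_chromosome_errors(self):
        rng = np.random.default_rng(6)
        G = rng.binomial(2, 0.3, (20, 10))
        t = self.make_table(G, ["chr1"] * 10)
        with pytest.raises(ValueError):
            nb_ld(t)

    def test_negative_adjusted_r2_reports_infinity(self):
        assert nb_from_r2prime(-0.001, 100) == float("inf")
        assert nb_from_r2prime(0.0, 10) == float("inf")

    def test_expected_r2_forms(self):
        assert expected_r2(100) == pytest.approx(1 / 100 + 3.19 / 100**2)
        assert expected_r2(20) == pytest.approx(
            0.0018 + 0.907 / 20 + 4.44 / 400)

    def test_point_estimate_reasonable(self):
        from broodnb.simulate import (SimConfig, simulate_genotypes,
                                      simulate_truth)

        cfg = SimConfig(parents_per_year=50, offspring_per_year=100,
                        n_loci=200, n_chromosomes=20, genotyping_error=0.0,
                        mating_design="random_union",
                        parent_equilibrium_generations=6, seed=42)
        truth = simulate_truth(cfg)
        geno = simulate_genotypes(truth, cfg)
        est = nb_ld(geno)
        assert est.method == "LD"
        assert 25 < est.point < 100
        assert est.ci_low <= est.point <= est.ci_high
        assert est.S == pytest.approx(100, abs=1)

    def test_pcrit_excludes_rare_alleles(self):
        rng = np.random.default_rng(7)
        G = np.concatenate([rng.binomial(2, 0.3, (60, 10)),
                            rng.binomial(2, 0.01, (60, 10))], axis=1)
        t = self.make_table(G, ["chr1"] * 10 + ["chr2"] * 5 + ["chr3"] * 5)
        # rare loci on chr2/chr3 all excluded -> only chr1 left -> error
        with pytest.raises(ValueError):
            nb_ld(t, pcrit=0.05)


class TestAccumulation:
    def test_monotone_and_exhaustive(self):
        ped = pedigree_n_over_p(40, 12, rng=np.random.default_rng(8))
        members = list(ped)
        rs = repro_summary(ped, members)
        acc = parent_accumulation(ped, members, n_perm=25, seed=2)
        assert (np.diff(acc["mean"]) >= 0).all()
        assert acc["mean"].iloc[-1] == rs.ns           # every permutation
        assert acc["sd"].iloc[-1] == 0.0

    def test_all_fullsibs_flat_at_two(self):
        ped = {f"O{i}": ("A", "B") for i in range(10)}
        acc = parent_accumulation(ped, list(ped), n_perm=10, seed=3)
        assert (acc["mean"] == 2).all()


class TestRichness:
    def test_worked_example(self):
        # S_obs=10, q1=4, q2=2, m=5:
        # chao2 = 10 + 0.8 * 16/4 = 13.2 ; jackknife1 = 10 + 4*0.8 = 13.2
        est, se = chao2(10, 4, 2, 5)
        assert est == pytest.approx(13.2)
        jest, _ = jackknife1(10, 4, 5)
        assert jest == pytest.approx(13.2)

    def test_no_singletons_returns_s_obs(self):
        est, se = chao2(8, 0, 3, 10)
        assert est == 8.0
        jest, _ = jackknife1(8, 0, 10)
        assert jest == 8.0

    def test_q2_zero_bias_corrected(self):
        est, se = chao2(5, 3, 0, 10)
        assert est == pytest.approx(5 + 0.9 * 3 * 2 / 2.0)
        assert se >= 0

    def test_estimates_bounded_below_by_s_obs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            ped = pedigree_n_over_p(rng.integers(4, 30),
                                    rng.integers(4, 20), rng=rng)
            members = list(ped)
            chao, jack = richness_estimates(ped, members)
            assert chao.ns_hat >= chao.s_obs
            assert jack.ns_hat >= jack.s_obs
            assert chao.q1 + chao.q2 <= chao.s_obs

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            richness_estimates({"O0": ("A", "B")}, ["O0"])

    def test_half_sampled_cohort_recovers_parent_count(self):
        # sample half the offspring; Chao2 should land near the true total
        rng = np.random.default_rng(10)
        ratios = []
        for rep in range(40):
            ped = pedigree_n_over_p(120, 40, rng=rng)
            members = list(ped)
            half = [members[i] for i in
                    rng.choice(len(members), 60, replace=False)]
            chao, _ = richness_estimates(ped, half)
            ratios.append(chao.ns_hat / 40)
        assert abs(np.mean(ratios) - 1.0) < 0.15
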