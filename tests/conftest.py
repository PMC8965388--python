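import numpy as np
import pytest

from broodnb.simulate import (SimConfig, simulate_genotypes, simulate_lengths,
                              simulate_truth, truth_from_families)


@pytest.fixture(scope="session")
def small_scenario():
    """One spawning year, 10 parents, 50 offspring, 100 loci."""
    cfg = SimConfig(n_spawn_years=1, parents_per_year=10,
                    offspring_per_year=50, n_loci=100, n_chromosomes=5,
                    genotyping_error=0.001, seed=11)
    truth = simulate_truth(cfg)
    geno = simulate_genotypes(truth, cfg)
    lengths = simulate_lengths(truth, cfg)
    return cfg, truth, geno, lengths


@pytest.fixture(scope="session")
def family_scenario():
    """Ten full-sib families of 5-10 with half-sib links, 200 loci."""
    rng = np.random.default_rng(5)
    sizes = rng.integers(5, 11, size=10)
    specs = [("A0", "B0", int(sizes[0])), ("A0", "B1", int(sizes[1])),
             ("A1", "B2", int(sizes[2])), ("A1", "B3", int(sizes[3]))]
    specs += [(f"C{i}", f"D{i}", int(sizes[i])) for i in range(4, 10)]
    cfg = SimConfig(n_loci=200, n_chromosomes=10, genotyping_error=0.001,
                    seed=5)
    truth = truth_from_families(specs, cfg)
    geno = simulate_genotypes(truth, cfg, seed=105)
    return cfg, truth, geno


def fs_pairs(families):
    out = set()
    for fam in families:
        fam = list(fam)
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                out.add(frozenset((fam[i], fam[j])))
    return out


def true_families(truth):
    fams = {}
    for off, pair in truth.true_pedigree.items():
        fams.setdefault(frozenset(pair), []).append(off)
    return list(fams.values())
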