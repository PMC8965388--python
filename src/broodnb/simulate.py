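"""Synthetic multi-cohort spawning scenarios with full truth tables.

Simulates semelparous spawning years: per-year parent pools are disjoint,
matings are either random disjoint pairs or polygamous with gamma-skewed
reproductive success, offspring inherit biallelic SNPs Mendelian-style with
genotyping error / missingness / read depth, and larval lengths follow
Gaussian length-at-age distributions.  Every stage of the inference pipeline
can therefore be tested against a known pedigree and cohort structure.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gtable import MISSING, GenotypeTable


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    n_spawn_years: int = 1
    first_spawn_year: int = 2015
    parents_per_year: int = 20
    # "polygamous_skewed": each offspring draws two distinct parents with
    #   gamma-skewed weights (semelparous field scenario).
    # "random_pairs": parents split into disjoint monogamous pairs.
    # "random_union": random union of gametes incl. selfing -- the idealized
    #   model the LD estimator is calibrated against.
    mating_design: str = "polygamous_skewed"
    offspring_per_year: int = 100
    vk_target: float | None = None             # None -> Poisson-like pairing noise only
    n_loci: int = 200
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    n_chromosomes: int = 10
    locus_spacing_bp: int = 2_000_000
    genotyping_error: float = 0.001
    missing_rate: float = 0.0
    depth_mean: float = 34.0
    depth_overdispersion: float = 5.0          # NB size parameter; larger = tighter
    length_at_age: list[tuple[float, float]] = field(
        default_factory=lambda: [(45.0, 5.0), (75.0, 6.0), (95.0, 6.0)])
    collections: list[tuple[int, float]] = field(
        default_factory=lambda: [(2017, 1.0)])
    stream: str = "sim_stream"
    on_target_fraction: float = 1.0
    n_paralog_pairs: int = 0                   # merged locus pairs for HDplot tests
    # generations of size-N random mating before the focal spawning, so the
    # parent pool carries equilibrium background LD (~1/(3N) for unlinked
    # loci) rather than none; 0 = parents drawn i.i.d. from HWE
    parent_equilibrium_generations: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.parents_per_year < 2:
            raise ConfigError("parents_per_year must be >= 2")
        if not (0.0 <= self.genotyping_error < 1.0):
            raise ConfigError("genotyping_error must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("allele frequencies must lie in (0, 1)")
        for mean, sd in self.length_at_age:
            if sd < 0:
                raise ConfigError("length sd must be >= 0")
        if self.mating_design not in ("random_pairs", "polygamous_skewed",
                                      "random_union"):
            raise ConfigError(f"unknown mating_design {self.mating_design!r}")


@dataclass
class TruthSet:
    """Ground truth: pedigree, cohorts, parent genotypes, per-year k-bar/V_k."""

    parents_by_year: dict[int, list[str]]
    true_pedigree: dict[str, tuple[str, str]]   # offspring -> unordered parent pair
    true_cohort: dict[str, int]                 # offspring -> spawn year
    allele_freqs: np.ndarray                    # (L,) alt-allele frequency
    parent_genotypes: dict[str, np.ndarray]     # parent -> (L,) int8 alt counts
    kbar_true: dict[int, float]
    vk_true: dict[int, float]

    @property
    def offspring(self) -> list[str]:
        return list(self.true_pedigree)


def _gamma_shape_for_vk(kbar: float, vk_target: float, n_parents: int) -> float:
    # E[V_k] ~ kbar*(1 - 1/N) + kbar^2 / shape under weighted pair sampling;
    # invert for shape, clamped to a sane range.
    base = kbar * (1.0 - 1.0 / n_parents)
    excess = vk_target - base
    if excess <= 0:
        return 1e6  # effectively equal weights
    return float(np.clip(kbar**2 / excess, 1e-3, 1e6))


def simulate_truth(config: SimConfig) -> TruthSet:
    """Draw the breeding structure: parents, matings, pedigree, cohorts.

    Deterministic given ``config.seed``.  Parent pools for different spawn
    years are disjoint (semelparity).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=config.n_loci)

    parents_by_year: dict[int, list[str]] = {}
    pedigree: dict[str, tuple[str, str]] = {}
    cohort: dict[str, int] = {}
    kbar_true: dict[int, float] = {}
    vk_true: dict[int, float] = {}
    parent_genotypes: dict[str, np.ndarray] = {}

    for y_idx in range(config.n_spawn_years):
        year = config.first_spawn_year + y_idx
        N = config.parents_per_year
        n = config.offspring_per_year
        parents = [f"P{year}_{i:04d}" for i in range(N)]
        parents_by_year[year] = parents
        selfing_ok = config.mating_design == "random_union"
        pool = rng.binomial(2, np.broadcast_to(freqs, (N, len(freqs))))
        pool = pool.astype(np.int8)
        for _ in range(config.parent_equilibrium_generations):
            nxt = np.empty_like(pool)
            for i in range(N):
                if selfing_ok:
                    a, b = rng.integers(0, N, size=2)
                else:
                    a, b = rng.choice(N, size=2, replace=False)
                nxt[i] = ((rng.random(len(freqs)) < pool[a] / 2.0)
                          .astype(np.int8)
                          + (rng.random(len(freqs)) < pool[b] / 2.0)
                          .astype(np.int8))
            pool = nxt
        for i, p in enumerate(parents):
            parent_genotypes[p] = pool[i]

        if config.mating_design == "random_union":
            picks = rng.integers(0, N, size=(n, 2))
            assignments = [(parents[a], parents[b]) for a, b in picks]
        elif config.mating_design == "random_pairs":
            order = rng.permutation(N)
            pairs = [(parents[order[2 * i]], parents[order[2 * i + 1]])
                     for i in range(N // 2)]
            pair_idx = rng.integers(0, len(pairs), size=n)
            assignments = [pairs[j] for j in pair_idx]
        else:
            if config.vk_target is None:
                w = np.ones(N)
            else:
                kbar_all = 2.0 * n / N
                shape = _gamma_shape_for_vk(kbar_all, config.vk_target, N)
                w = rng.gamma(shape, 1.0, size=N)
            w = w / w.sum()
            assignments = []
            for _ in range(n):
                i, j = rng.choice(N, size=2, replace=False, p=w)
                assignments.append((parents[i], parents[j]))

        counts: dict[str, int] = {}
        for k, (p1, p2) in enumerate(assignments):
            off = f"O{year}_{k:05d}"
            pedigree[off] = (p1, p2)
            cohort[off] = year
            counts[p1] = counts.get(p1, 0) + 1
            counts[p2] = counts.get(p2, 0) + 1
        ks = np.array(list(counts.values()), dtype=float)
        kbar_true[year] = 2.0 * n / len(counts)
        vk_true[year] = float(ks.var(ddof=1)) if len(ks) > 1 else 0.0

    return TruthSet(parents_by_year=parents_by_year, true_pedigree=pedigree,
                    true_cohort=cohort, allele_freqs=freqs,
                    parent_genotypes=parent_genotypes,
                    kbar_true=kbar_true, vk_true=vk_true)


def truth_from_families(family_specs: list[tuple[str, str, int]],
                        config: SimConfig, spawn_year: int | None = None,
                        seed: int | None = None) -> TruthSet:
    """Build a TruthSet from an explicit family design.

    ``family_specs`` is a list of (parent1, parent2, n_offspring); repeating
    a parent id across specs creates half-sib links.  Parent genotypes and
    allele frequencies are drawn as in :func:`simulate_truth`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    year = config.first_spawn_year if spawn_year is None else spawn_year
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=config.n_loci)

    parents = sorted({p for p1, p2, _ in family_specs for p in (p1, p2)})
    parent_genotypes = {p: rng.binomial(2, freqs).astype(np.int8)
                        for p in parents}
    pedigree: dict[str, tuple[str, str]] = {}
    cohort: dict[str, int] = {}
    counts: dict[str, int] = {}
    k = 0
    for p1, p2, size in family_specs:
        for _ in range(size):
            off = f"O{year}_{k:05d}"
            pedigree[off] = (p1, p2)
            cohort[off] = year
            counts[p1] = counts.get(p1, 0) + 1
            counts[p2] = counts.get(p2, 0) + 1
            k += 1
    ks = np.array(list(counts.values()), dtype=float)
    n = len(pedigree)
    return TruthSet(parents_by_year={year: parents}, true_pedigree=pedigree,
                    true_cohort=cohort, allele_freqs=freqs,
                    parent_genotypes=parent_genotypes,
                    kbar_true={year: 2.0 * n / len(counts)},
                    vk_true={year: float(ks.var(ddof=1)) if len(ks) > 1
                             else 0.0})


def _locus_coordinates(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    L, C = config.n_loci, config.n_chromosomes
    per = int(np.ceil(L / C))
    chrom = np.array([f"chr{i // per + 1}" for i in range(L)], dtype=object)
    pos = np.array([1 + (i % per) * config.locus_spacing_bp for i in range(L)],
                   dtype=np.int64)
    return chrom, pos


def simulate_genotypes(truth: TruthSet, config: SimConfig,
                       seed: int | None = None) -> GenotypeTable:
    """Mendelian offspring genotypes with error, missingness and read depth.

    Each offspring receives one allele from each true parent per locus; with
    probability ``genotyping_error`` the observed genotype is replaced by a
    fresh Hardy-Weinberg draw at that locus; calls are dropped at
    ``missing_rate``; depths are negative-binomial around ``depth_mean``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    offspring = truth.offspring
    n, L = len(offspring), config.n_loci
    p = truth.allele_freqs

    G = np.empty((n, L), dtype=np.int8)
    for i, off in enumerate(offspring):
        p1, p2 = truth.true_pedigree[off]
        g1 = truth.parent_genotypes[p1]
        g2 = truth.parent_genotypes[p2]
        a1 = rng.random(L) < g1 / 2.0
        a2 = rng.random(L) < g2 / 2.0
        G[i] = a1.astype(np.int8) + a2.astype(np.int8)

    eps = config.genotyping_error
    if eps > 0:
        err = rng.random((n, L)) < eps
        hwe = rng.binomial(2, np.broadcast_to(p, (n, L))).astype(np.int8)
        G = np.where(err, hwe, G)

    # depth: NB parameterized by mean mu and size k (var = mu + mu^2/k)
    k = config.depth_overdispersion
    mu = config.depth_mean
    dp = rng.negative_binomial(k, k / (k + mu), size=(n, L)).astype(np.int32)

    alt = np.zeros((n, L), dtype=np.int32)
    alt[G == 2] = dp[G == 2]
    het = G == 1
    alt[het] = rng.binomial(dp[het], 0.5)

    if config.n_paralog_pairs > 0:
        G, dp, alt = _inject_paralogs(G, dp, alt, config.n_paralog_pairs, rng)

    if config.missing_rate > 0:
        miss = rng.random(G.shape) < config.missing_rate
        G = np.where(miss, MISSING, G)
        dp = np.where(miss, 0, dp)
        alt = np.where(miss, 0, alt)

    chrom, pos = _locus_coordinates(config)
    loci = np.array([f"{c}:{q}" for c, q in zip(chrom, pos)], dtype=object)
    on_target = rng.random(L) < config.on_target_fraction
    region = np.where(on_target, np.arange(L), -1)

    return GenotypeTable(individuals=np.array(offspring, dtype=object),
                         loci=loci, chrom=chrom, pos=pos, genotypes=G,
                         depths=dp, alt_depths=alt, on_target=on_target,
                         target_region=region)


def _inject_paralogs(G, dp, alt, n_pairs, rng):
    """Overwrite the first ``n_pairs`` loci with reads merged from locus pairs.

    Merged loci mimic collapsed paralogs: apparent heterozygosity is inflated
    and heterozygote read ratios deviate from 1:1, which the H/D screen must
    flag.
    """
    G, dp, alt = G.copy(), dp.copy(), alt.copy()
    L = G.shape[1]
    for j in range(n_pairs):
        a, b = L - 2 * j - 2, L - 2 * j - 1  # merge the last loci pairwise
        tot = np.maximum(dp[:, a] + dp[:, b], 1)
        frac = (G[:, a] + G[:, b]) / 4.0
        merged_alt = rng.binomial(tot, frac)
        called = np.where(merged_alt == 0, 0, np.where(merged_alt == tot, 2, 1))
        G[:, j] = called.astype(np.int8)
        dp[:, j] = tot
        alt[:, j] = merged_alt
    return G, dp, alt


def simulate_lengths(truth: TruthSet, config: SimConfig,
                     seed: int | None = None) -> pd.DataFrame:
    """Sample individuals into collections and draw lengths from age bands.

    Returns columns ``id, stream, collection_year, length_mm``.  Each
    individual appears in at most one collection (sampling without
    replacement across collections); its age is collection year minus spawn
    year and must have a ``length_at_age`` entry.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    unsampled: dict[int, list[str]] = {}
    for off, year in truth.true_cohort.items():
        unsampled.setdefault(year, []).append(off)

    rows = []
    for cyear, frac in sorted(config.collections):
        for syear in sorted(unsampled):
            age = cyear - syear
            if age < 0:
                continue
            pool = unsampled[syear]
            if not pool:
                continue
            if age >= len(config.length_at_age):
                raise ConfigError(
                    f"no length_at_age entry for age {age} "
                    f"(spawn {syear}, collection {cyear})")
            take = int(round(frac * len(pool)))
            idx = rng.choice(len(pool), size=min(take, len(pool)), replace=False)
            chosen = [pool[i] for i in sorted(idx)]
            unsampled[syear] = [o for i, o in enumerate(pool) if i not in set(idx)]
            mean, sd = config.length_at_age[age]
            lengths = np.maximum(rng.normal(mean, sd, size=len(chosen)), 0.0)
            for off, lmm in zip(chosen, lengths):
                rows.append((off, config.stream, cyear, float(lmm)))

    return pd.DataFrame(rows, columns=["id", "stream", "collection_year",
                                       "length_mm"])


def write_fixtures(truth: TruthSet, genotypes: GenotypeTable,
                   lengths: pd.DataFrame, out_dir: str) -> dict[str, str]:
    """Write VCF + individuals CSV under ``out_dir`` and truth tables under
    ``out_dir/truth`` (kept separate so inference stages never read them)."""
    from .io import write_genotypes_vcf

    os.makedirs(out_dir, exist_ok=True)
    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)

    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "individuals": os.path.join(out_dir, "individuals.csv"),
        "pedigree": os.path.join(truth_dir, "true_pedigree.tsv"),
        "cohorts": os.path.join(truth_dir, "true_cohorts.tsv"),
    }
    write_genotypes_vcf(genotypes, paths["vcf"])
    lengths.to_csv(paths["individuals"], index=False)

    ped = pd.DataFrame(
        [(o, p1, p2) for o, (p1, p2) in truth.true_pedigree.items()],
        columns=["offspring", "parent1", "parent2"])
    ped.to_csv(paths["pedigree"], sep="\t", index=False)
    coh = pd.DataFrame(sorted(truth.true_cohort.items()),
                       columns=["offspring", "spawn_year"])
    coh.to_csv(paths["cohorts"], sep="\t", index=False)
    return paths
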