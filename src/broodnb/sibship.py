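"""Sibship and pedigree reconstruction from offspring SNP genotypes.

The pipeline is: pairwise relationship screening (full-sib / half-sib /
unrelated log-likelihoods via identity-coefficient mixtures), graph-based
full-sib partitioning with greedy joint-likelihood refinement, parental
genotype-pair reconstruction per family, greedy half-sib linking of families
through shared reconstructed parents, and family-cluster extraction with
locus-bootstrap support.

Genotypes are alt-allele counts (0/1/2, -1 missing).  The mistyping model
replaces an observed genotype with a Hardy-Weinberg draw at rate ``eps``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .gtable import MISSING, GenotypeTable

# identity-coefficient mixtures over (0, 1, 2) alleles shared IBD
K_COEFFS = {
    "FS": (0.25, 0.5, 0.25),
    "HS": (0.5, 0.5, 0.0),
    "U": (1.0, 0.0, 0.0),
}

TINY = 1e-300


@dataclass
class RelLikelihoods:
    individuals: np.ndarray
    ll: dict[str, np.ndarray]        # relationship -> (n, n) log-likelihood
    n_loci_used: np.ndarray          # (n, n) overlapping informative loci
    min_loci: int = 50

    def log_ratio(self, a: str, b: str) -> np.ndarray:
        return self.ll[a] - self.ll[b]

    def classifiable(self) -> np.ndarray:
        return self.n_loci_used >= self.min_loci


@dataclass
class Pedigree:
    offspring: np.ndarray
    parents: dict[str, tuple[str, str]]            # offspring -> (p1, p2)
    families: list[list[str]]                      # full-sib families
    parent_posteriors: dict[str, np.ndarray] = field(default_factory=dict)
    clusters: list[list[str]] = field(default_factory=list)
    cluster_support: list[float] = field(default_factory=list)

    @property
    def parent_ids(self) -> list[str]:
        out: set[str] = set()
        for p1, p2 in self.parents.values():
            out.update((p1, p2))
        return sorted(out)

    def offspring_parent_graph(self) -> nx.Graph:
        g = nx.Graph()
        for off, (p1, p2) in self.parents.items():
            g.add_edge(off, p1)
            g.add_edge(off, p2)
        return g


def genotype_priors(freqs: np.ndarray) -> np.ndarray:
    """HWE genotype probabilities, shape (L, 3), for alt frequencies."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=1)


def _error_matrix(pg: np.ndarray, eps: float) -> np.ndarray:
    """Observation model (L, 3, 3): E[l, true, obs] = P(obs | true)."""
    L = pg.shape[0]
    eye = np.broadcast_to(np.eye(3), (L, 3, 3))
    return (1.0 - eps) * eye + eps * pg[:, None, :]


def _shared_one_tables(pg: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """P(g_i, g_j | share exactly one allele IBD), shape (L, 3, 3)."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    L = len(p)
    zeros = np.zeros(L)
    # genotype of j given the shared allele is alt / ref
    given_alt = np.stack([zeros, q, p], axis=1)
    given_ref = np.stack([q, p, zeros], axis=1)
    a_frac = np.array([0.0, 0.5, 1.0])  # P(shared allele is alt | g_i)
    T = (a_frac[None, :, None] * given_alt[:, None, :]
         + (1 - a_frac)[None, :, None] * given_ref[:, None, :])
    return pg[:, :, None] * T


def relationship_tables(freqs: np.ndarray, eps: float
                        ) -> dict[str, np.ndarray]:
    """Observed genotype-pair probability tables per relationship.

    Returns {R: (L, 4, 4)} log tables; index 3 encodes a missing call and
    contributes log 1 = 0 so missing-aware indexing needs no masking.
    """
    pg = genotype_priors(freqs)
    t0 = pg[:, :, None] * pg[:, None, :]
    t1 = _shared_one_tables(pg, freqs)
    t2 = np.zeros_like(t0)
    idx = np.arange(3)
    t2[:, idx, idx] = pg

    E = _error_matrix(pg, eps)
    out = {}
    for R, (k0, k1, k2) in K_COEFFS.items():
        T = k0 * t0 + k1 * t1 + k2 * t2
        # observation error on both members: E^T T E per locus
        Tobs = np.einsum("lio,lij,ljp->lop", E, T, E)
        padded = np.zeros((len(freqs), 4, 4))
        padded[:, :3, :3] = np.log(np.maximum(Tobs, TINY))
        out[R] = padded
    return out


def _genotype_codes(G: np.ndarray) -> np.ndarray:
    g = G.astype(np.int64).copy()
    g[g == MISSING] = 3
    return g


def pairwise_llr(table: GenotypeTable, freqs: np.ndarray | None = None,
                 eps: float = 0.001, min_loci: int = 50) -> RelLikelihoods:
    """Log-likelihoods of FS / HS / U for every pair of individuals.

    Allele frequencies default to estimates from the offspring sample;
    monomorphic loci are excluded (they carry no pairwise information).
    Pairs overlapping at fewer than ``min_loci`` informative loci are
    flagged unclassifiable.
    """
    if freqs is None:
        freqs = table.allele_freqs()
    poly = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    table = table.subset(loci=poly)
    freqs = freqs[poly]

    g = _genotype_codes(table.genotypes)       # (n, L)
    n, L = g.shape
    tables = relationship_tables(freqs, eps)

    called = g < 3
    n_used = called.astype(np.int32) @ called.astype(np.int32).T

    ll = {R: np.zeros((n, n)) for R in K_COEFFS}
    for l in range(L):
        gl = g[:, l]
        for R, T in tables.items():
            ll[R] += T[l][gl[:, None], gl[None, :]]
    return RelLikelihoods(individuals=table.individuals, ll=ll,
                         n_loci_used=n_used, min_loci=min_loci)


# ---------------------------------------------------------------------------
# family joint likelihood machinery

def mendel_tables(freqs: np.ndarray, eps: float) -> np.ndarray:
    """log P(observed offspring genotype | ordered parent genotypes).

    Shape (L, 3, 3, 4): [locus, parent1, parent2, offspring]; offspring
    index 3 = missing contributes 0.
    """
    L = len(freqs)
    a = np.array([0.0, 0.5, 1.0])          # P(transmit alt | parent genotype)
    p1 = a[:, None, None]
    p2 = a[None, :, None]
    go = np.zeros((3, 3, 3))
    go[:, :, 0] = ((1 - p1) * (1 - p2))[:, :, 0]
    go[:, :, 2] = (p1 * p2)[:, :, 0]
    go[:, :, 1] = 1.0 - go[:, :, 0] - go[:, :, 2]
    M = np.broadcast_to(go, (L, 3, 3, 3)).copy()
    E = _error_matrix(genotype_priors(freqs), eps)   # (L, true, obs)
    Mobs = np.einsum("labt,lto->labo", M, E)
    out = np.zeros((L, 3, 3, 4))
    out[:, :, :, :3] = np.log(np.maximum(Mobs, TINY))
    return out


@dataclass
class FamilyLikelihoodModel:
    """Shared per-locus arrays for family-level likelihood evaluations."""

    log_pg: np.ndarray      # (L, 3) log HWE genotype priors
    log_mendel: np.ndarray  # (L, 3, 3, 4)
    codes: np.ndarray       # (n, L) genotype codes, 3 = missing
    individuals: np.ndarray
    index: dict[str, int]

    @classmethod
    def build(cls, table: GenotypeTable, freqs: np.ndarray | None = None,
              eps: float = 0.001) -> "FamilyLikelihoodModel":
        if freqs is None:
            freqs = table.allele_freqs()
        poly = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
        table = table.subset(loci=poly)
        freqs = freqs[poly]
        return cls(log_pg=np.log(np.maximum(genotype_priors(freqs), TINY)),
                   log_mendel=mendel_tables(freqs, eps),
                   codes=_genotype_codes(table.genotypes),
                   individuals=table.individuals,
                   index={s: i for i, s in enumerate(table.individuals)})

    @property
    def n_loci(self) -> int:
        return self.log_pg.shape[0]

    def subset_loci(self, loci_idx: np.ndarray) -> "FamilyLikelihoodModel":
        return FamilyLikelihoodModel(
            log_pg=self.log_pg[loci_idx],
            log_mendel=self.log_mendel[loci_idx],
            codes=self.codes[:, loci_idx],
            individuals=self.individuals, index=self.index)

    def offspring_terms(self, members: list[str]) -> np.ndarray:
        """Sum over members of log P(obs | parents); shape (L, 3, 3)."""
        L = self.n_loci
        A = np.zeros((L, 3, 3))
        rows = np.arange(L)
        for m in members:
            gm = self.codes[self.index[m]]
            A += self.log_mendel[rows, :, :, gm]
        return A

    def family_loglik(self, members: list[str],
                      terms: np.ndarray | None = None) -> float:
        """Marginal log-likelihood of a putative full-sib family: per locus,
        the parental genotype pair is integrated over its HWE prior."""
        A = self.offspring_terms(members) if terms is None else terms
        J = A + self.log_pg[:, :, None] + self.log_pg[:, None, :]
        return float(logsumexp(J.reshape(len(J), 9), axis=1).sum())

    def parent_pair_posterior(self, members: list[str]) -> np.ndarray:
        """Per-locus posterior over ordered parental genotype pairs (L,3,3)."""
        A = self.offspring_terms(members)
        J = A + self.log_pg[:, :, None] + self.log_pg[:, None, :]
        J -= logsumexp(J.reshape(len(J), 9), axis=1)[:, None, None]
        return np.exp(J)

    def shared_parent_terms(self, members: list[str]) -> np.ndarray:
        """(L, 3) log P(members | one parent genotype), other parent
        integrated over HWE."""
        A = self.offspring_terms(members)
        return logsumexp(A + self.log_pg[:, None, :], axis=2)

    def group_share_loglik(self, term_list: list[np.ndarray]) -> float:
        """Log-likelihood of several families sharing one common parent."""
        S = self.log_pg.copy()
        for t in term_list:
            S = S + t
        return float(logsumexp(S, axis=1).sum())


def _loglik_from_terms(model: FamilyLikelihoodModel, A: np.ndarray) -> float:
    J = A + model.log_pg[:, :, None] + model.log_pg[:, None, :]
    return float(logsumexp(J.reshape(len(J), 9), axis=1).sum())


def _share_score(model: FamilyLikelihoodModel, A_f: np.ndarray,
                 A_o: np.ndarray) -> float:
    """Log-likelihood of two offspring sets sharing exactly one parent."""
    B_f = logsumexp(A_f + model.log_pg[:, None, :], axis=2)
    B_o = logsumexp(A_o + model.log_pg[:, None, :], axis=2)
    return float(logsumexp(model.log_pg + B_f + B_o, axis=1).sum())


def partition_fullsib(rel: RelLikelihoods, model: FamilyLikelihoodModel,
                      threshold: float = 0.0, max_passes: int = 3
                      ) -> list[list[str]]:
    """Partition offspring into full-sib families.

    Families are assembled bottom-up from singletons by greedy
    single-offspring moves.  A move must increase the summed family
    marginal likelihood AND the full-sib join must beat the alternative
    explanation that the offspring is merely a half-sib of the destination
    family (guards against absorbing half-sibs).  Pairs whose FS vs
    max(HS, U) log-ratio is below ``threshold`` (or that are
    unclassifiable) are never considered join candidates, so starting from
    an erroneous transitive merge is impossible by construction.
    """
    ids = list(rel.individuals)
    n = len(ids)
    score = rel.ll["FS"] - np.maximum(rel.ll["HS"], rel.ll["U"])
    ok = rel.classifiable()
    edge = ok & (score > threshold)
    np.fill_diagonal(edge, False)
    candidates = {ids[i]: {ids[j] for j in np.flatnonzero(edge[i])}
                  for i in range(n)}
    families = [[i] for i in ids]

    rows = np.arange(model.n_loci)

    def member_term(m):
        gm = model.codes[model.index[m]]
        return model.log_mendel[rows, :, :, gm]

    terms = {m: member_term(m) for m in ids}
    fam_terms = [sum(terms[m] for m in f) for f in families]
    fam_ll = [_loglik_from_terms(model, A) for A in fam_terms]
    single_ll = {m: _loglik_from_terms(model, terms[m]) for m in ids}

    for _ in range(max_passes):
        improved = False
        for off in ids:
            src = next(k for k, f in enumerate(families) if off in f)
            if len(families[src]) == 1:
                src_wo_terms = np.zeros_like(terms[off])
                src_wo_ll = 0.0
            else:
                src_wo_terms = fam_terms[src] - terms[off]
                src_wo_ll = _loglik_from_terms(model, src_wo_terms)
            base_gain = src_wo_ll - fam_ll[src]
            best = None  # (gain, dst, dst_terms, dst_ll)
            for k, f in enumerate(families):
                if k == src or not f:
                    continue
                if not candidates[off].intersection(f):
                    continue
                with_terms = fam_terms[k] + terms[off]
                with_ll = _loglik_from_terms(model, with_terms)
                gain = base_gain + with_ll - fam_ll[k]
                if gain <= (0.0 if best is None else best[0]) + 1e-9:
                    continue
                # FS join must beat the half-sib attachment alternative
                fs_delta = with_ll - fam_ll[k] - single_ll[off]
                hs_delta = (_share_score(model, fam_terms[k], terms[off])
                            - fam_ll[k] - single_ll[off])
                if fs_delta <= hs_delta:
                    continue
                best = (gain, k, with_terms, with_ll)
            # moving out to a fresh singleton
            if len(families[src]) > 1:
                gain = base_gain + single_ll[off]
                if gain > (0.0 if best is None else best[0]) + 1e-9:
                    best = (gain, -1, terms[off], single_ll[off])
            if best is not None:
                _, dst, dst_terms, dst_ll = best
                families[src] = [m for m in families[src] if m != off]
                fam_terms[src] = src_wo_terms
                fam_ll[src] = src_wo_ll
                if dst == -1:
                    families.append([off])
                    fam_terms.append(dst_terms)
                    fam_ll.append(dst_ll)
                else:
                    families[dst] = sorted(families[dst] + [off])
                    fam_terms[dst] = dst_terms
                    fam_ll[dst] = dst_ll
                improved = True
        keep = [(f, A, ll) for f, A, ll in zip(families, fam_terms, fam_ll)
                if f]
        families = [f for f, _, _ in keep]
        fam_terms = [A for _, A, _ in keep]
        fam_ll = [ll for _, _, ll in keep]
        if not improved:
            break
    families = [sorted(f) for f in families if f]
    return sorted(families, key=lambda f: f[0])


def reconstruct_parents(model: FamilyLikelihoodModel, members: list[str]
                        ) -> dict:
    """Posterior over unordered parental genotype pairs per locus.

    Returns the full ordered (L, 3, 3) posterior plus per-locus argmax
    unordered pair, its posterior mass, and an ``uninformative`` mask for
    loci where every member is missing.
    """
    post = model.parent_pair_posterior(members)
    L = post.shape[0]
    sym = post + np.transpose(post, (0, 2, 1))
    pairs = [(a, b) for a in range(3) for b in range(a, 3)]
    mass = np.empty((L, len(pairs)))
    for k, (a, b) in enumerate(pairs):
        mass[:, k] = post[:, a, b] + post[:, b, a] if a != b else post[:, a, a]
    best = mass.argmax(axis=1)
    codes = np.array([model.codes[model.index[m]] for m in members])
    uninformative = (codes == 3).all(axis=0)
    return {
        "posterior": post,
        "pairs": pairs,
        "argmax_pair": [pairs[k] for k in best],
        "argmax_mass": mass[np.arange(L), best],
        "uninformative": uninformative,
    }


def link_halfsibs(families: list[list[str]], model: FamilyLikelihoodModel,
                  threshold: float = 10.0) -> Pedigree:
    """Link full-sib families through shared parents into a pedigree.

    Each family exposes two unordered parent slots.  Slot groups are merged
    agglomeratively: at each step the feasible pair of groups with the
    highest shared-parent log-likelihood-ratio gain is merged, while the
    gain exceeds ``threshold``.  Feasibility forbids a family contributing
    two slots to the same shared parent.  Each final slot group becomes one
    inferred parent.
    """
    F = len(families)
    terms = [model.shared_parent_terms(f) for f in families]

    # slot groups: each starts as one (family, slot); merging two groups
    # asserts that all their families share one parent.  Agglomerative
    # best-first merging: keep taking the highest-gain feasible merge while
    # it exceeds the threshold.  A slot's evidence term is the family's
    # shared-parent profile (the other parent integrated out).
    groups: dict[int, list[tuple[int, int]]] = {}
    gsum: dict[int, np.ndarray] = {}
    for f in range(F):
        for s in (0, 1):
            gid = 2 * f + s
            groups[gid] = [(f, s)]
            gsum[gid] = terms[f]

    def ll_of(S: np.ndarray) -> float:
        return float(logsumexp(model.log_pg + S, axis=1).sum())

    gll = {gid: ll_of(S) for gid, S in gsum.items()}
    gfam = {gid: {f for f, _ in mem} for gid, mem in groups.items()}
    # family pairs already sharing a parent; a second shared parent would
    # make them full sibs, which is the partitioner's decision, not ours
    shared_pairs: set[frozenset] = set()

    def gain(a: int, b: int) -> float:
        if gfam[a] & gfam[b]:
            return -np.inf
        for f in gfam[a]:
            for g in gfam[b]:
                if frozenset((f, g)) in shared_pairs:
                    return -np.inf
        return ll_of(gsum[a] + gsum[b]) - gll[a] - gll[b]

    def feasible(a: int, b: int) -> bool:
        if gfam[a] & gfam[b]:
            return False
        return not any(frozenset((f, g)) in shared_pairs
                       for f in gfam[a] for g in gfam[b])

    cache: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        cache[(a, b)] = gain(a, b)
    while cache:
        (a, b), best = max(cache.items(), key=lambda kv: kv[1])
        if best <= threshold:
            break
        if not feasible(a, b):
            del cache[(a, b)]
            continue
        for f in gfam[a]:
            for g in gfam[b]:
                shared_pairs.add(frozenset((f, g)))
        groups[a] = groups[a] + groups.pop(b)
        gsum[a] = gsum[a] + gsum[b]
        gll[a] = ll_of(gsum[a])
        gfam[a] = gfam[a] | gfam.pop(b)
        del gsum[b], gll[b]
        cache = {k: v for k, v in cache.items() if b not in k}
        for k in list(cache):
            if a in k:
                del cache[k]
        for other in groups:
            if other != a:
                cache[(min(a, other), max(a, other))] = gain(a, other)

    # emit parent ids per slot group
    slot_root = {}
    for gid, mem in groups.items():
        for fs in mem:
            slot_root[fs] = gid
    roots = sorted(groups)
    parent_id = {r: f"FP{k:04d}" for k, r in enumerate(roots)}
    parents: dict[str, tuple[str, str]] = {}
    for f, fam in enumerate(families):
        p1 = parent_id[slot_root[(f, 0)]]
        p2 = parent_id[slot_root[(f, 1)]]
        for off in fam:
            parents[off] = (p1, p2)

    posteriors = {}
    for r in roots:
        S = model.log_pg + gsum[r]
        S = S - logsumexp(S, axis=1)[:, None]
        posteriors[parent_id[r]] = np.exp(S)

    offspring = np.array(sorted(parents), dtype=object)
    return Pedigree(offspring=offspring, parents=parents,
                    families=[sorted(f) for f in families],
                    parent_posteriors=posteriors)


def family_clusters(pedigree: Pedigree) -> list[list[str]]:
    """Connected components of the offspring-parent graph (offspring only)."""
    g = pedigree.offspring_parent_graph()
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(m for m in comp if m in pedigree.parents)
        clusters.append(members)
    return sorted(clusters, key=lambda c: c[0])


def cluster_support(pedigree: Pedigree, table: GenotypeTable,
                    freqs: np.ndarray | None = None, eps: float = 0.001,
                    fs_threshold: float = 0.0, hs_threshold: float = 5.0,
                    min_loci: int = 50, B: int = 100, seed: int = 0
                    ) -> tuple[list[list[str]], list[float]]:
    """Locus-bootstrap support per family cluster.

    For each cluster, loci are resampled with replacement B times and the
    partition+link pipeline is rerun on the cluster's members; support is
    the fraction of replicates in which the members stay one connected
    component.  Singleton-offspring clusters have support 1 by definition.
    """
    if B < 1:
        raise ValueError("bootstrap B must be >= 1")
    if freqs is None:
        freqs = table.allele_freqs()
    rng = np.random.default_rng(seed)
    clusters = family_clusters(pedigree)
    idx = {s: i for i, s in enumerate(table.individuals)}
    supports = []
    for members in clusters:
        if len(members) == 1:
            supports.append(1.0)
            continue
        rows = np.array([idx[m] for m in members])
        sub = table.subset(individuals=rows)
        intact = 0
        for _ in range(B):
            loci_idx = rng.integers(0, sub.n_loci, size=sub.n_loci)
            boot = sub.subset(loci=loci_idx)
            bfreqs = freqs[loci_idx]
            rel = pairwise_llr(boot, freqs=bfreqs, eps=eps, min_loci=min_loci)
            model = FamilyLikelihoodModel.build(boot, freqs=bfreqs, eps=eps)
            fams = partition_fullsib(rel, model, threshold=fs_threshold,
                                     max_passes=1)
            ped = link_halfsibs(fams, model, threshold=hs_threshold)
            g = ped.offspring_parent_graph()
            n_comp = sum(1 for c in nx.connected_components(g)
                         if any(m in pedigree.parents for m in c))
            intact += int(nx.number_connected_components(g) == 1)
        supports.append(intact / B)
    return clusters, supports


def reconstruct_pedigree(table: GenotypeTable, eps: float = 0.001,
                         fs_threshold: float = 0.0, hs_threshold: float = 5.0,
                         min_loci: int = 50, max_passes: int = 3,
                         compute_support: bool = False, bootstrap_B: int = 100,
                         seed: int = 0,
                         freqs: np.ndarray | None = None) -> Pedigree:
    """Full sibship pipeline: pairwise screen, FS partition, HS linking,
    clusters (optionally with bootstrap support).

    Allele frequencies default to sample estimates; supply ``freqs`` when
    known externally (sample estimates are badly biased when the sample is
    a handful of families).
    """
    if freqs is None:
        freqs = table.allele_freqs()
    rel = pairwise_llr(table, freqs=freqs, eps=eps, min_loci=min_loci)
    model = FamilyLikelihoodModel.build(table, freqs=freqs, eps=eps)
    fams = partition_fullsib(rel, model, threshold=fs_threshold,
                             max_passes=max_passes)
    ped = link_halfsibs(fams, model, threshold=hs_threshold)
    if compute_support:
        clusters, supports = cluster_support(
            ped, table, freqs=freqs, eps=eps, fs_threshold=fs_threshold,
            hs_threshold=hs_threshold, min_loci=min_loci, B=bootstrap_B,
            seed=seed)
    else:
        clusters, supports = family_clusters(ped), []
    ped.clusters = clusters
    ped.cluster_support = supports
    return ped
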