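"""Core genotype-matrix container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1


@dataclass
class GenotypeTable:
    """Individuals x biallelic loci, genotypes coded as alt-allele counts.

    ``genotypes[i, l]`` is 0/1/2 (count of the alternate allele) or
    ``MISSING`` (-1).  ``depths`` holds per-genotype total read depth and
    ``alt_depths`` the reads supporting the alternate allele (used for the
    heterozygote read-ratio screen).  Positions are 1-based.
    """

    individuals: np.ndarray          # (n,) str ids
    loci: np.ndarray                 # (L,) str ids
    chrom: np.ndarray                # (L,) str
    pos: np.ndarray                  # (L,) int64, 1-based
    genotypes: np.ndarray            # (n, L) int8
    depths: np.ndarray | None = None      # (n, L) int32
    alt_depths: np.ndarray | None = None  # (n, L) int32
    on_target: np.ndarray | None = None   # (L,) bool
    target_region: np.ndarray | None = None  # (L,) int, -1 = off target

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.loci = np.asarray(self.loci, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, L = self.genotypes.shape
        if len(self.individuals) != n or len(self.loci) != L:
            raise ValueError("genotype matrix shape does not match id vectors")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L); True where the call is missing."""
        return self.genotypes == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of individuals with a non-missing call."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def individual_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def allele_freqs(self) -> np.ndarray:
        """Per-locus alternate allele frequency over called genotypes.

        Loci with no calls get frequency nan.
        """
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with np.errstate(invalid="ignore"):
            freqs = g.mean(axis=0).filled(np.nan) / 2.0
        return freqs

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def het_fraction(self) -> np.ndarray:
        """Observed heterozygosity: het calls / non-missing calls per locus."""
        called = ~self.missing_mask
        het = self.genotypes == 1
        with np.errstate(invalid="ignore"):
            return np.where(called.sum(0) > 0,
                            het.sum(0) / np.maximum(called.sum(0), 1),
                            np.nan)

    def subset(self, individuals: np.ndarray | None = None,
               loci: np.ndarray | None = None) -> "GenotypeTable":
        """Return a new table restricted to index arrays (bool or int)."""
        ii = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        ll = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if ii.dtype == bool:
            ii = np.flatnonzero(ii)
        if ll.dtype == bool:
            ll = np.flatnonzero(ll)

        def take2(a):
            return None if a is None else a[np.ix_(ii, ll)]

        def take1(a):
            return None if a is None else a[ll]

        return GenotypeTable(
            individuals=self.individuals[ii],
            loci=self.loci[ll],
            chrom=take1(self.chrom),
            pos=take1(self.pos),
            genotypes=self.genotypes[np.ix_(ii, ll)],
            depths=take2(self.depths),
            alt_depths=take2(self.alt_depths),
            on_target=take1(self.on_target),
            target_region=take1(self.target_region),
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            individuals=self.individuals.copy(),
            loci=self.loci.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            genotypes=self.genotypes.copy(),
            depths=None if self.depths is None else self.depths.copy(),
            alt_depths=None if self.alt_depths is None else self.alt_depths.copy(),
            on_target=None if self.on_target is None else self.on_target.copy(),
            target_region=None if self.target_region is None else self.target_region.copy(),
        )
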