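"""Genotype-matrix QC filters and SNP-panel selection.

Covers the paralog screen on heterozygosity and pooled heterozygote
read-ratio deviation, depth / call-rate / individual-missingness filters,
a per-locus Hardy-Weinberg exact test (reported, not auto-excluding), and
the two panel-selection rules (1-Mb-thinned pedigree panel; per-target-region
LD panel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtable import MISSING, GenotypeTable


@dataclass
class QCThresholds:
    h_max: float = 0.6                  # exclude locus if H > h_max
    d_max: float = 7.0                  # exclude locus if |D| > d_max
    individual_missing_max: float = 0.80  # exclude individual if missing > this
    min_depth: int = 8                  # genotypes with depth < this set missing
    hwe_alpha: float = 0.05             # reporting only


class QCError(ValueError):
    pass


def hwe_exact_p(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value for a biallelic locus.

    Sums probabilities of heterozygote counts no more likely than observed,
    conditioning on the allele counts (the standard exact SNP-HWE test).
    """
    n = n_het + n_hom_a + n_hom_b
    if n == 0:
        return float("nan")
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het
    # probabilities over all het counts with the same parity as n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln
    n_a = n_rare
    n_b = 2 * n - n_rare
    for i, h in enumerate(hets):
        ra = (n_a - h) // 2
        rb = (n_b - h) // 2
        logp[i] = (gammaln(n + 1) - gammaln(h + 1) - gammaln(ra + 1)
                   - gammaln(rb + 1) + h * np.log(2)
                   + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= obs + 1e-12].sum()))


def compute_locus_stats(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus H, read-ratio deviation D, MAF, call rate and HWE p-value.

    D pools reads across heterozygous calls at the locus: with x reads
    supporting the reference allele out of N total heterozygote reads,
    D = (x - N/2) / sqrt(N/4).  Loci with no heterozygous calls (or no
    heterozygote reads) get D = NaN and never trigger the |D| filter.
    """
    het = table.genotypes == 1
    if table.depths is not None and table.alt_depths is not None:
        dp = np.where(het, table.depths, 0)
        alt = np.where(het, table.alt_depths, 0)
        N = dp.sum(axis=0).astype(float)
        x = (dp - alt).sum(axis=0).astype(float)  # reads supporting REF
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(N > 0, (x - N / 2.0) / np.sqrt(N / 4.0), np.nan)
    else:
        D = np.full(table.n_loci, np.nan)

    hwe = np.empty(table.n_loci)
    for l in range(table.n_loci):
        g = table.genotypes[:, l]
        hwe[l] = hwe_exact_p(int((g == 1).sum()), int((g == 0).sum()),
                             int((g == 2).sum()))

    return pd.DataFrame({
        "locus": table.loci,
        "chrom": table.chrom,
        "pos": table.pos,
        "H": table.het_fraction(),
        "D": D,
        "maf": table.maf(),
        "call_rate": table.call_rate(),
        "on_target": (table.on_target if table.on_target is not None
                      else np.ones(table.n_loci, dtype=bool)),
        "target_region": (table.target_region if table.target_region is not None
                          else np.arange(table.n_loci)),
        "hwe_p": hwe,
    })


def apply_qc_filters(table: GenotypeTable,
                     stats: pd.DataFrame | None = None,
                     thresholds: QCThresholds | None = None
                     ) -> tuple[GenotypeTable, pd.DataFrame]:
    """Run the fixed-order QC: depth mask, locus H/|D| screen, individual
    missingness.  Returns the filtered table and an exclusion report with
    columns ``unit, type, reason, value, threshold``.
    """
    th = thresholds or QCThresholds()
    report_rows = []
    work = table.copy()

    # 1. depth rule: strictly-below-min-depth genotypes become missing
    if work.depths is not None and th.min_depth > 0:
        low = (work.depths < th.min_depth) & (work.genotypes != MISSING)
        work.genotypes = np.where(low, MISSING, work.genotypes).astype(np.int8)
        report_rows.append(("genotypes", "genotype", "depth_below_min",
                            int(low.sum()), th.min_depth))

    # 2. locus screen on the depth-masked matrix
    if stats is None:
        stats = compute_locus_stats(work)
    drop_h = stats["H"].to_numpy() > th.h_max
    d = stats["D"].to_numpy()
    drop_d = np.where(np.isnan(d), False, np.abs(d) > th.d_max)
    for l in np.flatnonzero(drop_h):
        report_rows.append((stats["locus"].iloc[l], "locus", "H_above_max",
                            float(stats["H"].iloc[l]), th.h_max))
    for l in np.flatnonzero(drop_d & ~drop_h):
        report_rows.append((stats["locus"].iloc[l], "locus", "absD_above_max",
                            float(stats["D"].iloc[l]), th.d_max))
    work = work.subset(loci=~(drop_h | drop_d))

    # 3. individual missingness (strict >)
    frac = work.individual_missing_fraction()
    drop_ind = frac > th.individual_missing_max
    for i in np.flatnonzero(drop_ind):
        report_rows.append((work.individuals[i], "individual",
                            "missing_fraction_above_max", float(frac[i]),
                            th.individual_missing_max))
    work = work.subset(individuals=~drop_ind)

    if work.n_loci == 0 or work.n_individuals == 0:
        raise QCError("no data survives QC")

    report = pd.DataFrame(report_rows,
                          columns=["unit", "type", "reason", "value",
                                   "threshold"])
    return work, report


def select_snp_panels(stats: pd.DataFrame, purpose: str, seed: int = 0,
                      maf_min: float = 0.05, call_rate_min: float = 0.80,
                      min_separation: int = 1_000_000) -> list:
    """Pick a SNP panel for pedigree or LD estimation.

    pedigree: among loci with MAF >= maf_min and call rate >= call_rate_min,
    a greedy per-chromosome scan keeps, per 1-Mb window, the locus with the
    lexicographically highest (MAF, call rate); successive picks are >= 1 Mb
    apart; exact ties are broken uniformly at random with ``seed``.

    ld: within each on-target region, keep the locus with the highest call
    rate (ties random); loci with MAF < maf_min are dropped.
    """
    rng = np.random.default_rng(seed)
    if purpose == "pedigree":
        elig = stats[(stats["maf"] >= maf_min)
                     & (stats["call_rate"] >= call_rate_min)]
        picked: list = []
        for _, sub in elig.groupby("chrom", sort=True):
            sub = sub.sort_values("pos", kind="mergesort")
            pos = sub["pos"].to_numpy()
            cursor = None
            i = 0
            while i < len(sub):
                start = pos[i] if cursor is None else max(pos[i], cursor)
                in_win = (pos >= start) & (pos < start + min_separation)
                if not in_win.any():
                    i += 1
                    continue
                cand = sub[in_win]
                key = list(zip(cand["maf"], cand["call_rate"]))
                best = max(key)
                ties = [j for j, k in enumerate(key) if k == best]
                choice = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
                row = cand.iloc[choice]
                picked.append(row["locus"])
                cursor = int(row["pos"]) + min_separation
                i = int(np.searchsorted(pos, cursor))
        return picked
    elif purpose == "ld":
        elig = stats[(stats["maf"] >= maf_min) & stats["on_target"]
                     & (stats["target_region"] >= 0)]
        picked = []
        for _, sub in elig.groupby("target_region", sort=True):
            best = sub["call_rate"].max()
            ties = sub[sub["call_rate"] == best]
            row = ties.iloc[rng.integers(len(ties))] if len(ties) > 1 else ties.iloc[0]
            picked.append(row["locus"])
        return picked
    raise ValueError(f"unknown panel purpose {purpose!r}")
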