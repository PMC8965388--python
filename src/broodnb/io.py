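"""Standard-format I/O: VCF genotype matrices and individual metadata tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .gtable import MISSING, GenotypeTable

log = logging.getLogger(__name__)


class VCFParseError(ValueError):
    pass


def read_genotypes_vcf(path: str) -> GenotypeTable:
    """Load diploid biallelic GT calls (with DP/AD when present) from a VCF.

    Multiallelic records are skipped with a logged count.  Positions are kept
    1-based.  Loci flagged ``ONTARGET`` in INFO (with optional ``REGION``)
    populate the on-target metadata.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    individuals = np.array(vcf.samples, dtype=object)
    n = len(individuals)

    loci, chroms, poss = [], [], []
    gts, dps, alts, targets, regions = [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        dps.append(np.zeros(n, dtype=np.int32) if dp is None
                   else np.maximum(dp[:, 0], 0).astype(np.int32))
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        alts.append(np.zeros(n, dtype=np.int32) if ad is None
                    else np.maximum(ad[:, 1], 0).astype(np.int32))
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(vid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        targets.append(bool(var.INFO.get("ONTARGET", 0)))
        regions.append(int(var.INFO.get("REGION", -1)))
    if n_multi:
        log.info("skipped %d multiallelic records in %s", n_multi, path)
    if not loci:
        raise VCFParseError(f"no usable biallelic records in {path}")

    return GenotypeTable(
        individuals=individuals,
        loci=np.array(loci, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        genotypes=np.array(gts, dtype=np.int8).T,
        depths=np.array(dps, dtype=np.int32).T,
        alt_depths=np.array(alts, dtype=np.int32).T,
        on_target=np.array(targets, dtype=bool),
        target_region=np.array(regions, dtype=np.int64),
    )


def write_genotypes_vcf(table: GenotypeTable, path: str) -> None:
    """Write an uncompressed VCF v4.2 with GT:DP:AD fields."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(table.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=ONTARGET,Number=0,Type=Flag,'
                 'Description="Locus in a capture-targeted region">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=Integer,'
                 'Description="Target region index">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in table.individuals) + "\n")
        dp = table.depths if table.depths is not None else np.zeros_like(
            table.genotypes, dtype=np.int32)
        ad = table.alt_depths if table.alt_depths is not None else np.zeros_like(
            table.genotypes, dtype=np.int32)
        for l in range(table.n_loci):
            info_parts = []
            if table.on_target is not None and table.on_target[l]:
                info_parts.append("ONTARGET")
            if table.target_region is not None and table.target_region[l] >= 0:
                info_parts.append(f"REGION={table.target_region[l]}")
            info = ";".join(info_parts) or "."
            cells = []
            for i in range(table.n_individuals):
                d = int(dp[i, l])
                a = int(ad[i, l])
                cells.append(f"{gt_str[int(table.genotypes[i, l])]}:{d}:{d - a},{a}")
            fh.write(f"{table.chrom[l]}\t{table.pos[l]}\t{table.loci[l]}\t"
                     f"A\tC\t.\tPASS\t{info}\tGT:DP:AD\t" + "\t".join(cells) + "\n")


def read_individual_table(path: str,
                          vcf_individuals: np.ndarray | None = None
                          ) -> pd.DataFrame:
    """Read the ``id,stream,collection_year,length_mm`` CSV.

    Enforces unique ids and positive lengths; when the VCF sample list is
    supplied, individuals absent from it are flagged in an ``in_vcf`` column
    and a warning is logged.
    """
    df = pd.read_csv(path)
    required = {"id", "stream", "collection_year", "length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"individual table missing columns: {sorted(missing)}")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate individual id(s): {sorted(set(dup))[:5]}")
    if (df["length_mm"] <= 0).any():
        bad = df.loc[df["length_mm"] <= 0, "id"].tolist()[:5]
        raise ValueError(f"non-positive length for individual(s): {bad}")
    if vcf_individuals is not None:
        present = set(vcf_individuals.tolist())
        df["in_vcf"] = df["id"].isin(present)
        n_absent = int((~df["in_vcf"]).sum())
        if n_absent:
            log.warning("%d individuals in metadata absent from VCF", n_absent)
    return df
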