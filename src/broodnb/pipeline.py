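"""Pipeline driver: QC -> sibship (per stream) -> mixture (per stream x
collection) -> reconciliation -> per-cohort estimators, with a reproducible
run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .effsize import (nb_ld, nb_sibship, parent_accumulation, repro_summary,
                      richness_estimates)
from .io import read_genotypes_vcf, read_individual_table
from .mixture import (MixtureFit, posterior_k_bdmcmc, posterior_k_overfitted,
                      select_k_and_assign)
from .qc import apply_qc_filters, compute_locus_stats, select_snp_panels
from .reconcile import (ConstraintEvent, assign_spawn_years,
                        link_across_collections, reconcile_cohorts)
from .sibship import reconstruct_pedigree

log = logging.getLogger(__name__)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle to
    ``config.out_dir``.  Deterministic under a fixed global seed."""
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = config.module_seeds()
    results: dict = {"version": __version__, "streams": {}}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("io")
        table = read_genotypes_vcf(config.vcf)
        meta = read_individual_table(config.individuals, table.individuals)
    except Exception as e:           # noqa: BLE001
        raise StageError("io", e) from e

    try:
        stage("qc")
        stats = None
        table, qc_report = apply_qc_filters(table, thresholds=config.qc)
        stats = compute_locus_stats(table)
        qc_report.to_csv(os.path.join(config.out_dir, "qc_exclusions.tsv"),
                         sep="\t", index=False)
    except Exception as e:
        raise StageError("qc", e) from e

    meta = meta[meta["id"].isin(set(table.individuals.tolist()))]
    idx = {s: i for i, s in enumerate(table.individuals)}

    table2_rows = []
    table1_rows = []
    for stream, smeta in meta.groupby("stream"):
        sres: dict = {}
        rows = np.array([idx[i] for i in smeta["id"]])
        stable = table.subset(individuals=rows)

        try:
            stage(f"sibship[{stream}]")
            panel = select_snp_panels(stats, "pedigree", seed=seeds["panel"])
            keep = np.isin(stable.loci, np.asarray(panel, dtype=object))
            ped_table = stable.subset(loci=keep) if keep.any() else stable
            sp = config.sibship
            pedigree = reconstruct_pedigree(
                ped_table, eps=sp.error_rate, fs_threshold=sp.fs_threshold,
                hs_threshold=sp.hs_threshold, min_loci=sp.min_loci,
                max_passes=sp.max_passes,
                compute_support=sp.compute_support,
                bootstrap_B=sp.bootstrap_B, seed=seeds["sibship"])
        except Exception as e:
            raise StageError(f"sibship[{stream}]", e) from e

        cluster_of = {}
        for k, cl in enumerate(pedigree.clusters):
            for m in cl:
                cluster_of[m] = k
        fam_of = {}
        for k, fam in enumerate(pedigree.families):
            for m in fam:
                fam_of[m] = k

        # mixture per collection
        assign_frames = []
        for cyear, cmeta in smeta.groupby("collection_year"):
            lengths = cmeta["length_mm"].to_numpy()
            n = len(lengths)
            if n < config.mixture.min_n:
                log.info("stream %s collection %s: n=%d < %d, skipping "
                         "mixture models (single-cohort path)",
                         stream, cyear, n, config.mixture.min_n)
                labels = np.zeros(n, dtype=int)
                kstar = 1
            else:
                try:
                    stage(f"mixture[{stream},{cyear}]")
                    mc = config.mixture.mcmc
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        kp1 = posterior_k_overfitted(
                            lengths, K_max=config.mixture.k_max,
                            cutoff=config.mixture.cutoff, mcmc=mc,
                            seed=seeds["mixture"])
                        kp2 = posterior_k_bdmcmc(
                            lengths, K_max=config.mixture.k_max,
                            birth_rate=config.mixture.birth_rate, mcmc=mc,
                            seed=seeds["mixture"] + 1)
                        fit, labels, kstar = select_k_and_assign(
                            lengths, kp1, kp2, mcmc=mc,
                            seed=seeds["mixture"] + 2)
                    for k in range(config.mixture.k_max):
                        table1_rows.append({
                            "stream": stream, "collection_year": int(cyear),
                            "K": k + 1,
                            "overfitted": float(kp1.probs[k]),
                            "bd_mcmc": float(kp2.probs[k])})
                except Exception as e:
                    raise StageError(f"mixture[{stream},{cyear}]", e) from e
            df = cmeta[["id", "length_mm"]].copy()
            df["stream"] = stream
            df["collection_year"] = int(cyear)
            df["mixture_label"] = [f"{cyear}:{l}" for l in labels]
            assign_frames.append(df)

        try:
            stage(f"reconcile[{stream}]")
            assignments = pd.concat(assign_frames, ignore_index=True)
            group_col = ("cluster_id"
                         if config.reconcile.relatedness == "cluster"
                         else "family_id")
            assignments["cluster_id"] = [
                cluster_of.get(i, f"solo_{i}") for i in assignments["id"]]
            assignments["family_id"] = [
                fam_of.get(i, f"solo_{i}") for i in assignments["id"]]
            per_coll = []
            for cyear, sub in assignments.groupby("collection_year"):
                per_coll.append(reconcile_cohorts(sub, group_col=group_col))
            assignments = pd.concat(per_coll, ignore_index=True)
            assignments = link_across_collections(assignments,
                                                  group_col=group_col)
            if config.reconcile.length_bands:
                events = [ConstraintEvent(**e)
                          for e in config.reconcile.events]
                sy = assign_spawn_years(assignments,
                                        config.reconcile.length_bands,
                                        events, cohort_col="unified_cohort")
                assignments = assignments.merge(sy.drop(columns="candidates"),
                                                on="unified_cohort",
                                                how="left")
            else:
                assignments["spawn_year"] = ""
        except Exception as e:
            raise StageError(f"reconcile[{stream}]", e) from e

        try:
            stage(f"effsize[{stream}]")
            ld_panel = select_snp_panels(stats, "ld", seed=seeds["panel"],
                                         maf_min=config.effsize.pcrit)
            cohort_results = {}
            for cid, sub in assignments.groupby("unified_cohort"):
                members = [i for i in sub["id"] if i in pedigree.parents]
                if len(members) < 2:
                    continue
                rs = repro_summary(pedigree.parents, members, cohort=str(cid))
                entry = {"n": rs.n_offspring, "N_s": rs.ns,
                         "k_bar": rs.kbar, "V_k": rs.vk}
                try:
                    sf = nb_sibship(rs, pedigree.parents, members,
                                    B=config.effsize.bootstrap_B,
                                    seed=seeds["effsize"])
                    entry["nb_sf"] = {"point": sf.point,
                                      "ci": [sf.ci_low, sf.ci_high]}
                except ValueError as e:
                    entry["nb_sf"] = {"error": str(e)}
                try:
                    rows_c = np.array([idx[i] for i in sub["id"]
                                       if i in idx])
                    ctable = table.subset(individuals=rows_c)
                    ld = nb_ld(ctable, panel=ld_panel,
                               pcrit=config.effsize.pcrit)
                    entry["nb_ld"] = {"point": ld.point,
                                      "ci": [ld.ci_low, ld.ci_high],
                                      "S": ld.S, "r2": ld.r2_mean,
                                      "pcrit": ld.pcrit}
                except ValueError as e:
                    entry["nb_ld"] = {"error": str(e)}
                chao, jack = richness_estimates(pedigree.parents, members)
                entry["ns_hat"] = {
                    "chao": {"est": chao.ns_hat, "se": chao.se},
                    "jackknife": {"est": jack.ns_hat, "se": jack.se}}
                acc = parent_accumulation(pedigree.parents, members,
                                          n_perm=config.effsize.n_perm,
                                          seed=seeds["effsize"])
                acc.to_csv(os.path.join(
                    config.out_dir,
                    f"accumulation_{stream}_{cid}.tsv"), sep="\t",
                    index=False)
                cohort_results[str(cid)] = entry
                table2_rows.append({
                    "stream": stream, "cohort": str(cid),
                    "spawn_year": sub["spawn_year"].iloc[0]
                    if "spawn_year" in sub else "",
                    "n": rs.n_offspring,
                    "k_bar": round(rs.kbar, 2), "V_k": round(rs.vk, 2),
                    "SF": (round(entry["nb_sf"]["point"])
                           if "point" in entry["nb_sf"] else ""),
                    "LD": (round(entry["nb_ld"]["point"])
                           if "point" in entry.get("nb_ld", {})
                           and np.isfinite(entry["nb_ld"]["point"]) else ""),
                    "N_s": rs.ns,
                    "Ns_chao": round(chao.ns_hat, 1),
                    "Ns_jackknife": round(jack.ns_hat, 1)})
        except Exception as e:
            raise StageError(f"effsize[{stream}]", e) from e

        assignments.to_csv(
            os.path.join(config.out_dir, f"assignments_{stream}.tsv"),
            sep="\t", index=False,
            columns=[c for c in ["id", "stream", "collection_year",
                                 "mixture_label", "cluster_id",
                                 "final_cohort", "unified_cohort",
                                 "spawn_year"] if c in assignments.columns])
        ped_df = pd.DataFrame(
            [(o, p1, p2) for o, (p1, p2) in sorted(pedigree.parents.items())],
            columns=["offspring", "parent1", "parent2"])
        ped_df.to_csv(os.path.join(config.out_dir, f"pedigree_{stream}.tsv"),
                      sep="\t", index=False)
        sres["n_families"] = len(pedigree.families)
        sres["n_clusters"] = len(pedigree.clusters)
        sres["cohorts"] = cohort_results
        results["streams"][stream] = sres

    if table1_rows:
        pd.DataFrame(table1_rows).to_csv(
            os.path.join(config.out_dir, "k_selection.tsv"), sep="\t",
            index=False)
    pd.DataFrame(table2_rows).to_csv(
        os.path.join(config.out_dir, "cohort_estimates.tsv"), sep="\t",
        index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "module_seeds": seeds,
        "config": config.to_dict(),
        "inputs": {"vcf": _sha256(config.vcf),
                   "individuals": _sha256(config.individuals)},
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(os.path.join(config.out_dir, "results.json"), "w") as fh:
        json.dump(results, fh, indent=2, default=str)
    return results
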