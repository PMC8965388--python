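# broodnb

Larval-cohort inference and effective breeding number (N_b) estimation from
SNP genotypes, for semelparous species where sibling relationships cannot
span spawning years.

The pipeline chains five stages:

1. **Genotype QC** (`broodnb.qc`) — per-genotype depth masking, a paralog
   screen on observed heterozygosity (H > 0.6) and pooled heterozygote
   read-ratio deviation (|D| > 7), per-individual missingness (> 80%),
   Hardy-Weinberg exact-test reporting, and two SNP-panel selection rules
   (a 1-Mb-thinned pedigree panel; a best-per-target-region LD panel).
2. **Sibship reconstruction** (`broodnb.sibship`) — pairwise FS/HS/U
   log-likelihoods from identity-coefficient mixtures, bottom-up full-sib
   partitioning with joint-likelihood refinement, parental-genotype
   reconstruction, agglomerative half-sib linking through shared parents,
   and family clusters with locus-bootstrap support.
3. **Length-mixture cohorts** (`broodnb.mixture`) — Bayesian univariate
   Gaussian mixtures with two K-selection procedures (overfitted-mixture
   weight cutoff; birth-death MCMC over the component count) and a
   consensus rule.
4. **Reconciliation** (`broodnb.reconcile`) — family clusters force related
   individuals into one cohort: stray length misassignments are relabelled
   to the cluster majority, substantially spanning clusters merge cohorts;
   cohorts are linked across collections and mapped to spawn years using
   length-at-age bands and management-event constraints.
5. **Estimators** (`broodnb.effsize`) — per-cohort reproductive-success
   moments (k-bar, V_k), sibship-frequency N_b with bootstrap CI, the
   Burrows composite-r2 LD N_b with cross-chromosome pairs, Waples
   finite-sample bias correction and delete-one jackknife CI, parentage
   accumulation curves, and Chao2 / first-order jackknife extrapolation of
   the minimum spawner number.

A synthetic-data generator (`broodnb.simulate`) produces multi-year
semelparous scenarios with full truth tables (pedigree, cohorts, parent
genotypes), Mendelian inheritance with genotyping error / missingness /
negative-binomial read depth, Gaussian length-at-age sampling, optional
paralog injection and optional equilibrium-LD parent pools, so every stage
is testable without external data.

## CLI

```sh
broodnb simulate --seed 1 --out fixtures/           # synthetic scenario + truth
broodnb qc --vcf fixtures/genotypes.vcf --out qc/   # locus stats + exclusions
broodnb sibship --vcf fixtures/genotypes.vcf --out ped/
broodnb cohorts --individuals fixtures/individuals.csv --out k.json
broodnb run --config run.yaml --seed 1              # full pipeline
```

`run` consumes a YAML config with `vcf`, `individuals`, `out_dir`, `seed`
and per-stage blocks (`qc`, `sibship`, `mixture`, `reconcile`, `effsize`);
see `broodnb.config.RunConfig` for every knob and its default.  The output
directory gets per-stream assignment/pedigree TSVs, a cohort-estimates
table, K-selection probabilities, accumulation curves, and a manifest with
all seeds, thresholds and input hashes.

## File formats

VCF v4.2 (GT:DP:AD) in; individuals CSV with header
`id,stream,collection_year,length_mm`; TSV/JSON out; YAML configuration.
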