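# urateburden

Hyperuricemia — chronically elevated serum urate — is the precursor of gout,
and much of its population-level variation traces to common variants in renal
and gut urate transporters (ABCG2, GLUT9/SLC2A9, URAT1/SLC22A12, OAT4/SLC22A11,
NPT1/SLC17A1, MCT9/SLC16A9) and regulators (GCKR, PDZK1, LRRC16A).
`urateburden` is a small, fully tested pipeline for the genetic-epidemiology
question behind that observation: *given diploid genotype counts for a set of
urate risk loci in several ancestral subgroups, how does each subgroup's
risk-allele load compare with a European (EUR) reference panel?*

It is aimed at researchers who have per-population genotype counts (or
per-individual calls / a small VCF) for a candidate SNP panel and want the
standard assessment: Hardy–Weinberg QC, allele frequencies, per-locus
comparison against 1000 Genomes EUR, and a per-population risk-allele burden
summary.

## The procedure

For each SNP with alleles A/B, genotype counts (n_AA, n_AB, n_BB) and
n = n_AA + n_AB + n_BB:

1. **Hardy–Weinberg QC.** With p̂ = (2·n_AA + n_AB)/2n, the observed genotype
   classes are tested against the expectations (np̂², 2np̂q̂, nq̂²) by a plain
   1-df χ² (no continuity correction). A locus is *excluded* only when it
   deviates (p < 0.006) in **every** population subgroup — a deviation
   everywhere points at the assay, not at any one population. Monomorphic
   sites cannot deviate and are reported with χ² = 0, p = 1. An exact test
   (conditional on allele counts) is available as an option.
2. **Allele frequencies.** count_A = 2·n_AA + n_AB, count_B = n_AB + 2·n_BB;
   frequencies are the proportions on 2n chromosomes.
3. **Comparison vs EUR.** Per retained locus and population, the 2×2 table of
   allele counts (population vs reference) is tested with the Pearson χ²
   (1 df, uncorrected), or Fisher's exact test when any expected cell is
   below 5 (Cochran's rule). Significance is p < 0.006, a Bonferroni-style
   threshold for the nine-locus panel.
4. **Risk-allele burden.** Each locus has an annotated *risk allele* (the
   allele associated with baseline-or-higher urate/gout risk). Per population:

   * `n_significant` — retained loci whose allele frequency differs
     significantly from EUR;
   * `risk_index` — those that are significant **and** carry the risk allele
     at strictly higher frequency than EUR;
   * `risk_percentage` — 100 · risk_index / n_significant.

A seeded simulator generates multi-population cohorts at chosen allele
frequencies, with Wright's inbreeding coefficient F controlling heterozygote
deficit (HWE holds at F = 0) and a per-SNP missing rate controlling call
rate, so the whole pipeline is testable end to end without external data.

## Worked example

The package ships its motivating dataset: nine urate loci genotyped in six
ancestral subgroups (Filipino, Japanese, Korean, Native Hawaiian, Marshallese,
Samoan; 1059 post-partum women in total) plus EUR allele counts from 1000
Genomes Phase III.

```sh
urateburden run --out out/
cat out/risk_burden.tsv
```

```text
population	n_tested	n_significant	risk_index	risk_percentage	risk_loci
Filipino	8	6	6	100.0	rs1183201,rs17300741,rs2231142,rs2242206,rs505802,rs734553
Japanese	8	8	8	100.0	rs1183201,rs17300741,rs2231142,rs2242206,rs505802,rs734553,rs742132,rs780094
Korean	8	6	6	100.0	rs1183201,rs17300741,rs2231142,rs2242206,rs505802,rs734553
Marshallese	8	6	5	83.3	rs17300741,rs2231142,rs2242206,rs505802,rs734553
Native Hawaiian	8	6	5	83.3	rs1183201,rs17300741,rs2242206,rs505802,rs734553
Samoan	8	8	6	75.0	rs1183201,rs17300741,rs2231142,rs2242206,rs505802,rs734553
```

Reading: the PDZK1 SNP rs12129861 deviated from HWE in all six subgroups and
was removed, leaving `n_tested = 8` loci. The Japanese subgroup differs from
EUR at all eight, and at all eight the risk allele is the more frequent one
(`risk_index = 8`, 100 %). The Filipino subgroup differs at six, all six in
the risk direction. `out/` also contains the per-allele frequency table, the
HWE p-value matrix, the per-locus comparison table (test used, p-value,
significance marker, risk direction) and a machine-readable `report.json`;
the JSON annotates populations whose computed index differs from the
originally published summary of this cohort.

Each stage is also available on its own (`urateburden freq|hwe|compare|risk`),
as is the simulator (`urateburden simulate --config cohort.yaml --out sim/`),
and everything can be driven from Python via `urateburden.run_pipeline` and
friends.

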