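# Methods

## Model and assumptions

The pipeline treats every locus as an autosomal biallelic SNP with diploid
genotypes observed per population. Loci are analysed independently (no
linkage disequilibrium is modelled), populations are analysed independently
(no admixture or structure adjustment), and the reference panel enters only
through its allele counts. These are the assumptions of the candidate-gene
design the package implements; they are not relaxed anywhere.

Orientation convention: `allele_a` is the alphabetically first nucleotide of
the pair, genotype counts are ordered (aa, ab, bb) in that orientation, and
every table, 2×2 test and simulator output uses it. This removes the
major/minor and effect/other ambiguity that plagues transcribed frequency
tables; the risk allele is a per-locus annotation, not an orientation.

### Hardy–Weinberg QC

With allele frequency p̂ estimated from the observed genotypes, the χ²
statistic is Σ(obs − exp)²/exp over the three genotype classes with
exp = (np̂², 2np̂q̂, nq̂²), df = 1, no continuity correction. Conventions:

* **Monomorphic sites:** χ² = 0, p = 1, flagged `monomorphic`. A fixed
  allele cannot deviate from equilibrium; software that reports p = 0 for
  such sites is producing an artifact, and this package deliberately does
  not reproduce it.
* **Degenerate expected cells** (an allele class with expectation 0)
  contribute 0, the limit of (obs−exp)²/exp with obs = exp = 0.
* **Exclusion rule:** a locus is dropped only when p < threshold in *every*
  subgroup. Deviation in all populations at once indicates an assay problem
  (the packaged dataset's PDZK1 SNP, with near-total heterozygote deficit
  everywhere, is the canonical case); deviation in one subgroup may be real
  population structure and does not justify removal.
* An exact test (conditional on allele counts, point-probability two-sided)
  is provided as `hwe_exact_test` for small samples, but the χ² is the
  default because it is the convention of the genotyping-QC literature this
  package mirrors.

### Comparison against the reference

Allele counts of population vs reference form a 2×2 table. The Pearson χ²
(1 df) is used without the Yates correction — the correction is conservative
for allele-count tables of this size and is offered only as an option
(`yates=True`). "When appropriate" is operationalised as Cochran's rule:
Fisher's exact test (two-sided, point-probability method, as in
`scipy.stats.fisher_exact`) whenever any expected cell under independence is
below 5. On the packaged dataset every comparison satisfies the χ²
condition, so the dispatch rule never changes its results there. All tests
are two-sided; significance is the strict inequality p < threshold.

### Risk-allele burden

`risk_index` counts loci that are simultaneously (i) HWE-retained,
(ii) significantly different from the reference, and (iii) have the risk
allele at *strictly* higher frequency than the reference. The percentage
uses `n_significant` as denominator, consistently for every population, and
is undefined (JSON `null`) when nothing is significant. The burden report
attaches the originally published summary values for this cohort wherever
the computed index differs from them; the published per-locus frequencies
imply the computed values under the stated definition, and the package
surfaces rather than hides the divergence.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.006 | significance level for reference comparisons; the panel's operative Bonferroni-style value. `bonferroni_threshold(alpha, m)` computes α/m for principled use (0.05/9 ≈ 0.00556). |
| `hwe_threshold` | 0.006 | per-population HWE deviation level feeding the all-subgroups exclusion rule |
| `yates` | False | continuity correction on the 2×2 χ² |
| `inbreeding` (simulator) | 0.0 | Wright's F; genotype law (p²+Fpq, 2pq(1−F), q²+Fpq). F = 0 is HWE, F = 1 eliminates heterozygotes. |
| `missing_rate` (simulator) | 0.0 | per-SNP probability that a call is masked missing; call rate ≈ 1 − missing_rate |
| `reference_n` (simulator) | 503 | reference-panel individuals (the 1000 Genomes EUR panel size); counts are drawn on 2·n chromosomes |

The default threshold of 0.006 is kept as printed rather than the exact
0.05/9 because it is the operative rule of the study design the packaged
dataset comes from; both are configurable everywhere.

## Numerical and reporting conventions

* All statistics are computed on unrounded proportions. Percentages printed
  in reports are rounded half-up to one decimal (`percent`), matching how
  such tables are conventionally typeset; rounding never feeds back into a
  test.
* Call rates are computed only from individual-level information
  (`n_missing` known). When counts were transcribed from a published table,
  `n_missing` is unknown (`.` in TSV) and the call rate is reported as not
  computable instead of being inferred — published call rates and genotype
  totals are not generally consistent with each other, and guessing would
  manufacture precision.
* The simulator consumes one `numpy` Generator seeded once per cohort, in
  population → SNP (sorted by rsID) → individual order, so identical specs
  produce byte-identical cohorts; the reference panel is drawn as allele
  counts directly, since only allele counts of the referent enter any
  computation.
* Degenerate inputs raise typed errors (`DegenerateInputError`,
  `ValidationError`, `SchemaError`) naming the SNP and population; the
  pipeline wraps stage failures with the stage name.

## What the simulator does and does not emulate

It emulates the study design: several subgroups of a few hundred diploid
individuals genotyped on a small SNP panel, a large reference panel known
only through allele counts, HWE deviation via a single inbreeding parameter,
and missingness that is independent per call. It does not emulate linkage
between loci, genotyping error that is correlated across individuals or
biased by genotype (the usual cause of real HWE failures), population
substructure within a labelled group, or uncertainty in the reference panel
beyond binomial sampling. Passing simulation-based tests therefore
demonstrates statistical correctness of the pipeline under its own model,
not robustness to assay artifacts in real data.

## Test and acceptance problem sizes

Oracle-equivalence tests run hundreds of randomized small instances (2×2
cells ≤ 200, Fisher totals ≤ 60, HWE n ≤ 500) against brute-force
recomputation; calibration checks use 2000 replicates of n = 500 for the HWE
type-I error and 200–500 replicates for power and null-rejection checks.
These sizes give binomial confidence intervals tight enough for the asserted
bounds while keeping the whole suite in a few seconds.

## Known limitations

* Biallelic autosomal SNVs only; no multi-allelic sites, no X-chromosome HWE,
  no imputation, phasing or liftover.
* VCF ingestion is deliberately minimal: uncompressed or bgzipped VCF with
  GT fields, biallelic records matched to annotations by ID.
* No odds ratios or confidence intervals on the comparisons, and no weighted
  (effect-size) polygenic score: the burden index is an unweighted count by
  design, and the per-locus effect sizes carried in the annotations are
  metadata only.
* The burden index inherits the usual caveats of candidate-panel scores:
  it depends on the panel's composition and on the reference chosen, and a
  higher index is not an individual-level risk prediction.
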