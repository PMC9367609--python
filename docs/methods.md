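# Methods

## Problem and scope

`ctdnahet` analyses longitudinal circulating tumor DNA (ctDNA) variant calls
from patients whose tumors — high-grade serous ovarian cancer being the
motivating setting — are monitored by deep targeted resequencing of plasma
cfDNA alongside one or more synchronous tumor biopsies. The inputs are the
*outputs* of an upstream calling stack (two somatic callers per sample,
consequence-annotated VCFs) plus a per-plasma-sample tumor fraction (TF)
estimated externally from shallow WGS copy-number data. The package does not
align reads, call variants, or predict consequences.

The analysis has four stages:

1. **Ensemble merge.** The two callers' call sets are unioned per sample,
   keyed by (chrom, pos, ref, alt). A variant found by both callers carries
   both caller labels; its depths come from the deeper call (ties favour the
   first argument). No normalisation is performed beyond splitting
   multi-allelic records; indels are taken as left-anchored VCF
   representations.

2. **Filtering cascade.** Deep targeted sequencing of cfDNA (mean ~7000×)
   yields abundant artifacts, so filtering is deliberately aggressive. Stages
   run in a fixed order, and each removed variant is audited with exactly one
   rule — the first that fails:

   | order | rule id | semantics |
   |---|---|---|
   | 1 | `vaf_threshold` | plasma only: remove calls with VAF > TF + 0.05 |
   | 2 | `min_alt_reads` | remove calls with < 5 supporting reads |
   | 3a | `likely_germline` | remove loci called in *every* patient sample with VAF in [0.40, 0.60] or ≥ 0.90 everywhere |
   | 3b | `population_af` | remove calls with population frequency > 1% |
   | 4a | `del_upstream_homopolymer` | 1-base deletion immediately 5' of a run of ≥ 3 identical bases |
   | 4b | `ins_upstream_homopolymer` | 1–2-base insertion immediately 5' of such a run |
   | 4c | `snv_flanking_repeat` | SNV with a run of ≥ 3 identical bases on either flank |
   | 4d | `inframe_repeat` | inframe indel whose unit occurs ≥ 2 consecutive times immediately up- or downstream |
   | 5 | `cohort_frameshift` | frameshift identity present in > 60% of the sample cohort, removed everywhere |

   All removal comparisons are strict: a call exactly at a boundary
   (VAF = TF + 0.05, 5 reads, 1% population frequency, 60% cohort fraction)
   is retained. Repeat runs are measured on the reference strand only.

3. **Heterogeneity statistics.** Variants are matched across samples by a
   key of locus + base change + consequence annotation. Spatial analysis
   partitions each patient's baseline keys into *private* (one sample),
   *shared* (plasma + exactly one biopsy) and *common* (plasma + ≥ 2
   biopsies, which takes precedence over shared); per biopsy–plasma pair
   concordance is reported as a percentage. Temporal analysis computes the
   pairwise Jaccard score J(a,b) = |a ∩ b| / |a ∪ b| between plasma
   timepoints, the tumor molecular burden (TMB: distinct retained
   nonsynonymous keys per sample) and the Pearson correlation between plasma
   TMB and TF.

4. **Clinical scenario calls.** Molecular recurrence (TRm) is the first
   timepoint whose TF rises ≥ 20% relative to the previous point. Driver
   persistence classifies each pathogenic key across ordered timepoints as
   truncal / lost / acquired / transient. The TP53BP1 scenario logic
   summarises the temporal pattern of pathogenic TP53BP1 variants
   (never / mutated_at_baseline_lost / acquired_at_relapse / persistent /
   mixed) and raises a PARP-inhibitor resistance flag only when a BRCA1/2
   variant and a TP53BP1 variant co-occur in the same sample's retained
   pathogenic set. "TP53BP1 loss" is proxied by pathogenic point variants;
   no copy-number calls are made.

Pathogenicity is a local table lookup (gene + HGVS.c or locus → tier among
known_driver / tier1 / tier2, with optional therapy annotations). There are
no live database queries.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `vaf_tolerance` | 0.05 | additive buffer over TF for the plasma VAF ceiling (percentage points, absorbs sequencing error) |
| `min_alt_reads` | 5 | minimum ALT-supporting reads |
| `max_population_af` | 0.01 | population-frequency ceiling (strict) |
| `homopolymer_min_run` | 3 | run length that makes indel/SNV context artifact-prone |
| `inframe_min_copies` | 2 | adjacent unit copies that make an inframe indel artifact-prone |
| `cohort_frameshift_fraction` | 0.60 | cohort recurrence above which a frameshift is a library artifact |
| `germline_vaf_band` / `germline_high_vaf` | [0.40, 0.60] / 0.90 | heterozygous band / homozygous floor of the germline heuristic |
| `trm_threshold` | 0.20 | relative TF increase calling molecular recurrence |

## Design choices where the design was open

- **VAF threshold direction and form.** "TF increased by 5%" is read as an
  additive percentage-point buffer (threshold = TF + 0.05) acting as an
  *upper* bound: in ctDNA with known tumor content, a call far above what TF
  supports is germline signal or artifact, and an additive buffer is the only
  reading that changes behaviour in the low-TF regime where monitoring
  operates. Both the additive/relative form and the direction are config
  switches.
- **Germline heuristic.** Tumor-only germline removal here uses cross-sample
  behaviour: a locus present in every sample of a patient whose VAF sits at
  germline levels everywhere (i.e. does not track TF) is removed. This is a
  standard substitution for cohort-specific germline pipelines. A
  consequence worth knowing: a true germline variant at ~50% VAF in a
  low-TF plasma sample is removed by the VAF ceiling (stage 1) before the
  germline stage sees it, so its audit rule differs by sample type. Clinically
  relevant germline alleles (e.g. BRCA1/2) should be tracked from the sample
  metadata rather than from the filtered somatic set.
- **Flanking-repeat plurality.** The SNV rule fires on a run adjacent to
  *either* flank by default (`snv_flank_mode="both"` available), since
  requiring both flanks would make the rule almost never fire at min_run 3.
- **Spatial partition totality.** A key present in two or more biopsies but
  absent from plasma fits none of the three literal class definitions; it is
  assigned to *shared* (multi-sample, sub-common) so that the three classes
  always partition the key universe. The synthetic generator never produces
  this configuration; in real data it is logged implicitly by the partition
  table.
- **TRm from zero.** A rise from TF = 0 to any positive TF is called (the
  relative increase is undefined; the appearance of ctDNA signal is a
  fortiori recurrence). An absolute-increase mode and a minimum-TF gate are
  provided.
- **Concordance denominator.** The biopsy–plasma concordance percentage uses
  the union (Jaccard) denominator by default, with per-set denominators as
  options; both the per-pair median and the median of per-patient medians
  are emitted, since the aggregation level is a reporting choice.
- **Scenario taxonomy.** The five-way TP53BP1 taxonomy (never / lost /
  acquired / persistent / mixed) is this package's formalisation of the
  clinically described patterns; it is determined purely by the
  baseline-vs-relapse key sets (lost = baseline keys absent at relapse,
  acquired = relapse keys absent at baseline).

## Synthetic cohort generator

The generator (`ctdnahet.simulate`) is first-class, tested code. Its
defaults emulate the cohort structure the analysis assumes: 12 patients,
two synchronous biopsies and three plasma timepoints (T0, TRm, TRc) each —
60 samples; mean depth 7000×; one truncal TP53 variant per patient present
in every sample; a germline BRCA1/2 variant at ~50% VAF in all samples with
probability 0.28; biopsy-private subclones, a 35% draw of which also appears
in T0 plasma; plasma-private subclones per timepoint with VAF = clone
fraction × TF/2; TP53BP1 scenario variants planted per a designed scenario
distribution (weighted toward baseline-loss, as observed clinically), with
somatic BRCA1 co-occurrence planted in a fraction of acquired/mixed
patients; per-sample artifacts for each repeat rule placed on planted
substrate verified to match the rule; one cohort-recurrent frameshift in 70%
of samples; 1–2 common-population variants per sample (population frequency
1.1–40%); and 5 caller-B-private low-support false positives per sample
(1–4 reads) so the ensemble merge and read-support filter are both
exercised. Caller B re-detects each true variant with sensitivity 0.8 at
perturbed (strictly lower) depth, so merged depths deterministically come
from caller A.

Tumor-fraction trajectories start at TF ~ U(0.04, 0.15), drift by factors
U(0.75, 1.15) before TRm, jump by U(1.25, 2.0) at TRm (the designed first
≥ 20% rise) and drift by U(0.70, 1.60) afterwards, capped at 0.33. The cap
guarantees germline-level VAF (≥ 0.40) always exceeds the plasma VAF
ceiling (≤ 0.38), making germline fates deterministic.

Depths are Poisson(7000) with binomial ALT draws at the true VAF; draws for
variants that must survive the read-support stage are redrawn (bounded) to
honour ALT ≥ 5, which biases realised VAF slightly upward only at the very
lowest VAFs. Every emitted variant gets one ground-truth row with its
generative class and *intended fate* — the first cascade rule it should
fail, computed from the realised depths by a small independent
re-statement of the rule semantics (not by calling the pipeline).

**What the generator does not emulate:** read-level errors (no FASTQ/BAM),
trinucleotide mutational signatures, real gene coordinates (genes are
contiguous blocks of a synthetic 100 kb contig), caller-specific biases
beyond sensitivity/false positives, CHIP variants, and copy-number events.
Passing recovery tests therefore demonstrates the *logic* of the cascade and
classifiers — boundary semantics, rule attribution, set arithmetic,
trajectory thresholding — not performance on real sequencing noise.

## Numerical and degenerate-input choices

- Jaccard of two sets with an empty union is 0 (the statistic is undefined
  at 0/0); the diagonal of a Jaccard matrix is 1 only for nonempty sets.
- Pearson TMB–TF correlation on a constant series is reported as NaN
  (undefined), never 0; fewer than 3 pairs is an error.
- VAF is always `alt_reads / total_depth` with `DP` preferred over the AD
  sum; round-trips through VCF are exact because depths are integers.
- Repeat-rule predicates distinguish a context window clipped at a
  chromosome end (run genuinely terminates) from an under-sized window
  (raises an insufficient-context error); the cascade fetches ±60 bp.
- Ties in the ensemble merge (equal depth) keep the first caller's record.
- All output tables are sorted on declared key columns; reruns on identical
  inputs are byte-identical except for the manifest timestamp.

## Problem sizes used in the checks

The default verification cohort is 12 patients × 5 samples (~1200 emitted
calls including artifacts and caller noise) on a 100 kb synthetic contig —
structure-faithful but small, chosen so the full suite and the acceptance
script each run in seconds while every class of injected variant appears
dozens of times. The recurrence harness uses 1000 independent designed
trajectories; the rule-oracle comparison uses 100 random 10 kb references ×
60 candidate variants each.

## Known limitations

- The germline heuristic needs multiple samples per patient; single-sample
  patients will under-remove germline variants (population filtering still
  applies).
- Consequence strings are matched verbatim across samples; annotation
  version drift between timepoints breaks key identity (a warning is
  emitted when one locus carries differing annotations).
- The cohort frameshift rule depends on cohort composition: filtering the
  same sample within different cohorts can differ by design.
- TF values are trusted inputs; no uncertainty in TF propagates into the
  VAF ceiling or TRm calls.
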