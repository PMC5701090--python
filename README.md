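# mstrisk

Microsatellite repeat-length genotyping and case/control risk
classification from targeted amplicon sequencing.

## The problem

Microsatellites (MSTs) are tracts of a short (1–6 bp) unit repeated in
tandem. Their lengths are polymorphic between individuals, and at some
loci the *genotype* — the unordered pair of repeat-tract lengths on the
two chromosomes — differs systematically between cancer patients'
germline DNA and healthy controls, which makes panels of such loci
candidate blood-test risk markers. Reading those lengths accurately is
hard: repeats confuse aligners and PCR introduces *stutter* (reads off by
one repeat unit), so reliable genotyping needs high read depth and
repeat-aware length calling rather than standard variant calling.

`mstrisk` implements the full marker workflow for researchers evaluating
such panels:

1. **Catalog** perfect tandem repeats in reference sequences and assemble
   de-duplicated marker panels (`mstrisk.catalog`).
2. **Genotype** each sample at each panel locus from amplicon reads:
   quality trimming, flank-anchored tract measurement, allele-length
   histograms, and a stutter-tolerant diploid caller
   (`mstrisk.genotyper`).
3. **Screen** loci for case/control informativeness (`mstrisk.screen`):
   the *modal* genotype is the most frequent genotype among controls and
   the *predominant cancer* genotype the most frequent among cases; a
   locus is informative either by a 2×2 Fisher exact test on modal vs
   non-modal counts with Benjamini–Hochberg FDR control (discovery mode)
   or when both genotypes cover >50 % of their cohort and differ
   (validation mode).
4. **Classify** samples by their risk score (`mstrisk.classifier`) — the
   fraction of called signature loci carrying the risk genotype —
   with ROC analysis, an accuracy-optimal score cutoff, sensitivity /
   specificity / odds ratio `(TP/FP)/(FN/TN)`, and leave-one-out
   cross-validation that refits the whole model per fold.
5. **Power** the study design with the noncentral-*t* power of the
   two-sample *t*-test (`mstrisk.power`).
6. **Simulate** everything — references with planted repeat loci, cohorts
   with planted informative loci, and stutter-noised reads with a
   truth manifest — for end-to-end validation (`mstrisk.simulate`).

## Worked example

Fit the risk model on a simulated cohort of 30 cases and 89 controls
genotyped at a 40-locus panel with 13 planted informative loci:

```python
from mstrisk import (MicrosatelliteRiskModel, SimulationConfig,
                     simulate_cohort_genotypes, simulate_reference)

config = SimulationConfig(seed=42, n_loci=40, n_informative=13)
_, catalog = simulate_reference(config)
matrix, manifest = simulate_cohort_genotypes(config, catalog)

res = MicrosatelliteRiskModel(matrix, mode="validation").fit()
print(res.summary())
```

```
Microsatellite risk classifier
==============================================
mode:                validation
samples scored:      119 (30 case / 89 control)
loci screened:       40
signature loci:      13
score cutoff:        0.3846  (>= 5 of 13 risk genotypes)
AUC:                 1.0000
sensitivity:         1.0000
specificity:         1.0000
odds ratio:          10919.00
----------------------------------------------
signature (locus, risk genotype):
  locus0000                    26/26
  ...
```

The screen recovered all 13 planted loci as the signature. The score
cutoff 0.3846 means a sample carrying the risk genotype at 5 or more of
its 13 called signature loci is classified at-risk; at that cutoff every
sample is classified correctly (sensitivity and specificity 1.0), and the
odds ratio is the Haldane-corrected `(TP/FP)/(FN/TN)` for a perfect
30/89 split. Cross-validation refits the signature and cutoff 119 times,
once per held-out sample:

```python
cv = res.loocv()
print(f"LOOCV: {cv.n_folds} folds, pooled sensitivity "
      f"{cv.pooled_sensitivity:.4f}, specificity {cv.pooled_specificity:.4f}")
# LOOCV: 119 folds, pooled sensitivity 0.9667, specificity 1.0000
```

The same workflow is available from the shell:

```bash
mstrisk simulate all --outdir study/
mstrisk catalog scan study/reference.fasta -o study/scanned.bed
mstrisk genotype run --panel study/catalog.bed --reference study/reference.fasta \
    --labels study/labels.tsv --reads-dir study/reads -o study/matrix.tsv
mstrisk screen run --matrix study/matrix.tsv --labels study/labels.tsv \
    --mode validation -o study/locus_stats.tsv
mstrisk classify fit --matrix study/matrix.tsv --labels study/labels.tsv \
    --model-out study/model.json
mstrisk power ttest --n-case 30 --n-control 89 --diff 30 --sd 15
```

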