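# Methods

## Repeat cataloging

`scan_tandem_repeats` detects *perfect* (ungapped, mismatch-free) tandem
tracts: a reported locus is a whole-number repeat of a primitive 1–6 bp
unit, at least `min_tract_bp` (default 10) long, that cannot be extended
by a full unit in either direction. A trailing partial copy is trimmed so
that tract length is always a multiple of the unit length. When tracts of
different unit sizes overlap, the smallest unit that explains the tract
wins; remaining ties go to the leftmost, then longest tract. Motifs are
stored as the lexicographically minimal rotation (so `AC` and `CA`
de-duplicate to one catalog entry) alongside the phase observed at tract
start. Tracts containing `N` are never called, and every reported tract
needs at least two whole copies of its unit — this per-unit floor
replaces a blanket `min_tract_bp ≥ 2×max_unit` precondition, which would
reject the default parameters. The scanner deliberately does not model
impure (mismatch-containing) repeats: the marker panels this package
targets are short pure homopolymer/dinucleotide tracts, and an
alignment-scored impurity model would add complexity without changing
those calls.

Coordinates are 0-based half-open internally; the 1-based inclusive
`chr:a-b` style of published marker tables is accepted on input and
produced on output. Strand is ignored — after rotation canonicalization
a repeat reads identically on either strand.

`assemble_panel` unions marker lists by exact coordinates; a locus
present in several sources keeps every source tag, and
`counts_by_source` counts unique loci per tag (the counts sum to the
panel size exactly when the sources are disjoint, which is how assembled
panels are normally built).

## Genotyping

Reads are treated as **unaligned**. Each locus is located in a read by
exact match of the `flank_len` (default 10, minimum 6) reference bases on
either side of the tract; the allele is the length in bp of the segment
strictly between the two anchors, accepted only when both anchors match
exactly once and the segment is a pure run of the locus motif in some
rotation. This sidesteps the well-known failure mode of aligned BAMs at
repeats (arbitrary indel placement) and is appropriate for amplicon reads
that span the whole tract. Reads are first quality-trimmed with a
sliding-window rule (window 4, mean Q20, Trimmomatic semantics: cut at
the start of the first failing window, then keep individually good bases
at the cut point; drop reads shorter than `min_len`).

The diploid caller reduces the per-locus allele-length histogram with a
fraction threshold: alleles below `min_allele_frac` (default 0.25) of the
locus depth are treated as PCR stutter and discarded; two or more
survivors give a heterozygote of the two best-supported lengths (count
ties prefer the shorter allele, the common stutter direction), exactly
one a homozygote, and loci under `min_depth` are missing. The default
`min_depth` is 10, suited to modest-coverage discovery data; validation
runs at several-hundred-fold depth can raise it (e.g. 30) without losing
calls. No probabilistic stutter correction is attempted: at the
several-hundred-fold depths this pipeline targets, stutter peaks sit far
below the 25 % threshold (a ±1-unit stutter rate of 0.1 puts the stutter
peak near 5 % of depth), and the threshold rule is transparent and
order-invariant. Genotype equality throughout screening and
classification is exact equality of the unordered (a1, a2) bp pair.

## Locus screening

For each locus with call rate ≥ `min_call_rate` (default 0.5):

* the **modal genotype** is the most frequent genotype among called
  controls (ties broken to the lexicographically smaller pair), with a
  *predominance* flag recording whether its frequency strictly exceeds
  0.5 — ties are never predominant;
* the **predominant cancer genotype** is the same statistic over cases;
* **discovery mode** runs a two-sided Fisher exact test
  (minimum-likelihood summation, via `scipy.stats.fisher_exact`) on the
  2×2 table of modal vs non-modal counts in cases and controls, applies
  Benjamini–Hochberg step-up adjustment across the screened loci
  (`statsmodels`), and calls a locus informative when its adjusted value
  falls strictly below `q_cutoff` (default 0.0001, i.e. an FDR of
  0.01 %);
* **validation mode** calls a locus informative when the control modal
  and case predominant genotypes are each predominant and differ.

Missing calls are excluded from every numerator and denominator. The
per-locus odds ratio orients the risk category toward cases — non-modal
in discovery, the case-predominant genotype in validation — with the
Haldane–Anscombe +0.5 correction applied to all four cells whenever any
cell is zero. Modal is defined as *most frequent* (always defined) with
predominance as a separate flag so that discovery screening remains
defined at loci where no genotype reaches 50 %.

## Risk classification

A sample's score is the fraction of its *called* signature loci carrying
the risk genotype (validation) or any non-modal genotype (discovery);
samples with no called signature loci are unscorable, and samples with
fewer than half of the signature called can be flagged low-confidence.
Classification is `score ≥ cutoff`. The ROC sweeps the distinct observed
scores (plus a sentinel); AUC is the trapezoidal area, which equals the
Mann–Whitney concordance probability with ties credited 0.5 (asserted
against a brute-force pairwise oracle and scikit-learn in the tests). The
fitted cutoff maximizes accuracy over the distinct observed scores plus a
reject-all sentinel at 1.0 (needed so that "classify everyone healthy" is
expressible when it is the best rule); accuracy ties resolve to the
larger, more specific cutoff.

Leave-one-out cross-validation refits the **entire** model per fold —
modal/predominant genotypes, informative-locus set, risk genotypes and
cutoff are all re-estimated on the remaining samples before the held-out
sample is scored. This is the statistically honest variant;
`fixed_signature=True` reproduces the optimistic variant that fits the
signature once on the full cohort. Because a single held-out sample has
no sensitivity of its own, the result carries both pooled metrics over
held-out predictions and per-fold training metrics; folds whose refit
signature is empty are reported as unpredictable rather than silently
dropped.

## Power

The cohort-size power calculation is the closed-form power of the
two-sided pooled-variance two-sample *t*-test: df = n₁+n₂−2,
noncentrality δ = Δ/(s·√(1/n₁+1/n₂)), power = P(|T′| > t₁₋α/₂) under the
noncentral *t* (SciPy's `nct`). "Confidence interval of 0.95" is read as
two-sided α = 0.05. A Welch variant (Satterthwaite df under equal
variances) is available; the computation is agnostic to the units of Δ
and s, which for this design are classifier score percent. Tests verify
it against a 100 000-replicate Monte-Carlo oracle and statsmodels'
`TTestIndPower`.

## Synthetic data

The generator's defaults are the study conditions the package models:

| parameter | default | meaning |
| --- | --- | --- |
| `n_loci` | 347 | enrichment panel size |
| `n_cases` / `n_controls` | 30 / 89 | validation cohort |
| `n_informative` | 13 | planted signature size |
| `control_modal_freq` | 0.8 | top control genotype frequency per locus |
| `case_shift_freq` | 0.7 | shifted top genotype frequency in cases at planted loci |
| `depth_mean` / `depth_sd` / `depth_min` | 579 / 315 / 83 | per-locus read depth model (reads) |
| `stutter_rate` | 0.02 | per-read ±1-unit stutter probability |
| `base_error_rate` | 0.001 | per-base substitution probability |
| `tract_len_range` | 12–26 bp | planted tract lengths (mono/di-nucleotide) |

The cohort frequencies 0.8/0.7 are modeling choices for a strong
germline marker: a clear control majority genotype and a case shift
comfortably above the 50 % predominance rule — they are not estimated
from published data. References place one locus per contig with
rejection-sampled random flanks, guaranteeing the planted tract is the
contig's only repeat and each locus' left anchor is unique, so read
assignment needs no aligner. Control genotypes at each locus put
`control_modal_freq` on the reference homozygote and spread the rest
uniformly over genotypes built from alleles within `allele_spread` units;
informative loci give cases a different top genotype (the one-unit
expansion homozygote) at `case_shift_freq`. Depth per sample and locus is
a rounded normal clamped below at `depth_min` — clamping, rather than
redrawing, keeps the realized mean within a few percent of the nominal
mean while enforcing a hard floor. Stutter is ±1 unit only, and base
errors are excluded from the two anchor windows by default (the package
tests genotyping logic, not flank-rescue alignment; a switch enables
errors everywhere). All outputs are byte-deterministic given the config
seed, and the truth manifest (JSON, versioned) records per-locus
distributions, per-sample genotypes and the informative set.

What the simulation does **not** emulate: real population allele-frequency
spectra (each locus gets the same parametric shape), linkage between
loci, instrument-specific error profiles, multi-unit stutter jumps,
alignment artifacts, contamination, or covariate structure (age, smoking,
ancestry). Passing recovery tests therefore demonstrates that the
pipeline's logic is correct under its stated noise model, not that the
markers themselves would validate in new human cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script keep the full 347-locus, 119-sample
design for genotype-level simulations (which are cheap) and use reduced
panels for read-level simulation and LOOCV — 8–20 loci, since per-read
processing dominates and the fold count depends only on the cohort size.
The depth model is never reduced. Fisher exact agreement with the
hypergeometric enumeration oracle is verified exhaustively for all 2×2
tables with total ≤ 40 at 1e-12; ROC/AUC agreement with the concordance
oracle is exact. Degenerate inputs follow explicit conventions: a zero
Fisher margin gives p = 1, empty histograms are missing calls (not
errors), all-missing loci are unscreenable, and unscorable samples are
reported distinctly from scored ones.
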