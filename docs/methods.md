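# Methods

## Overview

`trapsil` analyses which genes are susceptible to KRAB/KAP1-mediated
silencing from gene-trap integration data. The chain is: barcoded LM-PCR
pyrosequencing reads → exact-primer selection and barcode demultiplexing →
20-bp junction-tag mapping (≤2 mismatches) → non-redundant gene model by
same-strand transcript overlap clustering → orientation-aware gene
assignment → REP/NREP pools per vector and per-gene silencing groups →
matched-control ROC-area enrichment of genomic/chromatin features at
multiple interval scales, with two complementary significance tests.

## Read processing

A read is kept only when sequencing primer A and primer B both occur
exactly (no mismatches) in the expected layout
`primerA + barcode + LTR remnant + genomic DNA + primerB`; everything else
is discarded with a reason (`primer_mismatch`, `no_barcode`,
`ltr_mismatch`). The 4-bp barcode encodes vector type and phenotype
(LI `TGAC/AGTC`, LR `CTGA`, MI `TCGA/AGCT`, MR `GTAC`; L/M = LV/MLV,
I/R = non-repressing/repressing). Every input read ends in exactly one of
{mapped, unmapped, ambiguous, too_short, discarded}; this conservation is
asserted in tests.

The 20 bases adjacent to primer B are the mapping tag. Mapping tolerates at
most 2 substitutions and scans both strands of every chromosome. The
implementation splits the tag into `max_mismatches + 1` near-equal segments
(pigeonhole: any window within tolerance must contain one segment exactly),
finds exact segment occurrences with plain string search, and verifies each
candidate window by Hamming distance. This is exactly equivalent to the
brute-force scan (asserted against an independent exhaustive oracle on 1000
random instances) at a fraction of the cost.

Conventions fixed here and used everywhere downstream:

* coordinates are 0-based half-open internally (SGA's 1-based positions are
  converted on read and restored on write);
* a mapped site's `position` is the forward-strand coordinate of the first
  tag base; `strand` is the provirus orientation (`-` when the tag matches
  the reverse complement);
* two or more windows tying at the minimal distance give `ambiguous`, and
  ambiguous sites are excluded downstream. The original mapper's tie policy
  is not documented anywhere we could find, so exclusion — the conservative
  choice — is used;
* `N` in a tag is never matched (`unmapped`, reason `ambiguous_base`).

## Gene model and assignment

Transcripts (refFlat-like: name, chrom, strand, txStart, txEnd) are grouped
into clusters = connected components of the same-strand overlap graph per
chromosome, with cluster bounds the 5'-most start and 3'-most end of the
members. Overlap means a nonempty intersection of half-open intervals;
intervals that merely touch do not cluster. For an interval graph the
components are exactly what a sorted sweep produces; equivalence with an
explicit union-find over all pairs is asserted in tests.

A cluster's TSS is its first transcribed base (`start` on `+`, `end − 1` on
`-`); "single known TSS" means one distinct transcription start among
members (txStart on `+`, txEnd on `-`). A site is *intragenic* when it
falls inside a cluster span, and *assigned* ("mapped relative to" the gene)
only when the provirus orientation matches the gene strand. Sites inside
overlapping opposite-strand clusters are reported once per cluster and
flagged `multi`. Intragenic fractions are reported per pool both as
sense-assigned and as any-orientation counts, since published totals do not
state which convention they used.

`dist_to_tss` is measured 5'→3' along the gene and is ≥ 0 for intragenic
sites.

## Silencing-phenotype gene groups

Candidate genes must span ≥ 20 kb (`min_gene_size`), have a single known
TSS, and carry ≥ 3 (`min_hits`) sense-assigned integrants within 20 kb of
the TSS (`window_full`). Groups:

* **group 1, long-range repression** — REP fraction over [0, 20 kb] ≥ the
  majority fraction *and* at least one REP integrant beyond 10 kb
  (`window_proximal`);
* **group 3, absence of repression** — NREP fraction ≥ the majority
  fraction;
* **group 2, limited repression** — both windows occupied, REP majority in
  [0, 10 kb] and NREP majority in (10, 20 kb].

"Mainly/mostly" is not quantified in the source description; the majority
fraction defaults to 2/3 and is echoed in every output header so calls are
auditable. When rules overlap the precedence is 1, then 3, then 2: a gene
with a strong overall REP majority is long-range even if its distal window
happens to be NREP-tilted. A gene with hits only below 10 kb cannot be
distinguished from group 1 and is left unclassified rather than guessed.
This rule set is a declared operationalization, not a claimed reproduction
of the original (unstated) decision rule. Flipping one NREP integrant to
REP can never demote a call toward group 3 (verified exhaustively for ≤ 6
integrants).

## Feature tracks and quantification

Track kinds and their window quantifiers over
`[anchor − half_width, anchor + half_width)` (clipped at chromosome ends,
no wraparound):

| kind            | source            | quantifier                                  |
|-----------------|-------------------|---------------------------------------------|
| interval        | BED               | number of overlapping intervals             |
| point_count     | SGA               | sum of per-position counts capped at cutoff |
| sequence_gc     | genome            | G+C base fraction                           |
| sequence_cpg    | genome            | CG dinucleotide frequency per bp            |
| tss_set         | clusters / ranks  | qualifying TSSs in window                   |

The per-position cap (cutoff, default 1) follows ChIPcor-style counting of
occupied positions; `cutoff=None` reduces to plain summation (equivalence
asserted). Expression-threshold TSS sets ("top 1/16th", "top 1/2") are
rank-based with ties broken by gene id, hence deterministic. Values are raw
counts, not end-corrected: matched controls absorb edge bias, which is the
point of the nested design. Gene-density counting uses TSSs in the window
by default (whether the original counted overlapping gene bodies instead is
unknowable from the text; both interpretations are constructible from the
track builders).

Anchored profiles aggregate capped counts in fixed bins over ±40 kb around
oriented anchors (window 500 bp for plots, 50 bp for statistics; bin 0 is
always the 5'-distal end, minus-strand anchors flip the axis). Metagene
profiles split each gene body into 40 equal bins (the last absorbs the
division remainder) plus 2-kb flanks in fixed 50-bp bins, reported as
per-bp densities, strand-flipped so column 0 is the 5' flank. The 50-bp
flank bin width and the remainder policy are this package's choices; the
source description is silent on both. Genes shorter than 40 bp are skipped
with a warning. Bin sums conserve capped in-range counts (asserted on
random fixtures).

## Matched controls and ROC area

Each case site receives its own `n_controls` random positions (default 10;
the original count is unstated). Two matching modes:

* `uniform` — chromosome ∝ length, position uniform, strand random;
* `msei_matched` — additionally matches the control's distance to the
  nearest MseI site (TTAA) to the case site's own distance within a
  tolerance (default 100 bp), as a surrogate for LM-PCR recoverability,
  since the library was MseI-digested. Chromosomes without TTAA fall back
  to uniform with a warning.

Neither mode claims to reproduce the original (unstated) matching
criteria. Control draws are deterministic under the seed.

The ROC area is `mean_i (b_i + t_i/2)` with `b_i`/`t_i` the fractions of
site *i*'s own controls strictly below / tied with the site's value. Ties
are half-weighted; this is forced jointly by requiring area = 0.5 when all
values tie and antisymmetry under case/control swap. When all sites share
one control pool the area equals the tie-corrected Mann–Whitney AUC
`U/(n·m)` (asserted against scipy on random fixtures). Sites with NA
feature values are dropped with a warning. Any strictly increasing
transform of the feature leaves the area unchanged.

## Group comparison

The published analysis names only a "non-central chi-square test"; two
tests are implemented and both are reported per (feature, scale):

* **chi2_clogit** — conditional logistic regression over matched sets
  (1 case + m controls), log-likelihood
  `Σ_sets [η_case − log Σ_j exp(η_j)]` with `η = βx + γx·1[group B]`,
  written from scratch with its analytic gradient and fitted by BFGS;
  the likelihood-ratio χ² (df = 1) tests the interaction γ = 0. Features
  are standardized before fitting (the LR is scale-invariant). Suspected
  separation or non-convergence falls back to the permutation p with a
  warning.
* **permutation** — two-sided p for `|A_A − A_B|` under group-label
  exchange. Because each site's score is computed against its own controls
  only, relabelling just reshuffles precomputed per-site scores, so the
  test is vectorized; assignments are enumerated exhaustively when their
  count is below the Monte-Carlo budget (default 10⁴), otherwise sampled
  with the add-one correction.

Stars follow the * p<0.05, ** p<0.01, *** p<0.001 convention on raw
p-values; a Benjamini–Hochberg column is emitted alongside for
transparency, with no correction applied to the stars themselves.

Gene-group expression comparisons use the two-sided Wilcoxon rank-sum
test: full enumeration of group assignments of the pooled ranks when both
groups have ≤ 10 genes (correct under ties, unlike textbook exact tables),
otherwise the normal approximation with tie and continuity correction. The
approximation sits within ~0.015 of the exact enumeration at n = 8.

## Synthetic data: what it emulates, what it does not

The generator produces, deterministically per seed: random-GC genomes
(`chrS1..chrSn`, named to avoid collision with real assemblies);
transcripts placed without inter-gene overlap, ~20% carrying a same-strand
overlapping isoform (half sharing the 5' end, so both single- and
multi-TSS clusters occur); CpG-island and DNase intervals at the TSSs of a
random "active" half of genes; SGA count tracks for two active (H3K4me3,
H3K27ac) and two repressive (H3K9me3, H4K20me3) marks; an expression table
higher for active genes by construction; integration sites; and reads.

Vector targeting: MLV sites are drawn Normal(TSS, 1 kb) along the gene
axis (so about half land just upstream, i.e. intergenic — mirroring the
real difference in intragenic fractions between vector classes), LV sites
uniform within gene bodies; 90% of proviruses are sense-oriented.

Phenotype model (the planted structure the enrichment scan must recover):

```
logit P(REP) = logit(baseline_p_rep)
             + distance_effect · exp(−|d| / distance_decay_bp)
             + feature_effect · density
```

with `d` the signed distance to the target TSS and `density` the value of
a configurable track (default DNase) in a ±1 kb window. Defaults:
`baseline_p_rep = 0.35` (roughly the repressible share in a mixed trap
population), `distance_effect = 2` log-odds at the TSS,
`distance_decay_bp = 10 kb` (the scale at which repression efficiency is
described as falling off), `feature_effect = 0` (enrichment is opt-in).
Only directions of these effects are constrained by observation; the sizes
are knobs precisely so that tests can plant effects of known magnitude.
The decay *scale* cannot set the strength of the distance term, which is
why `distance_effect` exists as a separate knob; `distance_decay_bp = 0`
disables the term, and baselines of exactly 0 or 1 are honoured exactly
(±∞ logits propagate through).

Reads are error-free by default; a `corrupt_fraction` introduces one-base
primer-A substitutions (discarded downstream by design) and
`read_error_rate` per-base substitutions confined to the genomic tag
(errors in primers are governed by `corrupt_fraction` alone, keeping the
two failure modes separable).

Not emulated: pyrosequencing flowgrams and quality values, chimeric LM-PCR
artifacts, restriction-fragment length biases, splicing structure, copy
number, and any correlation structure between chromatin marks beyond the
active/inactive dichotomy. Passing tests therefore demonstrate that the
pipeline's logic is correct and that planted effects of realistic size are
recovered — not that real pyrosequencing noise or real chromatin
covariance are handled.

## Numerical and degenerate-input choices

* Distance ties (equidistant positions) resolve to the smaller coordinate.
* `n_controls = 0` is rejected (the ROC area is undefined).
* Empty site groups yield NA heatmap rows; pools with zero mapped sites
  report NA intragenic fractions.
* Zero-length windows quantify to 0; anchors outside the chromosome raise.
* The permutation p uses `(hits + 1)/(n_perm + 1)` for Monte-Carlo draws
  and the exact fraction under full enumeration.
* Seeds: every stochastic stage takes an explicit seed; the generator
  derives independent streams per stage from (stage constant, seed).

## Problem sizes used in validation

The test suite and acceptance script run on two-chromosome genomes of
0.15–1 Mb with 10–40 genes and 80–1500 integrants: large enough for every
statistical check (binomial oracles at n = 10⁴ draws, 200-replicate null
calibration, 500-replicate type-I-error estimation, 1000-instance mapping
oracle) while keeping the full suite in tens of seconds. Planted-effect
sizes for the enrichment-recovery checks (`baseline_p_rep = 0.03`,
`feature_effect = 4`, mark density ≈ 0.05 points/kb) were chosen by the
power analysis sketched above: the REP group (~45 sites of 500) has
expected area ≈ 0.8 while the NREP group stays within 0.05 of background.

## Known limitations

* The conditional-logistic model handles one feature at a time (plus the
  group interaction); multi-feature adjustment is out of scope.
* `msei_matched` control matching is a recoverability surrogate, not a
  reproduction of the original matching (which is undocumented).
* The gene-group decision rule is an explicit operationalization of a
  verbally described classification; absolute group counts from the
  original data are not reproducible from the rule alone.
* Mapping excludes multi-mapping tags; with short (20-bp) tags on real
  genomes this discards repetitive-region integrants.
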