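# Methods

`apchits` reconstructs the downstream genetic analysis of colorectal polyps
from familial adenomatous polyposis (FAP) patients and sporadic cases:
germline/somatic partitioning of targeted-sequencing variant calls, APC
domain-aware hit classification, amplicon-panel copy-number calling,
VAF-based allelic-imbalance and mosaicism inference, and the cohort-level
contingency statistics. This note records the models, the defaults and the
reasoning behind the genuinely open design choices.

## Coordinate system and gene model

All protein coordinates are 1-based with closed intervals (HGVS convention);
genomic intervals in amplicon annotations are 0-based half-open (BED
convention). The bundled APC model has 2843 codons, a mutation cluster
region (MCR) of codons 1286–1513, and seven 20-amino-acid β-catenin-binding
repeats (20AARs) at 1262–1281, 1376–1395, 1492–1511, 1572–1591, 1827–1846,
1952–1971 and 2029–2048. These repeat intervals follow the public APC domain
annotation (UniProt P25054); they are shipped as an overridable YAML config
rather than hard-coded constants so a user can substitute their preferred
boundaries. The defaults satisfy the published constraints on the cohort's
germline variants: a truncation at codon 89 retains 0 repeats, truncations
at 1928/1933 retain 5, and any truncation inside the MCR retains at most 3.

A truncating allele's retained-20AAR count is the number of repeats whose
*end* precedes the truncation codon; a frameshift truncates at its first
altered codon (the `fs*N` downstream stop is ignored). Missense and
in-frame alleles leave all repeats intact.

## HGVS subset parsing

The parser covers the notation actually used in targeted colorectal panels:
cDNA substitutions (`c.1417C>T`), deletions/duplications/insertions/delins
on plain coding positions, and protein changes in one- or three-letter code
(`p.Q473*`, `p.S1068Gfs*57`, `p.A123T`, `p.T123=`). Intronic and UTR cDNA
positions are rejected — the pipeline has no transcript model to resolve
them. The codon comes from the protein notation when present, else
`ceil(cdna_position / 3)`; disagreements beyond ±1 codon raise a warning and
the protein notation wins (±1 absorbs frameshifts whose first altered
residue lies one codon downstream of the nucleotide change, e.g.
`c.2844delT` / `p.M949Cfs*6`).

## Hit classification

A polyp's APC hit total is germline hit (pathogenic variant or whole-gene
deletion: 0/1) + distinct somatic APC small variants (keyed by `hgvs_c`, so
the same notation at two VAFs counts once) + somatic copy-number-loss hit
(0/1, suppressed when the loss is the patient's germline deletion
re-detected in the lesion). All somatic APC small variants passing filters
count by default, because the published tallies are based on detected
somatic mutations; `include_nontruncating=False` restricts to truncating
alleles, since whether the original counts included non-truncating variants
is not stated.

The VAF cutoff is 5% and inclusive (`vaf >= 0.05`); boundary behavior was
unspecified so the inclusive convention was fixed once. Germline evidence in
the matched normal requires normal VAF ≥ 0.25 (configurable) — tolerant of
FFPE sampling noise while excluding low-level artifacts. A missing normal
sample leaves origins `unknown` with a warning, never silently somatic. The
MCR rate is polyps with ≥1 somatic APC mutation in the MCR over polyps with
≥1 somatic APC mutation, and is reported as undefined (not 0) on an empty
denominator.

## Copy-number calling

Counts are scaled within each (primer pool, sample) to fractions using a
0.5 pseudocount, `(c + 0.5) / Σ(c + 0.5)`; the pseudocount can be disabled,
restoring exact invariance to per-sample scaling. Per amplicon the log2
ratio against the mean of the normal-reference samples is computed, and the
gene's ratios are tested against 0 with a two-sided one-sample t-test.
Testing on the log2 scale treats loss and gain symmetrically; the original
analysis does not state its scale. "Neighboring amplicons" defaults to all
amplicons of the gene; an optional sliding window (recommended width 5)
tests sub-gene regions, and the most significant window is reported. A call
requires both p < α (default 0.05) and an effect-size guard on the mean
log2 ratio (≤ −0.32 for loss, ≥ +0.26 for gain, i.e. ~0.8×/1.2×), because
with many amplicons trivial shifts reach significance. Degenerate variance
or fewer than 4 amplicons yields `no_call` with p reported as 1. The α and
effect thresholds for declaring a loss were not published; both are config.

## Allelic state and mosaicism

For a germline variant at depth d and VAF v, an exact two-sided binomial
test of `round(v·d)` successes against 0.5 classifies the site. In tumors a
significant deviation is `increased` or `decreased` VAF (allelic imbalance);
in blood/normal tissue a significant VAF below 0.4 flags a postzygotic
(mosaic) variant. The 0.4 ceiling keeps heterozygous sampling noise at high
depth from being flagged; the published exemplar is a blood VAF of 16.7% at
which the flag fires at any realistic depth.

## Cohort statistics

Pearson chi-square is uncorrected everywhere (no Yates correction) — this
choice is validated by reproducing the published 0.102 / 0.407 / 0.010
p-values exactly at 3 decimals. Fisher's exact test (two-sided, sum of
hypergeometric probabilities ≤ the observed table's) is used for 2×2
tables; r×c tables use chi-square, as the published r×c p-values indicate.
Mood's median test classifies observations above vs at-or-below the pooled
grand median and tests the 2×k table — by Fisher when it is 2×2 with any
expected count below 5, else by chi-square. Reported tables round p to 3
decimals; result objects keep full precision.

The germline×somatic cross-tab tallies one entry per somatic APC mutation
(double-somatic polyps contribute two), with rows from the germline
retained-20AAR category (0 → 5′ variant, 5 → 3′ variant, whole-gene
deletion) and somatic retained counts binned 0/1/2/3+.

## Published-table fixtures

The study's per-polyp calls are supplementary-only; the printed marginals
are encoded as reconstruction fixtures that the pipeline must reproduce by
aggregation, not as asserted constants:

* a 99-polyp fixture for the germline-carrier polyps (74 with a somatic
  second hit = 74.7%, 9 with double somatic mutations = 9.1%, 83 somatic
  mutations distributed over the published cross-tab cells 52/22/9);
* a 60-polyp fixture for the somatic mutation spectrum (38 in-MCR = 63.3%,
  28 indels = 46.7%, 31 nonsense = 51.7%, C>T and C>A dominating the SNV
  spectrum).

Two denominators in the source are not mutually consistent at polyp level
(74/99 somatically mutated polyps vs rates quoted out of 60 polyps), hence
two fixtures. The source's abstract also rounds the double-somatic rate to
9.9% where its results print 9.1% (9/99); this package follows the
arithmetic, 9/99 = 9.1%. The whole-deletion row of the cross-tab is placed
at two retained repeats (cells 0/0/9/0), matching the textual description
of those patients' MCR mutations; only the row total (9) and grand total
(83) are load-bearing.

## Synthetic cohorts

The generator emulates the study conditions: 17 FAP pedigrees (germline mix
0.75 pathogenic variant / 0.10 whole-gene deletion / 0.15 none, matching
15/2/3 of 20 patients), 13 sporadic patients, ~6 polyps per FAP patient and
~3 per sporadic patient, somatic APC hit-count mixtures (FAP
0.25/0.66/0.09 for 0/1/2 somatic given a germline hit; sporadic
0.306/0.444/0.222/0.028), MCR concentration 0.633 (FAP) vs 0.444
(sporadic), KRAS rates by histology (0.24 low-grade, 0.78 high-grade/
carcinoma), tumor purity ~ Beta(8, 2) (mean 0.8, a realistic
microdissected-FFPE range), depth ~ Poisson(800). Germline VAF is
Binomial(d, 0.5)/d — or Binomial(d, mosaic fraction) for configured mosaic
patients — and somatic VAF is Binomial(d, purity·CCF/2)/d. Amplicon counts
are negative binomial (dispersion 0.1, moderate FFPE-like overdispersion;
no noise model was published) around per-amplicon lognormal efficiencies ×
per-pool totals, on a 9-gene/325-amplicon/2-pool panel. All draws come from
one seeded generator in documented order, so outputs are byte-reproducible
per seed.

What the generator does **not** emulate: read-level artifacts (FFPE
deamination, strand bias), alignment error, intra-tumor subclonality beyond
a single CCF, polymerase stutter at homopolymers, and correlated amplicon
dropout. Passing recovery tests therefore demonstrate correctness of the
downstream logic under the stated statistical model, not robustness to raw
Ion Torrent data pathologies — primary variant calling is upstream of this
package by design.

## Problem sizes and numerical choices

The acceptance script and test suite use: all 46 375 2×2 tables with total
≤ 30 for the Fisher-vs-enumeration check; 200 random tables for the
chi-square closed form (tolerance 1e-10); 1000 neutral and 500 loss
simulations (12 amplicons, log2 sd 0.1) for CNA calibration and power;
synthetic cohorts of ~150–300 polyps for recovery. Pool fractions are
checked to 1e-12. Type-I calibration is judged within 3·√(α(1−α)/reps) of
α. These sizes make every check a matter of seconds while keeping
Monte-Carlo error well below the margins being tested.

## Known limitations

* No transcript-aware annotation: the HGVS subset has no genome FASTA and
  rejects intronic/UTR positions; splice classification relies on the input
  notation.
* Copy-number calling is gene-level (optionally windowed); no segmentation
  across genes, no allele-specific copy number, no purity deconvolution.
* Pathogenicity is an input flag, not a prediction.
* The median test's Fisher fallback applies only to 2×2 median splits;
  larger k always uses chi-square.
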