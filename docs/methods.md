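# Methods

## Scope and model

`achropuce` classifies copy-number variants (deletions/losses and
duplications/gains) into the five ACMG tiers plus the French guidelines'
sixth, catalog-driven PIEV class (recurrent neurodevelopmental-disorder
CNVs with incomplete penetrance and variable expressivity). The classifier
is a transparent weighted rule system, not a learned model: each criterion
either fires or does not, contributes a fixed signed weight, and the class
is a threshold function of the sum. The package deliberately implements
only the criteria that are automatable from tabular reference data;
criteria requiring literature review or patient phenotype matching are out
of scope and are the main reason a rule system of this kind leaves many
variants as VUS on real data.

## Coordinates and matching

All coordinates are 0-based half-open internally; `chr:start-end` region
strings and 1-based TSV dialects are converted on read, BED is native.
Chromosome names are normalized without the `chr` prefix ("23"/"24" map to
X/Y). Genome build is carried as metadata and checked between query and
bundle; a mismatch is a hard error, there is no liftover.

Similarity between two variants is the reciprocal overlap
`RO = 2·I/(L_a + L_b)` — symmetric, in [0, 1], equal to 1 exactly for
identical intervals. Two variants are *non-comparable* exactly when their
relative size difference `|ΔL|/max(L_a, L_b)` exceeds 0.30 **and** they
share no gene; this strict conjunction is applied uniformly to control,
patient and syndrome matching (whether the rule was meant for all sources
was an open design point; uniformity was chosen as the simplest defensible
reading). Exactly 30% is not excluded (the rule is a strict inequality).
The denominator `max(L_a, L_b)` keeps the measure symmetric and bounded —
the size-difference definition itself was an open choice.

Reference lookups go through per-chromosome interval trees
(`intervaltree`); results are sorted by descending overlap, ties broken by
identifier, and are property-tested against a brute-force all-pairs scan.

## The criteria registry

Weights: direct ±1, major ±0.45, minor ±0.225, inheritance ±0.45. Class
thresholds: ≥ +1 → 5, ≥ +0.9 → 4, ≤ −1 → 1, ≤ −0.9 → 2, else 3, evaluated
outside-in so the overlapping "≥ +1 vs ≥ +0.9" boundary sentences resolve
deterministically. Sums of 0.45/0.225 multiples must compare exactly
against 0.9/1.0, so every threshold comparison allows a 1e−9 slack
(0.45 + 0.225 + 0.225 classifies as exactly 0.9).

Pathogenic side: syndrome-region overlap ≥ 80% (direct); full coverage by
a class-5 patient variant (direct); morbid gene content, 5′ deletion of a
haploinsufficient gene, homozygous deletion (copy number 0), amplification
(copy number > 3) (major); case–control morbidity enrichment, absence from
controls (< 50% best overlap), partial (< 80%) overlap with a class-5
patient variant when no morbid gene explains it, size > 1 Mb (minor).

Benign side: a control polymorphism — population frequency ≥ 1% or
observation count ≥ 2 at ≥ 80% overlap — is direct (−1); a control match
at > 80% overlap, or a CNV containing no genes (or only
pseudogenes/uncharacterized genes), is major; best control overlap in
[50%, 80%], morbidity non-enrichment, or gene content without any morbid
gene, is minor. Inheritance: de novo, affected parent or mosaic parent
+0.45; asymptomatic parent −0.45; unknown contributes nothing.

Design choices worth knowing:

* **Each criterion fires at most once**, however many reference matches
  support it: the guideline's criteria are per-criterion, not per-match,
  arguments.
* **Control evidence is not stacked**: polymorphism suppresses the >80%
  major criterion, which suppresses the 50–80% minor one.
* **Gene-content claims require gene data.** "No genes in the CNV" is
  asserted only when the bundle actually carries gene annotation; an empty
  bundle asserts nothing about gene content. Likewise "no morbid gene"
  requires at least one (non-pseudogene) gene hit.
* **Phenotype-dependent criteria are proxied** by the binary `is_morbid`
  gene flag, since no patient phenotype input exists. This is a proxy, not
  a faithful implementation of "associated with the same phenotype".
* Whether inheritance alone can combine with one major to cross a "likely"
  threshold is implied by additivity and implemented additively.
* The registry is configurable (`enabled_criteria`, weights, thresholds,
  overlap cut-offs) via YAML/JSON, because which guideline criteria are
  automatable is itself a judgment call.

## PIEV matching

A catalog entry matches when (i) its type is compatible (BOTH matches
either), (ii) the reciprocal overlap between the CNV and the entry's
region *expanded by the entry's breakpoint tolerance* reaches the
threshold (default 0.70), and (iii) every candidate gene of the entry lies
fully inside the CNV (vacuously true for entries without candidate genes;
a symbol absent from the gene annotation fails containment —
conservative). The best overlap wins, ties broken by name. A match
overrides the numeric score entirely; score and criteria are still
reported. Tolerance expansion is the mechanism for accepting recurrent
CNVs whose breakpoints deviate from the reference positions, which is
expected given the segmental-duplication architecture that generates them;
no published tolerance value exists, so it is a per-entry catalog column.
One known limitation: a CNV much larger than the catalog region that fully
contains it can still fail the reciprocal-overlap test; the threshold is
configurable for laboratories that want to accept such atypical events.

## Morbidity map

Enrichment is a plain frequency comparison (case_count/case_total vs
control_count/control_total) on the best same-type region at ≥ 0.70
reciprocal overlap; ties are not enrichment; no significance test is
applied, matching the qualitative "more frequent" wording of the
underlying criterion. Matching is type-specific because the case–control
counts are reported per event type.

## Trio filtering

A proband CNV is excluded when a parental CNV of the same type reaches
0.70 reciprocal overlap (no published stringency exists; 0.70 is the
package default and configurable). Retained variants keep UNKNOWN
inheritance — parental call sets are routinely incomplete, so promotion to
de novo (and its +0.45) is an explicit opt-in flag. The 300-variant batch
figure is treated as a chunk size for logging, not a cap; results are
invariant to chunking.

## Validation arithmetic

For validation the five tiers are collapsed: {4,5} positive, {1,2}
negative, 3 VUS (excluded from the four ratios, tallied per truth
stratum), PIEV excluded entirely. Sensitivity, specificity, PPV and NPV
are the standard ratios; zero denominators yield absent values. Display
rounding is half-up: one decimal for the four ratios, nearest integer for
VUS rates; full precision is always retained in the report object. The
acceptance suite checks this arithmetic against the published validation
table of five CNV classifiers; the four ratios of all five tools reproduce
exactly, while three of the ten published VUS integers disagree with their
own published counts by under one point (mixed rounding conventions in the
source), so VUS values are checked to ±1 point.

## Synthetic data

The fixture generator emulates, at desk scale, a balanced
pathogenic/benign validation set over curated reference databases — the
kind of set obtained by drawing benign variants from a control-population
archive and pathogenic/benign variants from a curated patient database. It
lays a toy genome (4 chromosomes × 100 Mb) out in disjoint 2 Mb slots with
100 kb margins, one evidence source per slot: 12 syndrome regions (1.2 Mb,
each containing a morbid gene), 30 class-5 patient variants (1.2 Mb, each
with one non-morbid gene), 40 control variants (400 kb; alternating
recurrent count-5/frequency-2% and singleton), 20 morbidity regions
(600 kb; alternating enriched 30:2 and non-enriched 1:5 per 1000),
8 recurrent-CNV catalog entries (800 kb, two candidate genes, 100 kb
tolerance), plus haploinsufficient-gene, pseudogene, plain-gene and desert
slots. 80 genes total with morbid/HI/pseudogene fractions 0.25/0.15/0.10
applied by deterministic rounding.

Planted CNVs (200 per truth stratum by default) follow five pathogenic and
four benign recipes, each constructed so the exact set of fired criteria is
predictable; two recipes intentionally land exactly on the ±0.9 "likely"
boundary to exercise it. Because slots are disjoint, no planted CNV can
pick up foreign evidence, which is what makes zero-crossover label
recovery a designed property of the generator + classifier pair rather
than a statistical outcome. The generator is deterministic: one spec, one
set of bytes.

What this does **not** show: performance on real data, where reference
sets overlap each other, breakpoints are noisy, size/frequency spectra are
heavy-tailed, and most of the VUS burden comes from criteria this package
does not automate. The fixture validates the machinery (parsing, matching,
scoring, thresholds, override, exclusion), not clinical accuracy.

## Problem sizes and numerics

Default test and acceptance runs use 400 planted CNVs, 60 recurrent-CNV
plants, 100 random trios, 10⁴ random interval pairs for the overlap
property suite and 500-entry indexes for the oracle-equivalence check —
sizes chosen so the whole suite runs in seconds while still exercising
every code path multiply. All randomness is seeded; scores are plain
float sums with the 1e−9 threshold slack described above; no other
numerical tolerances exist in the package.
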