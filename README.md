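# achropuce

Rule-based classification of copy-number variants (CNVs) after the French
Achro-Puce cytogenetics guidelines: weighted evidence scoring over
reciprocal-overlap matches against reference variant sets, the five-tier
ACMG classes plus the guideline's sixth catalog-driven class (PIEV), trio
filtering of inherited variants, and the confusion-matrix arithmetic used
to validate such classifiers.

## Who this is for

Laboratory geneticists and bioinformaticians who need a transparent,
auditable first-pass classification of CNV calls (from arrays or
sequencing) against their own curated reference tables — control-population
CNVs, pathogenic patient variants, syndrome regions, a case–control
morbidity map, gene annotation and a recurrent-CNV catalog. Every verdict
comes with the full list of fired criteria and their evidence, never a bare
label.

## The model

Variants are compared by **reciprocal overlap**,

```
RO(a, b) = 2·|a ∩ b| / (len(a) + len(b))  ∈ [0, 1]
```

and pairs differing by more than 30% in size *with no shared gene content*
are excluded as non-comparable. Each automatable criterion carries a signed
weight:

| tier | weight | examples |
|---|---|---|
| direct | ±1 | overlap with a known syndrome region; recurrent polymorphism in control databases |
| major | ±0.45 | morbid gene in the CNV; 5′ deletion of a haploinsufficient gene; homozygous deletion; amplification (>3 copies); control match with >80% overlap; no genes in the CNV |
| minor | ±0.225 | case–control enrichment; absence from controls; partial overlap with a pathogenic variant; size >1 Mb; control overlap 50–80%; no morbid gene |
| inheritance | ±0.45 | de novo / affected or mosaic parent (+); asymptomatic parent (−) |

The global score is the plain sum of fired criteria; classes follow fixed
thresholds evaluated outside-in: **≥ +1 → class 5** (pathogenic),
**≥ +0.9 → class 4**, **≤ −1 → class 1** (benign), **≤ −0.9 → class 2**,
otherwise **class 3** (VUS). Two majors — or one major and two minors — land
exactly on a "likely" threshold, reproducing the guideline's qualitative
class-4/class-2 rules. A CNV matching the recurrent-CNV catalog (with
breakpoint tolerance and candidate-gene containment) is classified **PIEV**
directly, overriding the numeric score.

## Worked example

Generate a synthetic reference bundle and classify a deletion that sits on
one of its syndrome regions:

```
$ achropuce fixtures --out bundle
$ achropuce classify --region 1:150001-1350000 --type del \
      --inheritance de_novo --bundle bundle
CNV      LOSS 1:150001-1350000 (1,200,000 bp, build GRCh37)
class    5
score    +2.350
criteria:
  P_SYNDROME                 +1.000  syndrome SYN000 overlap 1.000
  M_GENE_MORBID              +0.450  morbid gene(s): MORB000
  m_ABSENT_CONTROLS          +0.225  no control match at >= 50% reciprocal overlap
  m_SIZE_GT_1MB              +0.225  size 1200000 bp > 1000000 bp
  I_DENOVO                   +0.450  inheritance DE_NOVO
genes:
  MORB000      exons impacted   5  [M--]
```

The deletion coincides with a syndrome region (+1),
contains a disease-associated gene (+0.45), is absent from the control set
(+0.225), exceeds 1 Mb (+0.225) and arose de novo (+0.45): score +2.35,
class 5 (pathogenic). Validation arithmetic is available directly:

```
$ achropuce validate --counts 3271,29,8,1800,1650,3164
classifier: TP=3271 FP=29 FN=8 TN=1800 VUS(path)=1650 VUS(benign)=3164
  sensitivity_pct: 99.8
  specificity_pct: 98.4
  ppv_pct: 99.1
  npv_pct: 99.6
  vus_rate_pathogenic_pct: 33.0
  vus_rate_benign_pct: 63.0
```

Other subcommands: `batch` (table in, CSV/JSON out; malformed rows are
reported, not fatal), `trio` (exclude parentally matched variants before
classifying), `fixtures` (write a synthetic bundle).

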