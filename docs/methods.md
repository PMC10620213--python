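# Methods

This note documents the models, parameter choices and numerical
conventions behind `trioprio`, and what the synthetic cohorts do and do
not establish about behavior on real data.

## Unit of analysis

The pipeline's unit is a *proband-specific genotype*: one variant site
joined with one trio. A joint multi-sample VCF therefore expands into
one record per (site, trio) pair, each carrying exactly the three trio
members' calls. The identity key used for every join is
`(chrom, pos, ref, alt, proband_id)`; chromosome names are normalized to
prefix-free form so `chr7` and `7` inputs mix freely.

## QC cascade

Rules are evaluated in the fixed order *missing genotype → low depth →
low GQ → caller flag → common AF*; the order affects only which rule is
blamed in the report, never membership of the kept set (tested against
an order-free oracle). Conventions:

| parameter | default | meaning |
|---|---|---|
| `min_depth_exclusive` | 20 reads | depth must be **strictly** greater, in **all three** members |
| `min_gq_exclusive` | 50 | same, for phred-scaled genotype quality |
| `max_pop_af` | 0.01 | population minor-allele frequency strictly above this fails |
| `failing_filter_flags` | `VQSR`, `ExcessHet` | substring match against FILTER entries, so full tranche labels match |
| `treat_missing_af_as_rare` | true | ultra-rare variants are often absent from reference panels |

Depth/GQ thresholds are applied per trio member because downstream
inheritance logic needs all three genotypes to be trustworthy; a
site-level reading would admit trios with one unreliable member. Absent
DP or GQ is treated as failing its rule (conservative). The
trained false-positive filter used in some production pipelines is not a
statistical model this package defines; `filter_cohort` exposes an
injectable keep-predicate in the equivalent pipeline position, whose
drops are accounted separately.

## Inheritance decision table

For biallelic, QC-passing records (genotype notation: proband | father |
mother):

| region | pattern | category |
|---|---|---|
| autosome or PAR-X | ≥1 alt \| 0/0 \| 0/0 | de_novo |
| autosome | 1/1 \| 0/1 \| 0/1 | autosomal_recessive |
| non-PAR X, male | alt \| 0 \| 0/1 | x_linked_male |
| non-PAR X, male | alt \| 0 \| 0/0 | de_novo |
| anything else | — | other |

Design choices where the definitions left room:

* Male X calls `1` and `1/1` are both treated as hemizygous alternate
  (caller dialects differ); the father must be hemizygous reference.
* An X variant in a male whose mother is homozygous reference is
  labeled **de_novo**, not X-linked — the mother demonstrably lacks the
  allele — keeping the categories disjoint.
* Phase is ignored (`0|1` ≡ `0/1`); compound heterozygotes, mosaicism,
  Y and MT are out of scope.
* GRCh38 pseudoautosomal intervals (X:10,001–2,781,479 and
  X:155,701,383–156,030,895, 1-based inclusive) ship as defaults and can
  be replaced from a BED file (0-based half-open, converted on load).

De novo calls for the same variant key in more than `max_probands`
(default 2) distinct probands are removed entirely as presumptive
artifacts — true recurrent de novo hits at identical positions across a
small cohort are vanishingly unlikely.

## LGD consensus detector

Truncating consequences (frameshift, stop gained, splice
acceptor/donor; start/stop loss included by default and toggleable) are
detected iff the gene's LoFtool percentile is strictly below 0.25; an
unscored gene is *not* detected, since intolerance cannot be asserted.
Missense variants are detected at ≥ `min_votes` of six predictor votes,
with the cutoffs' printed inequality directions applied literally —
strict for SIFT/CADD/REVEL/M-CAP, inclusive for PolyPhen-2/MPC — and no
rounding tolerance at the boundaries. Everything else, including
in-frame indels and splice-region (non-acceptor/donor) variants, is
never detected.

Absent predictor scores never vote (`count_as_benign`, the default).
The alternative `drop_from_denominator` policy rescales the threshold
to the scored tools, `ceil(min_votes · n_present / 6)`, requiring at
least one scored tool — the proportional reading of "k of 6" when the
denominator shrinks.

Detection sets at rising `min_votes` are nested by construction;
truncating detections are invariant to the six missense scores and vice
versa (both property-tested).

## ACMG combining and PS2

The 2015 ACMG/AMP combining table is frozen in
`src/trioprio/data/acmg_rules.json` as minimum evidence-tier counts, so
rule edits are data, not code. Pathogenic and benign sides are
evaluated independently; both qualifying is a conflict resolved to VUS.
No evidence-strength modifiers or Bayesian point systems are applied —
the categorical rules are what guideline classifiers emit.

`apply_ps2_upgrade` adds PS2 to **every** record whose
(variant, proband) is confirmed de novo by the pedigree — not only VUS
records — then recombines the full vector. In practice only VUS calls
change class; a guard keeps a record from ever moving toward benign if
a tool's original label exceeded what its reported criteria support.
Recombining the full vector (rather than promoting VUS+PS2 by lookup)
is the defensible reading because the added strong criterion can
interact with existing moderates to reach P, not just LP.

## Evaluation statistics

* **Concordance** is the Jaccard index on (variant, proband) keys,
  × 100. This is the one fixed definition used everywhere; concordance
  of two empty sets is an error, not 100%.
* **Venn regions** are exclusive and partition the union exactly
  (property-tested); shares are relative to the union.
* **PPV** = detections in listed genes / all detections.
* **Odds ratio**: 2×2 of detected/undetected × listed/unlisted over the
  post-QC proband-specific pool (variant-level, not gene-collapsed);
  OR = ad/bc with the 95% Woolf CI `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`.
  Any zero cell triggers Haldane–Anscombe +0.5 on all four cells,
  flagged in the result; an empty margin is an error.
* **Diagnostic yield** = % of probands with ≥ 1 detection in a listed
  gene; multiple hits in one proband count once.
* **Two-proportion Z** uses the pooled estimate with a two-sided normal
  p-value; a pooled proportion of exactly 0 or 1 returns p = 1, flagged.
  No multiple-testing correction is applied across summary-table cells.
* **Summary tables** render percentages half-up at one decimal.
* **Threshold sweep**: detection is rerun at `min_votes` = 1…6 and
  Pearson's r over the (PPV, yield) points is reported with a two-sided
  p-value when ≥ 3 points have a defined PPV and both coordinates vary.

## Synthetic cohorts

The generator emulates: joint-VCF trio genotype structure with
Mendelian background transmission; planted de novo / recessive /
X-linked-male genotypes at per-trio counts; QC failure modes injected
into background sites at per-rule rates; two-component predictor-score
mixtures; and gene-list enrichment of damaging plants.

Study conditions (defaults): 220 trios, 80% male probands, a per-trio
budget of 20 variants of which 4 de novo + 3 recessive + 2 X-linked
(males) are planted — leaving roughly nine proband-specific ultra-rare
genotypes per trio after cleaning, the scale reported for real exome
cohorts of this kind — against a 1031-symbol reference list drawn from
an 8000-gene universe. Plants are 60% missense / 25% truncating / 15%
other; 35% of plants come from the damaging score component (per-tool
vote probability 0.90, 5% missing) and the rest from the benign
component (vote probability 0.15, matching the scattered false votes
real predictors produce on benign variants). `enrichment` (default 4.0)
is the odds multiplier for a damaging plant's gene being listed.

Two deliberate constructions make the tests sharp rather than lucky:

* Background transmissions that would *accidentally* produce a
  proband-specific pattern (het × het → hom-alt child; carrier mother →
  hemizygous son on X) are degraded to non-qualifying genotypes, so
  exact planted-set recovery is a designed property of the generator.
* `implied_detection_odds_ratio` gives the closed-form odds ratio the
  generator's mixture actually implies (vote-failure of damaging plants
  attenuates it below `enrichment`); calibration tests check CI coverage
  of that quantity, not of the raw knob.

Gene symbols are synthetic tokens (`G000001`…), never real gene names.
Identical seeds give byte-identical files; all randomness flows from a
single `numpy` generator.

What the synthetic cohorts do **not** model: read-level error, allele
balance, indel realignment artifacts, relatedness structure beyond the
trio, linkage between sites, realistic per-gene mutation rates, or
correlated predictor scores (votes are independent given the
component). Passing tests therefore establish the pipeline's logic and
statistics, not the error profile it would face on a real cohort; in
particular the sweep's PPV–yield trade-off is flatter here than with
real, correlated predictors.

## Problem sizes used in checks

The test suite exercises cohorts of 8–220 trios; the cohort-scale
recovery check uses 200 trios (~860k genotype pairs), the nesting
property 10,000 random score panels, the combining-table equivalence 50
random 8-criterion subsets × 256 combinations, the enrichment
calibration 100 replicate pools of ~2,000 proband-specific variants,
and the null-uniformity check 10,000 Z tests. The acceptance script
simulates one full 220-trio cohort plus the 100-replicate calibration.
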