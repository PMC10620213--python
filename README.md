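# trioprio

Trio whole-exome variant prioritization: find candidate disease variants
in parent–proband trios, compare detection strategies, and quantify how
well each one enriches for a reference gene list.

## Who this is for

Groups analyzing trio WES cohorts for conditions with heterogeneous
genetics (autism spectrum disorder being the motivating case), where
guideline-based classifiers (ACMG/AMP implementations such as InterVar
or TAPES) capture highly penetrant de novo variants but under-call
inherited, partially penetrant ones. `trioprio` implements the
complementary strategy — a likely gene-disrupting (LGD) consensus
detector — together with the shared upstream cleaning, the pedigree-aware
PS2 upgrade for imported classifier output, and the statistics needed to
compare the approaches.

## What it computes

**QC cascade.** Each variant site, joined with each trio, must have
called genotypes in all three members with depth > 20 reads and GQ > 50,
carry no VQSR-tranche/ExcessHet caller flag, and be rare (population
minor-allele frequency ≤ 1%). An injectable predicate slot after the
cascade accepts an optional trained false-positive filter.

**Inheritance classification.** Proband-specific genotypes are
*de novo* (proband carries an allele absent from both parents),
*autosomal recessive* (proband homozygous alternate, both parents
carriers) or *X-linked in males* (hemizygous alternate outside the
pseudoautosomal regions, carrier mother, reference father). Multiallelic
sites are dropped, and de novo calls recurring in more than two probands
are removed as likely artifacts.

**LGD consensus detection.** Protein-truncating variants (frameshift,
nonsense, start/stop loss, splice acceptor/donor) are detected when the
gene's LoFtool percentile is < 0.25. Missense variants face a vote of
six predictors —

    SIFT < 0.05   PolyPhen-2 ≥ 0.15   CADD > 20
    REVEL > 0.50  M-CAP > 0.025       MPC ≥ 2

— and are detected at ≥ k of 6 votes (default k = 5).

**ACMG combining + PS2.** The 28 ACMG/AMP evidence criteria combine into
P/LP/VUS/LB/B by the standard 2015 rules (shipped as data). PS2, the
confirmed-de-novo strong criterion, is assigned to every de novo record
imported from an external classifier and the class is recombined —
promoting qualifying VUS calls without ever downgrading.

**Evaluation.** Jaccard concordance and Venn regions between detection
sets; PPV (fraction of detections in listed genes); odds ratio with 95%
Woolf CI against the post-QC proband-specific pool (Haldane–Anscombe
correction on zero cells); diagnostic yield (% probands with ≥ 1 listed
detection); pooled two-proportion Z tests for summary tables; and a
vote-threshold sweep correlating PPV with yield.

**Synthetic cohorts.** `trioprio.synthetic` generates joint VCF + PED +
annotation + gene-list + truth files with planted inheritance patterns,
configurable QC failure rates, mixture-model predictor scores and a
known gene-list enrichment, so the whole pipeline runs and is testable
without any real data.

## Worked example

```bash
trioprio --outdir demo --seed 11 simulate
trioprio --outdir demo --seed 11 all
```

prints (abridged):

```
simulate: {'trios': 220, 'planted': 1904, 'classifier_InterVar': 597, 'classifier_TAPES': 608}
filter: {'input': 956560, 'kept': 942514, 'missing_genotype': 54, 'low_depth': 69, 'low_gq': 70,
         'gatk_flag': 9016, 'common_af': 4837, 'fp_filter': 0}
inherit: {'biallelic': 937455, 'multiallelic_dropped': 5059, 'proband_specific': 1904,
          'recurrent_denovo_dropped': 0, 'de_novo': 880, 'autosomal_recessive': 660,
          'x_linked_male': 364}
detect: {'input': 1904, 'detected': 494, 'lgd_truncating': 190, 'lgd_missense': 304}
acmg: {'denovo_keys': 880, 'InterVar_records': 597, 'InterVar_lp_p': 501,
       'InterVar_vus_upgraded': 230, 'TAPES_records': 608, 'TAPES_lp_p': 514,
       'TAPES_vus_upgraded': 233}
eval: {'tools_evaluated': 3}
```

Reading: the 220-trio cohort yields 956,560 (site × trio) genotype
pairs, of which 942,514 survive QC; exactly the 1,904 planted
proband-specific genotypes are recovered (880 de novo, 660 recessive,
364 X-linked); the LGD detector flags 494 of them; and the PS2 upgrade
promotes ~230 mock-classifier VUS calls per tool to LP. `demo/evaluation.json`
then holds, per detection set, the 2×2 table against the gene list, the
odds ratio with its CI, PPV, yield, pairwise concordances, Venn regions
and the threshold sweep with its Pearson r.

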