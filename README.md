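# famseg

Family-based rare-variant prioritization for exome studies of cancer
families.  Given a multi-sample VCF of germline calls, a pedigree with
phenotype labels, and a per-variant annotation table, `famseg` filters the
variant set down to the candidates that *segregate with disease* under a
configurable inheritance model — the standard analysis when a striking
familial cancer pedigree tests negative on known-gene panels and
whole-exome sequencing is used to hunt for new predisposing genes.

## The method

Variants flow through a four-stage cascade:

1. **Population filter** — keep variants with MMAF < 0.1%, where the MMAF
   (max minor allele frequency) is `max_s AF_s` over the consulted
   population databases (SweGen, gnomAD); a variant unseen everywhere has
   MMAF 0 and is flagged novel.
2. **Exonic filter** — keep protein-altering and splice consequences
   (missense, nonsense, splicing, frameshift, in-frame indel).
3. **Segregation strata** — the core step.  Each family is analysed in two
   strata: a *strict* filter in which every obligate carrier (affected
   member) must carry the variant and no one else may, and a *relaxed*
   filter modelling incomplete penetrance, in which up to `k` members of a
   slack pool of unaffected relatives may also carry it (equivalently:
   the variant survives exclusion by some combination of pool members —
   both formulations are implemented and proven equivalent by exhaustion).
   Strata generalize to per-stratum obligate-carrier definitions for
   families whose two filters differ by phenotype (e.g. breast+lung double
   primaries vs. any breast cancer), and a recessive mode requires affected
   members homozygous with heterozygous parents.  A variant is reported in
   the first stratum it passes, so strata are disjoint ("additional"
   variants).
4. **CADD tiers** — keep variants with phred-scaled CADD > 20; CADD > 25
   marks the high-risk tier.  All cutoffs are strict inequalities.

Side channels (never part of the cascade): a 64-gene hereditary-cancer
panel screen (MMAF < 0.2, with ClinVar assertions) and a known risk-SNP
carrier report.  A Mendelian gene-dropping simulator generates pedigree
genotypes from population allele frequencies, plants causal variants with
chosen penetrance/phenocopy rates, and emits annotation tables — so the
whole pipeline is testable end to end without any data download.

## Worked example

The package ships fixtures reconstructing three study families from their
published candidate tables (pedigrees, genotypes encoding the printed
carrier patterns, and annotations, plus decoy variants that each fail
exactly one filter):

```python
import famseg

fx = famseg.build_paper_fixture("Family1")
candidates, funnel = famseg.run_family_cascade(
    fx.annotations, fx.genotypes, fx.config, fx.thresholds
)
print(funnel.as_dict())
# {'total': 45, 'post_population': 36, 'post_exonic': 32,
#  'post_segregation_strict': 9, 'post_segregation_slack': 28,
#  'post_cadd': 24, 'strict_candidates': 7, 'slack_candidates': 17}
```

Of 45 input variants, 24 survive: 7 under the strict filter (only the
affected mother and daughter carry) and 17 more when one of the three
healthy sisters is allowed to be a non-penetrant carrier.  The same run
for Families 2 and 3 yields 9 + 8 and 1 + 34 candidates.  The equivalent
shell pipeline:

```bash
famseg fixtures --out-dir fixtures/
famseg run --vcf fixtures/family1/family1.vcf --ped fixtures/family1/family1.ped \
    --sidecar fixtures/family1/family1.phenotypes.tsv \
    --annotations fixtures/family1/family1.annotations.tsv \
    --config fixtures/family1/family1.config.ini --out-dir out/
# Family1: 24 candidates (7 strict, 17 slack); reports in out/
```

`out/` then contains per-stratum candidate tables (Filter / Gene /
Position / Ref/Alt / SNP / Type / Change / MMAF / CADD, sorted by stratum
then CADD), the funnel, panel and SNP screens, and a run manifest with
input digests.  `famseg simulate` produces gene-dropped cohorts with a
planted causal variant and a truth sidecar for recovery experiments.

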