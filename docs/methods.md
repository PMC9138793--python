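# Methods

## Model and assumptions

`famseg` implements carrier-pattern filtering, not statistical linkage: a
variant is a candidate when the observed carrier set across sequenced family
members is *consistent* with the configured inheritance model, and is
discarded otherwise.  No LOD score or segregation probability is computed;
with the small pedigrees this method targets (4–8 sequenced members), the
evidence is combinatorial, and the interesting dial is how much incomplete
penetrance the filter tolerates.

Assumptions baked into the filters:

* **Autosomal dominant, single variant.**  Every affected individual
  (obligate carrier) carries one copy; carrier status is phase-free, so
  heterozygous and homozygous calls are equivalent (`dosage >= 1`).
  Hemizygous male X calls are normalized to dosage 2 on input, which makes
  X-linked loci fall out of the same rule.
* **Incomplete penetrance as a bounded slack.**  The relaxed stratum allows
  up to `slack_k` members of a designated pool of unaffected relatives to be
  non-penetrant carriers.  Two equivalent formulations exist: count the
  pool carriers and require `1 <= count <= k` for a slack-only call, or
  enumerate every combination of `k` pool members as permissible carriers
  and require survival under at least one (treating the rest as excluders).
  Both are implemented (`segregate_slack`, `segregate_slack_by_enumeration`)
  and the test suite proves them equal over all 3^6 dosage patterns of a
  six-member pedigree.  The production path is the count-based one
  (linear, not exponential, in pool size).
* **Hard excluders stay hard.**  Members outside the slack pool who must
  not carry (e.g. the unrelated-by-hypothesis father under maternal
  inheritance) disqualify a variant in every stratum.
* **Generalized strata.**  Some families' two filters differ by *phenotype
  definition* rather than by slack — e.g. stratum 1 takes the breast+lung
  double-primary patients as obligate carriers with the breast-only proband
  as a non-carrier, while stratum 2 obliges all four affected women.  The
  engine therefore evaluates an ordered list of strata, each with its own
  obligate/excluder/slack sets; a variant is assigned to the first stratum
  it passes, which makes reported strata disjoint by construction and gives
  the "additional variants" semantics of a two-filter analysis.  Treating
  the proband as a stratum-1 non-carrier is the only reading under which
  the two reported strata partition the candidates; with the proband merely
  unconstrained, every all-four-carrier variant would collapse into
  stratum 1.
* **Recessive search is single-variant homozygous**: obligate carriers at
  dosage 2 and every designated parent exactly heterozygous.  Compound
  heterozygosity (two variants in one gene) is deliberately out of scope.

## Cascade and thresholds

Order: population filter → exonic filter → segregation → CADD tiers.  The
four filters select on independent per-variant properties, so the final
candidate set is order-invariant (tested); only the intermediate funnel
counts depend on the order, which follows the analysis workflow.

| parameter | default | meaning |
|---|---|---|
| `mmaf_population_max` | 0.001 | keep MMAF strictly below 0.1% |
| `mmaf_ultrarare` | 0.0001 | reporting tier, strictly below 0.01% |
| `cadd_min` | 20 | candidate tier, CADD strictly above |
| `cadd_highrisk` | 25 | high-risk tier, CADD strictly above |
| `panel_mmaf_max` | 0.2 | panel-screen frequency cut (strict) |
| `slack_k` | 1 | permitted non-penetrant carriers in the pool |

All comparisons are strict inequalities; a variant at exactly MMAF 0.001 or
CADD 20.0 fails.  MMAF is the maximum of per-database *alternate*-allele
frequencies; in the rare regime the filters operate in, alt and folded
minor frequencies coincide.  An allele frequency absent from a database
("." in the table) contributes nothing to the maximum but is distinct from
an explicit 0: absent-everywhere sets the novel flag.  ClinVar assertions
are reported, never used to exclude (a likely-benign candidate stays in
the table).  Missing genotypes are handled asymmetrically: missing in an
obligate carrier fails the variant (genotype-incomplete), missing in an
excluder or pool member is conservatively treated as non-carrier with a
per-variant warning.

## Built-in family fixtures

The three bundled families are reconstructed from their published candidate
tables, which print every surviving variant with gene, hg19 position,
ref/alt, rsID, consequence, MMAF and CADD, stratified by filter.  Fixture
construction:

* **Genotypes** encode the stated carrier patterns: strict-stratum rows are
  carried by the obligate carriers only; relaxed-stratum rows add exactly
  one slack-pool member, rotated deterministically through the pool (row
  index mod pool size).  Which healthy relative carried which variant is
  not published, so this assignment is synthetic; it does not affect any
  printed count.
* **Per-database frequencies** are reconstructed from the printed MMAF:
  SweGen carries the maximum, gnomAD a correlated lower value (0.75×).
  Only the maximum is ever consumed downstream.
* **Decoys** (≥ 4 per failure mode per family) each fail exactly one stage:
  common MMAF (including the 0.001 boundary), non-exonic/synonymous
  consequence, low CADD (including the 20.0 boundary), and
  segregation-inconsistent carrier patterns (excluder carriage, slack
  overflow, missing obligate).  They exercise every filter negatively.
* **Side-channel rows** plant the published panel-gene observations
  (FANCA/FANCM/TOPBP1 in Family 1, the BRCA2 rs80358899 carrier in the
  Family 2 proband, the CASP8 rs1045485 risk allele in the proband and her
  sister) at frequencies above the cascade cutoff, so they surface in the
  panel/SNP screens without touching candidate counts.  Their positions
  are synthetic placeholders within the named genes.

Known data oddities, preserved deliberately: one Family 1 position string
exceeds the length of its chromosome (as printed; fixtures store it
verbatim and no contig-length validation is applied); the Family 1 CLK1
variant is printed at MMAF 0.00041 although the running text counts it as
ultra-rare — the table value is used, so the strict-stratum ultra-rare
count computed here is 3, not 4; the Family 3 ultra-rare total of 31 is
obtained only when the strict-stratum PRKD1 variant (MMAF 0) is counted
together with the 30 relaxed-stratum rows, and that reading is adopted.
The PRKD1 carrier pattern itself (both brothers, neither parent) is
non-Mendelian as published; the fixture reproduces it and the
Mendelian-consistency checker flags exactly that row.

## Simulator

`gene_drop` draws founder alleles Bernoulli(af) per chromosome copy and
transmits one uniformly chosen allele from each parent down the pedigree
(male X: single maternal allele, hemizygous flag).  `plant_causal_variant`
seeds a chosen individual heterozygous (all founders heterozygous for a
recessive plant), transmits by gene dropping, and assigns affection with
probability `penetrance` to carriers and `phenocopy_rate` to non-carriers;
the truth record goes to a sidecar, never into the VCF.  Simulated
annotations draw the underlying allele frequency from a mixture — weight
0.3 on "absent from the databases" (novel), else log-uniform on
[1e-6, 0.5] — with CADD uniform on [0, 40] and a realistic consequence mix
(50% missense, 25% synonymous, 12% non-exonic, 5% splicing, 3% nonsense,
3% frameshift, 2% in-frame).  The zero-weight and the log-uniform tail are
a deliberate simplification of site-frequency spectra.

What the simulator does **not** model: linkage disequilibrium and haplotype
structure, sequencing error and coverage, de novo mutation, population
substructure in the database frequencies.  Passing recovery tests therefore
demonstrate the correctness of the filtering logic under clean Mendelian
transmission, not robustness to genotyping artifacts in real exomes.

## Numerical and design choices

* Test and verification problem sizes: exhaustive segregation checks cover
  all 3^6 = 729 dosage patterns of a six-member pedigree; recovery
  experiments use 1,000 seeded replicates per scenario; simulator soundness
  uses 10,000 independently dropped trio sites (frequency recovery judged
  at 3 binomial standard errors).  These sizes make the checks exact or
  tight while keeping the default suite in the seconds range.
* The planted-variant recovery rate has a closed form on the
  one-founder-lineage pedigree — survival of the strict filter requires
  every carrier penetrant, giving `sum_S 2^-4 f^(1+|S|)` over child
  transmission subsets — and the test computes it by exhaustive enumeration
  rather than hard-coding the number.
* Multi-allelic VCF records are decomposed into one biallelic key per alt
  allele with genotypes recoded per allele; decomposition preserves each
  sample's total alt-allele load (tested).  Phasing is ignored.
* Candidate tables sort by stratum, then CADD descending, ties by position;
  frequencies are printed in fixed notation ("0.0000649", never "6.49e-05").
* All randomness flows through explicit seeds (numpy `default_rng`);
  fixtures are fully deterministic and byte-identical across runs.

## Limitations

Genome-wide funnel totals from a real cohort cannot be reproduced from the
bundled fixtures, which contain only the published per-family candidate
variants plus decoys; the funnel machinery is validated structurally
(monotone counts, composition arithmetic) instead.  The 24-SNP risk panel
is not redistributed — the screen ships with the single rsID the source
tables document and accepts any user-supplied list.  Liftover, gVCF input,
annotation of raw VCFs, and splice-prediction scoring are out of scope.
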