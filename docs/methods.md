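# Methods

`trioscreen` implements a cohort variant-analysis workflow for rare
disease exome studies built around two ideas: (i) de novo variant
identification in proband–parent trios with a Poisson mutation-rate
burden test, and (ii) an exome-wide screen for case-specific *digenic*
combinations of rare deleterious heterozygous variants in
haploinsufficient genes. Because real patient exomes in such studies
are access-restricted, the package ships a first-class synthetic
cohort generator with planted truth; every pipeline stage is exercised
end-to-end against that truth.

## Cohort model and quality control

The unit of input is a jointly genotyped multi-sample VCF
(GT:GQ:DP:AD) plus a 6-column PED pedigree describing complete trios,
proband-only samples, and unrelated population controls. Multiallelic
records are split into one biallelic variant per ALT allele; alleles
belonging to another ALT are counted as reference for the split under
consideration, and allele depths follow each ALT's own AD column. No
further normalization (left-alignment, trimming) is attempted — inputs
are assumed to come from a joint-genotyping pipeline that emits
left-aligned records.

Hard filters, all configurable (`FilterThresholds`):

| parameter | default | meaning |
|---|---|---|
| `gq_min` | 20 | per-genotype minimum genotype quality (phred) |
| `dp_min` | 20 | per-genotype minimum read depth |
| `het_ab` | (0.3, 0.7), open | allele-balance window for heterozygotes |
| `hom_ab_min` | 0.98, strict | minimum AB for hom-alt calls |
| `missing_max` | 0.10 | maximum per-site missing-genotype rate |
| `hwe_min` | 1e-12 | minimum Hardy-Weinberg exact-test p |
| `controls_dp_min` | None | per-genotype DP override for controls |

Allele balance is computed from AD as alt/(ref+alt), never from DP,
because DP may include reads removed by the caller's internal filters.
All AB windows are strict inequalities. A genotype failing GQ/DP/AB is
masked to missing *before* the missing rate is computed; a site is then
dropped if its FILTER field is not PASS, its missing rate exceeds 10%,
or the HWE exact test falls below 1e-12. The operation is idempotent
and monotone in the thresholds.

Design choices that were genuinely open:

* **HWE on founders only.** The exact test conditions on parents and
  unrelated controls, excluding probands, because case genotypes at a
  trait-associated site legitimately depart from equilibrium; the
  departure we want to catch is a genotyping artifact. The test is the
  standard heterozygote-count-conditional two-sided exact test, built
  by outward recurrence from an interior heterozygote count and
  normalized at the end, which is stable for cohort-scale counts.
* **Controls sequenced on a different platform** (e.g. genomes rather
  than exomes) can be given a lower per-genotype DP floor via
  `controls_dp_min`; the override is per-genotype, not per-site.
* **Missing AD on a variant genotype** is treated as a filter failure
  under the default strict mode; a lenient mode skips AB-dependent
  filters for such genotypes instead.

## Annotation and variant classes

The package consumes a pre-computed annotation table (exact TSV header
`chrom pos ref alt gene consequence pop_af dann dann_rank splice_ada
plp_label`) rather than running an annotator; the synthetic module
fabricates this table. Classes:

* **LGD** (likely gene-disrupting): frameshift, nonsense, or a
  splice-site variant with dbscSNV ADA > 0.9. The splice rule is
  applied literally: canonical splice dinucleotides are *not* exempted
  from the ADA requirement, and a splice variant without an ADA score
  is not LGD (logged).
* **D-mis** (deleterious missense): missense with DANN > 0.98, strict.
* **rare**: population allele frequency strictly below the
  context-dependent cutoff — 0.5% for the digenic screen, 0.1% for de
  novo calling. An absent frequency is treated as 0 (the allele is
  unseen in the reference panel), which is the usual convention and is
  logged for audit.

LGD and D-mis are disjoint by construction; P/LP labels are expert
input and are never computed.

## De novo identification and burden

A candidate de novo variant requires, at a QC-passed site: proband
heterozygous with GQ ≥ 60, DP ≥ 20 and AB in the **closed** interval
[0.3, 0.7]; both parents homozygous reference with GQ ≥ 25, DP ≥ 20
and AB < 0.03; and population allele frequency < 0.1%. The closed
proband window intentionally differs from the open cohort-QC window —
both are taken literally from common practice for this two-stage
design. An orthogonal-confirmation hook accepts an external
confirmed/unconfirmed table (second caller, Sanger); by default all
calls are confirmed.

Burden per consequence class uses the standard mutation-rate
expectation E = 2 · n_trios · Σ_g μ_g(class) over a configurable gene
set (two transmitted haploid genomes per trio) and reports enrichment
observed/E with the upper-tail Poisson probability P(X ≥ observed).
The survival function is evaluated through SciPy, which computes it
stably in log space; tests verify it against direct log-space
summation. Supporting reports: Ti/Tv over SNV calls (transitions
A↔G, C↔T), a chi-square goodness of fit of per-trio counts to a
Poisson law with the rate at the sample mean (upper-tail bins pooled to
expected ≥ 5, dof = bins − 2), and a descriptive Spearman correlation
of counts against parental age.

## Digenic screen

The screen models additive haploinsufficiency. Stages, in order:

1. **Gene set**: autosomal genes with pLI strictly above 0.9.
2. **Qualifying variants** per proband: heterozygous, MAF < 0.5%,
   LGD or D-mis, gene in the set. Zygosity is het-only because the
   model is two damaged haplotypes across two genes; hom-alt variants
   are reported separately, not paired.
3. **Pair enumeration**: all unordered gene pairs with at least one
   qualifying variant on each side. For trio probands the evidence is
   restricted to couples whose origins draw one haplotype from each
   parent ({paternal, maternal}, or de novo standing in for either
   side); a variant carried by both parents, or with missing parental
   genotypes, has unknown origin and never satisfies the rule.
   Proband-only samples pair without origin restriction, since origin
   is unknowable without parents.
4. **Unaffected exclusion**: a pair is dropped when any single
   unaffected individual (parent or control) carries qualifying
   variants in *both* genes. The exclusion is gene-level, not
   exact-variant-level — the conservative reading that minimizes false
   positives — and is anti-monotone in the control set.
5. **Scoring**: a trained variant-combination classifier is an
   external tool, so the built-in score is an explicit stand-in:
   score = (mean deleteriousness of the best evidence couple; LGD = 1.0,
   D-mis = DANN rank) × (mean pLI of the two genes). An externally
   supplied score column overrides it verbatim. Zones are assigned
   from three ordered cutoffs (defaults 0.35 / 0.60 / 0.85 for
   candidate / 99%-zone / 99.9%-zone); four confidence tiers need
   three boundaries, and a calibrated classifier would supply its own.
   Only 99.9%-zone pairs proceed.
6. **Expression**: both genes must be brain- or skeletal-expressed.
7. **Recurrence**: surviving gene pairs carried by ≥ 2 unrelated
   probands form the recurrent tier; single-proband pairs are retained
   in a secondary tier.

Gene-pair identity uses uppercased, whitespace-stripped symbols with
lexicographic canonical order, so (A,B) ≡ (B,A) and results are
invariant to proband input order. The exclusion and expression filters
act on independent pair attributes and commute (property-tested).

## Synthetic cohort generator

Defaults mirror the study conditions the pipeline targets: 52 trios,
69 proband-only samples, 1,048 population controls; 1.5 de novo coding
variants per exome (the observed scale for trio exome studies, ~80
events over 52 trios); SNV transition probability 0.71, giving
Ti/Tv → 0.71/0.29 ≈ 2.45 at large n.

* **Gene panel**: 400 genes across chromosomes 1–22 and X, 15% with
  pLI > 0.9 (drawn uniform on (0.905, 0.9999); the rest from a
  low-skewed beta below 0.9), independent brain (65%) and skeletal
  (50%) expression flags, and log-uniform per-gene mutation-rate
  weights normalized so 2 · Σ μ equals the de novo rate, split 30/60/10
  across synonymous/missense/LGD.
* **Background sites**: 3 per gene; 10% common (AF uniform on
  0.05–0.40), the rest rare with AF from a Beta(0.5, 400) truncated
  below 0.5%, so both rare-qualification and control-exclusion logic
  see real traffic. Founders are drawn in Hardy-Weinberg proportions;
  trio probands receive Mendelian-transmitted alleles, so every
  non-planted proband het has a carrier parent and the only true de
  novo events are the planted ones.
* **Planted signal**: de novo counts per proband ~ Poisson(1.5), each
  event assigned to a gene by mutation-rate weight; two case-specific
  digenic pairs planted into 2 probands each (one trio proband with
  variants transmitted from opposite parents, one singleton) and one
  decoy pair additionally planted into 2 controls. Planted pair
  variants are D-mis with DANN rank ≥ 0.95 in genes with pLI ≥ 0.95,
  so they clear the 99.9% zone by construction; each carrier receives
  its own private variants, as recurrent pairs in real cohorts
  typically involve different alleles of the same genes.
* **Read evidence**: DP ~ Poisson(45), GQ high with a 3% low-GQ
  jitter, 0.5% sporadic missing genotypes, AD binomial around the true
  allele fraction with a 0.2% error rate on homozygous calls. Entries
  belonging to planted truths (carriers, and both parents at planted
  trio sites, including the non-transmitting parent) are overwritten
  with guaranteed-clean evidence so the truth is recoverable by the
  stated thresholds rather than by luck.
* **Deliberately bad sites**: two high-missingness sites, one all-het
  (HWE-violating) site, one non-PASS site, all recorded in the truth
  object; tests assert they are dropped for the stated reasons.

All randomness flows through one `numpy` generator seeded from the
config; fixture writers use fixed float formatting, so a seed fully
determines the output bytes (verified by manifest hashing).

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: linkage disequilibrium, sequence-
context mutation models, platform batch effects, genotype errors that
flip calls (noise here only degrades evidence, never miscalls), sex
chromosomes (all genotypes are simulated diploid; the X is present
only so the autosome exclusion logic has something to exclude),
relatedness or ancestry structure, and indel alignment ambiguity.

## Problem sizes and numerical notes

The default simulated cohort holds ~1,400 sites × 1,273 samples, which
the whole pipeline (simulate → write → re-read → QC → de novo → screen)
traverses in a few seconds; the burden-calibration study uses 2,000
replicates. The HWE recurrence is normalized after construction to
avoid overflow; upper-tail Poisson p-values below the double floor are
reported as 0 with an infinite-enrichment marker when the expectation
is exactly 0; ties in the HWE two-sided summation are included using a
1 + 1e-12 relative tolerance, the usual guard for this test.

## Known limitations

* The pair score is a stand-in; its absolute zone boundaries carry no
  clinical meaning and exist so the pipeline's tiering logic is
  testable and overridable.
* Recurrence significance is not assessed (cohorts of this size report
  counts, not p-values).
* Phasing is genotype-based only: a variant carried by both parents has
  unresolvable origin and is conservatively excluded from biparental
  evidence rather than phased by read backtracking.
* The burden test treats the mutation-rate table as known; uncertainty
  in μ is not propagated.
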