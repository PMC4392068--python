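# Methods

## Scope and model of the problem

`triotriage` implements the automated portion of a clinical reporting
workflow for trio exome studies of severe developmental disorders. The
input is assumed to be *called and annotated* data: decomposed variant
genotypes for child and parents, a most-severe consequence term per
variant, per-population allele frequencies, optional pathogenicity scores,
CNV intervals with an externally determined inheritance status, and a
curated gene panel. Variant calling, annotation, de novo genotype-quality
modelling, Sanger validation, uniparental-disomy and mosaicism detection,
and the expert phenotype review itself are all outside the package; the
cascade is therefore deterministic given its inputs.

## Inheritance classification

Inheritance is derived per variant by enumerating the (maternal gamete,
paternal gamete) pairs consistent with the parental genotypes and the
child's alt dosage:

- no consistent pair and both parents carry zero alt alleles → `de_novo`;
- no consistent pair otherwise → `mendelian_error`;
- dosage 2 → `biparental`; dosage 1 → `maternal`, `paternal`, or
  `inherited_ambiguous` when either parent could have transmitted;
- non-carrier child or missing parental genotypes → `uninformative`.

On the X chromosome male probands are hemizygous: the father's genotype is
ignored and the mother's carrier status decides maternal vs de novo.
Pseudoautosomal regions are treated as autosomal only when an explicit PAR
interval table is supplied; by default all of X is hemizygous in males,
since the generator never places variants in PARs. One consequence of the
gamete enumeration worth noting: a heterozygous child of a homozygous-alt
mother and heterozygous father is classified `maternal`, not ambiguous —
the alt copy must be maternal even though both parents are carriers.

Genotype error is not modelled. `mendelian_error` calls (and candidates
removed by inheritance-dependent exclusions) are emitted on a diagnostics
stream rather than silently dropped, because in real data they indicate
genotyping artefacts that upstream QC would handle.

A variant *segregates with disease* when it is de novo or when some parent
who could have transmitted it is affected. For `biparental` and
`inherited_ambiguous` calls any affected potential transmitter suffices;
this is an assumption where the source workflow is silent.

## Cascade semantics and defaults

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.01 | keep MAF ≤ 1% (boundary inclusive); missing MAF kept |
| `dominant_maf_threshold` | off | optional stricter bound (e.g. 0.001) in dominant genes |
| `cnv_loss_min_bp` | 100 000 | strict `>` for de novo/segregating losses |
| `cnv_gain_min_bp` | 250 000 | strict `>` for de novo/segregating gains |
| `cnv_unknown_inheritance_min_bp` | 500 000 | strict `>` for unknown-inheritance genic CNVs |
| `apply_x_missense_exclusion` | on | drop inherited X missense without family history/database hit |
| `benign_missense_score_cutoff` | off | optional score floor for *inherited* missense candidates |
| `xld_requires_segregation` | on | X-linked dominant genes follow the dominant inheritance rule |
| `mode` | trio | `proband_only` skips all inheritance-dependent rules |

Design choices that were genuinely open:

- **Filter order** is frequency → function → panel gene → genotype →
  inheritance. The cascade is a pure conjunction, so order affects only
  reason trails and cost, not the flagged set.
- **MAF aggregation** takes the maximum across configured population
  keys (conservative), and missing frequency is treated as rare because
  novel variants dominate diagnoses in this setting.
- **LOF partition.** Of the twelve functional terms, the seven
  truncating/ablating ones (transcript ablation, splice donor/acceptor,
  stop gained, frameshift, stop lost, initiator codon) count as loss of
  function; in-frame indels, missense, transcript amplification and
  coding-sequence variant are altered-product terms. The distinction is
  consumed only by the CNV mechanism matching.
- **Mechanism matching for sequence variants** is deliberately absent: a
  rare functional variant in a panel gene is matched on allelic
  requirement and inheritance only. Mechanism (loss of function vs
  dosage vs ...) gates the CNV path alone.
- **Compound heterozygotes** require a trans-consistent pair in trio
  mode: pairs unambiguously from the same parent are excluded; a de novo
  member may pair with either inherited member; ambiguous members (both
  parents heterozygous) remain eligible because trans cannot be ruled
  out. Proband-only mode enumerates all het pairs. Counting operations
  count one compound-het event per gene per proband, however many pairs
  qualify.
- **Recessive homozygotes** in trio mode require a `biparental` call —
  each parent carries at least one alt. A homozygous child whose stated
  parents cannot both have transmitted (including the double-de-novo
  configuration) is treated as a transmission inconsistency and excluded
  to the diagnostics stream.
- **Trio-mode fallback.** When parental genotypes are missing, the
  affected rules silently revert to proband-only semantics (logged), so a
  partial trio never loses candidates it would have kept as a singleton.
- **Phenotype gate.** Entries with required phenotype terms only
  *annotate* mismatching candidates (`phenotype-mismatch`); nothing is
  removed, because the phenotype comparison is a human step.
- **Two findings per proband** are allowed; there is no per-proband cap.

Boundary conventions: the MAF threshold is inclusive (`≤ 1%` kept); CNV
size thresholds are strict (`> 100 kb`), so events of exactly the
threshold length are dropped; CNV length is `end − start + 1` on 1-based
closed intervals. Inherited-but-non-segregating CNVs are never flagged by
the size rule.

## Reporting arithmetic

Predictive value = 100 × reported / reviewed, rounded half away from zero
to integer percent; undefined (rendered `..`) when nothing was reviewed.
Diagnostic yield = 100 × diagnosed / cohort size, same rounding, except
classes under 1% keep one decimal so small contributions stay visible. A
proband is diagnosed when at least one of its candidates is reported;
probands with two reported findings are counted so that
`reported findings − diagnosed probands = two-finding probands` holds.
Chromosomal-event diagnoses (uniparental disomy, mosaicism) found outside
the cascade enter the summary as opaque extra events with no reviewed
count.

## Synthetic cohort generator

The generator emulates the *statistical shape* of a large published trio
cohort, not human population genetics. Defaults per proband: rare
protein-altering variants ~ Poisson(400), of which ~ Poisson(30) fall in
panel genes; ~ Poisson(50) rare silent variants; 100 common variants
(MAF drawn uniformly in 1.1–30%) whose genotypes are drawn from parental
frequencies and transmitted Mendelianly; de novo functional variants
~ Poisson(1); a compound-het pair in a recessive panel gene with
probability 0.05; CNV count ~ Poisson(2) with log-uniform sizes spanning
10 kb–2 Mb (so all three size thresholds are exercised). 11% of children
have one affected parent and 2% have two; 51% of probands are male and are
hemizygous for X variants. Allele frequencies come from a two-component
mixture (rare log-uniform ≤ 1%, 20% missing; common > 1%) because only
the threshold crossing matters to the cascade. Genes are synthetic
identifiers on a synthetic genome (20 kb genes every 300 kb); the panel
mixes allelic requirements roughly 55/30/10/5 (monoallelic / biallelic /
X-linked recessive / X-linked dominant) across mechanisms.

Spike-ins insert variants with known expected triage outcomes in both
modes — positive controls (de novo dominant, recessive homozygote,
trans compound het, hemizygous X) and negative controls (common variant,
synonymous variant, cis compound het, inherited X missense) — and a truth
table records the expectation per spike. `truth_eval` matches truth rows
to candidates by proband and position set and reports per-category
sensitivity/specificity.

What the generator does **not** emulate: realistic site-frequency spectra,
linkage, annotation errors, genotype quality, exome capture artefacts, or
calibrated per-proband flag-count distributions. Passing tests therefore
demonstrate the *logic* of the cascade (rule correctness, mode
monotonicity, spike recovery), not its operating characteristics on real
patients. Genotyping error is off by default; a small error rate exists
solely to exercise Mendelian-error handling.

## Verification strategy and problem sizes

The inheritance classifier is checked exhaustively against an independent
gamete-enumeration oracle over all 27 autosomal genotype combinations and
all X combinations for both proband sexes. Cohort-level properties
(trio ⊆ proband-only per family, affected-parent toggling only adds
candidates, 100% spiked-positive recovery, 0% spiked-negative flagging)
run on one seeded 200-trio cohort shared across the suite; the acceptance
script regenerates a 150-trio cohort from its own seed. These sizes give
tight Poisson means (SE ≈ 1.4 on the 400-variant count at n = 200) while
keeping the suite fast. Bookkeeping arithmetic is verified on fixtures
encoding a 1133-trio cohort's published summary counts; three printed
percentages in that source table are not integer-roundings of their own
printed counts (they appear to have been computed on a post-validation
subset) and are deliberately not asserted.

## Known limitations

- Phasing uses parental origin only; population or read-backed phasing is
  not attempted, so ambiguous het pairs are (correctly) never excluded as
  cis.
- X-linked dominant handling in females follows the dominant segregation
  rule by default (`xld_requires_segregation`); the alternative —
  flagging all rare X-linked dominant hets — is a configuration switch
  because curated practice varies.
- The per-proband flagged-count *distributions* of real cohorts constrain
  but do not identify generator parameters; no attempt is made to match
  them exactly.
- CNV inheritance status is consumed as given; the package never
  re-derives CNV segregation from parental data.
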