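# triotriage

Automated clinical variant triage for parent–offspring exome trios.

Children with severe undiagnosed developmental disorders carry tens of
thousands of genomic variants each; only one or two are diagnostically
relevant. `triotriage` implements the scalable filtering cascade used by
large trio-sequencing diagnostic programmes: starting from annotated
multi-sample variant calls, a copy-number event table, a pedigree, and a
curated genotype-to-phenotype gene panel, it reduces each child's variant
load to a short list of flagged candidates for expert review, and then
turns review decisions into cohort-level predictive-value and
diagnostic-yield bookkeeping.

## The filtering cascade

Candidates must pass, in order:

1. **frequency** — minor allele frequency ≤ 1% (maximum across reference
   populations; missing frequency counts as rare; an optional stricter
   0.1% threshold can be applied in dominant genes);
2. **function** — the most severe consequence is one of the twelve
   protein-altering sequence-ontology terms (transcript ablation through
   coding-sequence variant); the truncating subset is treated as loss of
   function;
3. **location** — the variant's gene has a reportable panel entry; each
   entry carries an *allelic requirement* (monoallelic, biallelic,
   X-linked dominant/recessive) and a *mutation consequence* (loss of
   function, dominant negative, activating, increased gene dosage, ...);
4. **genotype** — the child's genotypes satisfy the allelic requirement:
   a single heterozygote suffices in a monoallelic gene, biallelic genes
   need homozygous-alt or a compound-heterozygous pair in *trans*, and
   X-linked recessive genes need hemizygous males or homozygous females;
5. **inheritance** — with parental genotypes, inheritance is derived by
   gamete enumeration (de novo / maternal / paternal / biparental /
   ambiguous / Mendelian error). Heterozygous candidates in dominant genes
   are kept only when de novo or transmitted by an affected parent;
   homozygous recessive candidates require both parents to be carriers;
   inherited X-chromosome missense variants are excluded unless there is a
   family history or the variant is in a known-pathogenic database.

Copy-number events follow a parallel path: rare losses are flagged when
they fully contain a panel gene with a loss-of-function or
dominant-negative mechanism, gains when they overlap an
increased-gene-dosage gene, and non-panel genic events on size alone
(>100 kb losses / >250 kb gains when de novo or segregating with disease,
>500 kb when inheritance is unknown).

Every flagged candidate records the ordered rule trail it passed, so every
flag is auditable. The phenotype comparison performed by human reviewers is
out of scope; an optional gate only *annotates* candidates whose panel
entry requires phenotype terms the patient lacks.

Cohort bookkeeping follows the standard definitions: the **predictive
value** of a flag class is the percentage of reviewed candidates reported
as likely diagnostic, and the **diagnostic yield** is the percentage of
the cohort diagnosed by that class.

A seeded synthetic-cohort generator (`triotriage.synth`) produces trio
VCFs, CNV tables, pedigrees, panels and spike-in truth tables with this
cohort structure, so the full pipeline is testable without patient data.

## Worked example

Simulate a small cohort with two spiked de novo diagnoses and one spiked
compound heterozygote, triage it in trio mode, and summarise:

```bash
triotriage simulate --out demo/cohort --seed 7 --n-trios 5 --config sim.yaml
triotriage triage --vcf-dir demo/cohort/trios --ped demo/cohort/cohort.ped \
    --panel demo/cohort/panel.tsv --cnv demo/cohort/cnvs.tsv \
    --family-history demo/cohort/family_history.tsv --mode trio --out demo/trio
triotriage summarize --candidates demo/trio/candidates.tsv --cohort-size 5 --out demo/summary
```

which prints

```
21 candidates flagged across 5 probands -> demo/trio/candidates.tsv
                                  inherited  de_novo
autosomal_dominant                        0        4
autosomal_recessive_homozygous            0        0
autosomal_recessive_compound_het          9        0
x_linked_dominant                         0        1
x_linked_recessive                        3        0
Total                                    12        5
```

The four de novo dominant flags include the two spiked diagnoses (the
others are background de novo variants that landed in panel genes); the
compound-het row counts events once per gene. Each row of
`candidates.tsv` carries the full reason trail, e.g.

```
FAM00000_c|autosomal_dominant|1|1012310|PG0000   de_novo
  frequency<= 0.01 > functional_consequence > panel_gene:PG0000 >
  requirement:monoallelic > inheritance:de_novo
```

Because all ten parents are unaffected, rerunning with
`--mode proband-only` flags far more candidates (inherited heterozygotes
in dominant genes dominate); the trio-mode list is always a subset.

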