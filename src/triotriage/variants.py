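"""Variant data model and trio VCF ingestion.

A :class:`VariantRecord` is one decomposed (site, alt-allele) pair with the
proband's and parents' genotypes attached, plus the annotations the triage
cascade consumes: gene symbol(s), the most-severe sequence-ontology
consequence term, a population minor allele frequency, optional pathogenicity
scores, and a known-pathogenic-database membership flag.

Consequence handling follows the twelve protein-altering ("functional")
sequence-ontology terms used by exome diagnostic pipelines, of which the
truncating/ablating subset is treated as loss of function.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .pedigree import TrioPedigree

logger = logging.getLogger(__name__)

#: The functional (protein-altering) consequence terms, in decreasing
#: severity order. Variants whose most severe consequence is not in this
#: list are filtered out as non-functional.
FUNCTIONAL_TERMS: tuple[str, ...] = (
    "transcript_ablation",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "initiator_codon_variant",
    "in_frame_insertion",
    "in_frame_deletion",
    "missense_variant",
    "transcript_amplification",
    "coding_sequence_variant",
)

#: Truncating / gene-ablating subset of :data:`FUNCTIONAL_TERMS`. The
#: remaining five functional terms alter the protein product without
#: truncating it.
LOF_TERMS: frozenset[str] = frozenset(
    {
        "transcript_ablation",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "initiator_codon_variant",
    }
)


def normalize_term(term: str) -> str:
    """Normalise a sequence-ontology term to lower-case underscore spelling.

    Accepts space-, hyphen- and underscore-delimited spellings
    (``"stop-gained"``, ``"stop gained"`` and ``"stop_gained"`` are the same
    term).
    """
    return term.strip().lower().replace("-", "_").replace(" ", "_")


@dataclass(frozen=True)
class ConsequenceTable:
    """Severity-ordered functional term list with its LOF subset."""

    terms: tuple[str, ...] = FUNCTIONAL_TERMS
    lof_subset: frozenset[str] = LOF_TERMS

    def __post_init__(self) -> None:
        if not self.lof_subset <= set(self.terms):
            raise ValueError("lof_subset must be a subset of the functional terms")

    def severity_rank(self, term: str) -> Optional[int]:
        t = normalize_term(term)
        try:
            return self.terms.index(t)
        except ValueError:
            return None


DEFAULT_CONSEQUENCES = ConsequenceTable()


def is_functional(term: str, table: ConsequenceTable = DEFAULT_CONSEQUENCES) -> bool:
    """True iff *term* is one of the protein-altering consequence terms."""
    t = normalize_term(term)
    if t in table.terms:
        return True
    logger.debug("consequence term %r treated as non-functional", term)
    return False


def is_lof(term: str, table: ConsequenceTable = DEFAULT_CONSEQUENCES) -> bool:
    """True iff *term* is a protein-truncating / gene-ablating term."""
    return normalize_term(term) in table.lof_subset


def max_maf(per_population_afs: Mapping[str, float]) -> Optional[float]:
    """Aggregate per-population allele frequencies to a single MAF.

    The maximum across populations is used (a variant common in any one
    population is treated as common). Returns ``None`` when no frequency is
    available, which downstream filtering treats as rare.
    """
    for key, value in per_population_afs.items():
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"allele frequency {key}={value} outside [0, 1]")
    if not per_population_afs:
        return None
    return max(per_population_afs.values())


@dataclass(frozen=True)
class Genotype:
    """Alt-allele dosage for one sample at one decomposed site.

    ``ploidy`` is 1 only for hemizygous calls (X/Y in males).
    """

    alt_count: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if not 0 <= self.alt_count <= self.ploidy:
            raise ValueError(
                f"alt_allele_count {self.alt_count} exceeds ploidy {self.ploidy}"
            )

    @property
    def is_het(self) -> bool:
        return self.ploidy == 2 and self.alt_count == 1

    @property
    def is_hom_alt(self) -> bool:
        return self.ploidy == 2 and self.alt_count == 2

    @property
    def is_hemizygous_alt(self) -> bool:
        return self.ploidy == 1 and self.alt_count == 1

    @property
    def carries_alt(self) -> bool:
        return self.alt_count > 0

    def vcf_string(self) -> str:
        if self.ploidy == 1:
            return str(self.alt_count)
        return {0: "0/0", 1: "0/1", 2: "1/1"}[self.alt_count]


@dataclass
class VariantRecord:
    """One decomposed SNV/indel with trio genotypes and annotations."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene_symbols: frozenset[str] = frozenset()
    consequence: str = ""
    minor_allele_frequency: Optional[float] = None
    child_gt: Optional[Genotype] = None
    mother_gt: Optional[Genotype] = None
    father_gt: Optional[Genotype] = None
    pathogenicity_scores: dict[str, float] = field(default_factory=dict)
    in_known_pathogenic_db: bool = False

    def __post_init__(self) -> None:
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele must differ from ref allele")
        self.consequence = normalize_term(self.consequence) if self.consequence else ""
        if self.minor_allele_frequency is not None and not (
            0.0 <= self.minor_allele_frequency <= 1.0
        ):
            raise ValueError("minor_allele_frequency outside [0, 1]")

    @property
    def norm_chromosome(self) -> str:
        c = self.chromosome
        return c[3:] if c.lower().startswith("chr") else c

    @property
    def is_x(self) -> bool:
        return self.norm_chromosome.upper() == "X"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.norm_chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class VcfAnnotationConfig:
    """Which INFO keys carry the annotations the pipeline consumes."""

    gene_key: str = "GENE"
    consequence_key: str = "CQ"
    frequency_keys: tuple[str, ...] = ("AF", "AF_POPA", "AF_POPB")
    score_keys: tuple[str, ...] = ("SIFT", "PolyPhen")
    known_db_key: str = "KNOWN_PATH"


DEFAULT_VCF_CONFIG = VcfAnnotationConfig()


def _split_genes(raw: object) -> frozenset[str]:
    if raw is None:
        return frozenset()
    if isinstance(raw, (tuple, list)):
        raw = ",".join(str(x) for x in raw)
    text = str(raw)
    for sep in ("&", ";", "|"):
        text = text.replace(sep, ",")
    return frozenset(g for g in (p.strip() for p in text.split(",")) if g)


def _info_scalar(value: object, alt_index: int) -> object:
    """Pick the per-alt element from Number=A INFO tuples."""
    if isinstance(value, (tuple, list)):
        if alt_index < len(value):
            return value[alt_index]
        return value[0] if value else None
    return value


def _genotype_from_call(sample: "pysam.libcbcf.VariantRecordSample", alt_index: int) -> Optional[Genotype]:
    alleles = sample.get("GT")
    if alleles is None:
        return None
    observed = [a for a in alleles if a is not None]
    if not observed:
        return None
    ploidy = len(observed)
    if ploidy > 2:  # defensive: collapse polyploid calls to diploid dosage
        ploidy = 2
        observed = observed[:2]
    alt_count = sum(1 for a in observed if a == alt_index + 1)
    return Genotype(alt_count=alt_count, ploidy=ploidy)


def read_trio_vcf(
    path: str | Path,
    pedigree: TrioPedigree,
    config: VcfAnnotationConfig = DEFAULT_VCF_CONFIG,
) -> list[VariantRecord]:
    """Read a multi-sample VCF into decomposed :class:`VariantRecord` objects.

    One record is produced per (site, alt allele); multi-allelic sites are
    decomposed so that per-sample alt dosage is conserved. The proband sample
    must be present; parent samples listed in the pedigree must be present,
    while absent pedigree parents simply yield missing genotypes.

    Raises
    ------
    ValueError
        If a sample named in the pedigree is missing from the VCF.
    """
    path = str(path)
    missing_key_warned: set[str] = set()
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        wanted = {"child": pedigree.proband_id}
        if pedigree.mother_id:
            wanted["mother"] = pedigree.mother_id
        if pedigree.father_id:
            wanted["father"] = pedigree.father_id
        for role, sid in wanted.items():
            if sid not in samples:
                raise ValueError(f"{role} sample {sid!r} not present in {path}")
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                info = rec.info
                genes = _split_genes(info.get(config.gene_key)) if config.gene_key in info else frozenset()
                if config.gene_key not in info and config.gene_key not in missing_key_warned:
                    missing_key_warned.add(config.gene_key)
                    warnings.warn(f"annotation key {config.gene_key!r} absent in {path}")
                csq_raw = _info_scalar(info.get(config.consequence_key), ai) if config.consequence_key in info else None
                if config.consequence_key not in info and config.consequence_key not in missing_key_warned:
                    missing_key_warned.add(config.consequence_key)
                    warnings.warn(f"annotation key {config.consequence_key!r} absent in {path}")
                afs: dict[str, float] = {}
                for key in config.frequency_keys:
                    if key in info:
                        v = _info_scalar(info.get(key), ai)
                        if v is not None:
                            afs[key] = float(v)
                scores: dict[str, float] = {}
                for key in config.score_keys:
                    if key in info:
                        v = _info_scalar(info.get(key), ai)
                        if v is not None:
                            scores[key] = float(v)
                known = bool(info.get(config.known_db_key, False)) if config.known_db_key in info else False

                def gt_for(sid: Optional[str]) -> Optional[Genotype]:
                    if not sid or sid not in samples:
                        return None
                    return _genotype_from_call(rec.samples[sid], ai)

                records.append(
                    VariantRecord(
                        chromosome=rec.chrom,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        gene_symbols=genes,
                        consequence=str(csq_raw) if csq_raw is not None else "",
                        minor_allele_frequency=max_maf(afs),
                        child_gt=gt_for(pedigree.proband_id),
                        mother_gt=gt_for(pedigree.mother_id),
                        father_gt=gt_for(pedigree.father_id),
                        pathogenicity_scores=scores,
                        in_known_pathogenic_db=known,
                    )
                )
    return records
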