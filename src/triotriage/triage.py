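"""The automated variant-triage cascade for one proband.

Variants are filtered in a fixed order — population frequency, functional
consequence, panel-gene restriction, genotype/allelic-requirement matching
(including compound-heterozygote detection), then inheritance rules — and
each surviving candidate carries an ordered ``reason_trail`` of the rules it
passed, so any flag can be audited and replayed. The cascade is a pure
conjunction: the order fixes the trail and short-circuit cost, not the final
set.

Copy-number events run through a parallel path: losses are matched against
panel genes with a loss-of-function or dominant-negative mechanism when the
gene is *fully contained* in the event; gains against increased-gene-dosage
genes they merely overlap; and genic events in non-panel genes are flagged on
size alone (>100 kb losses and >250 kb gains when de novo or segregating with
disease, >500 kb when inheritance is unknown — all strict inequalities).

In trio mode, heterozygous candidates in dominant (monoallelic) genes are
kept only when de novo or inherited from an affected parent; homozygous
recessive candidates require both parents to carry the allele; inherited
missense variants on the X chromosome are excluded unless the family has a
history of the disorder or the variant is in a known-pathogenic database.
Without parental genotypes these rules fall back to proband-only semantics,
so the trio-mode flagged set is always a subset of the proband-only set for
families with unaffected parents.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .inheritance import INHERITED_MODES, classify_inheritance, segregates_with_disease
from .panel import PanelEntry, PanelVersion
from .pedigree import TrioPedigree
from .variants import (
    ConsequenceTable,
    DEFAULT_CONSEQUENCES,
    VariantRecord,
    is_functional,
)

logger = logging.getLogger(__name__)

CATEGORIES = (
    "autosomal_dominant",
    "autosomal_recessive_homozygous",
    "autosomal_recessive_compound_het",
    "x_linked_dominant",
    "x_linked_recessive",
    "cnv_panel",
    "cnv_size_rule",
)

CNV_LOSS_MECHANISMS = frozenset({"loss_of_function", "dominant_negative"})
CNV_GAIN_MECHANISM = "increased_gene_dosage"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and switches of the triage cascade."""

    maf_threshold: float = 0.01
    dominant_maf_threshold: Optional[float] = None  # stricter optional value, e.g. 0.001
    cnv_loss_min_bp: int = 100_000  # strict >
    cnv_gain_min_bp: int = 250_000  # strict >
    cnv_unknown_inheritance_min_bp: int = 500_000  # strict >
    apply_x_missense_exclusion: bool = True
    benign_missense_score_cutoff: Optional[float] = None  # disabled by default
    benign_missense_score_key: str = "PolyPhen"
    xld_requires_segregation: bool = True
    mode: str = "trio"  # "trio" | "proband_only"

    def __post_init__(self) -> None:
        if self.mode not in ("trio", "proband_only"):
            raise ValueError(f"mode must be trio/proband_only, got {self.mode!r}")
        for name in ("maf_threshold", "cnv_loss_min_bp", "cnv_gain_min_bp", "cnv_unknown_inheritance_min_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cnv_loss_min_bp > self.cnv_unknown_inheritance_min_bp:
            raise ValueError("loss threshold must not exceed unknown-inheritance threshold")

    @property
    def effective_dominant_maf(self) -> float:
        return self.dominant_maf_threshold if self.dominant_maf_threshold is not None else self.maf_threshold


CNV_TYPES = ("loss", "gain")
CNV_INHERITANCE = ("de_novo", "inherited_segregating", "inherited_non_segregating", "unknown")


@dataclass(frozen=True)
class CnvRecord:
    """One copy-number event with gene overlaps and inheritance status."""

    chromosome: str
    start: int  # 1-based closed interval
    end: int
    cnv_type: str
    inheritance_status: str = "unknown"
    overlapped_genes: frozenset[str] = frozenset()
    fully_contained_genes: frozenset[str] = frozenset()
    minor_allele_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CNV start must not exceed end")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}")
        if self.inheritance_status not in CNV_INHERITANCE:
            raise ValueError(f"unknown inheritance_status {self.inheritance_status!r}")
        if not self.fully_contained_genes <= self.overlapped_genes:
            raise ValueError("fully_contained_genes must be a subset of overlapped_genes")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


Payload = Union[VariantRecord, CnvRecord, tuple[VariantRecord, VariantRecord]]


@dataclass
class FlaggedCandidate:
    """A variant, CNV, or compound-het pair that survived the cascade."""

    proband_id: str
    payload: Payload
    category: str
    inheritance: Union[str, tuple[str, str]]
    reason_trail: list[str]
    matched_panel_entry: Optional[PanelEntry] = None
    phenotype_match_note: str = ""

    def __post_init__(self) -> None:
        if not self.reason_trail:
            raise ValueError("reason_trail must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if isinstance(self.payload, tuple):
            g1, g2 = (v.gene_symbols for v in self.payload)
            if not (g1 & g2):
                raise ValueError("compound-het pair must share a gene")

    @property
    def gene(self) -> str:
        if isinstance(self.payload, CnvRecord):
            if self.matched_panel_entry is not None:
                return self.matched_panel_entry.gene_symbol
            return ""
        if isinstance(self.payload, tuple):
            shared = self.payload[0].gene_symbols & self.payload[1].gene_symbols
            if self.matched_panel_entry is not None:
                return self.matched_panel_entry.gene_symbol
            return sorted(shared)[0]
        if self.matched_panel_entry is not None:
            return self.matched_panel_entry.gene_symbol
        return sorted(self.payload.gene_symbols)[0] if self.payload.gene_symbols else ""

    @property
    def chromosome(self) -> str:
        p = self.payload
        return p[0].chromosome if isinstance(p, tuple) else p.chromosome

    @property
    def positions(self) -> tuple[int, ...]:
        p = self.payload
        if isinstance(p, tuple):
            return tuple(sorted(v.position for v in p))
        if isinstance(p, CnvRecord):
            return (p.start, p.end)
        return (p.position,)

    @property
    def is_de_novo(self) -> bool:
        if isinstance(self.inheritance, tuple):
            return "de_novo" in self.inheritance
        return self.inheritance == "de_novo"

    @property
    def candidate_id(self) -> str:
        """Mode-independent identifier of the flagged event."""
        pos = ",".join(str(x) for x in self.positions)
        return f"{self.proband_id}|{self.category}|{self.chromosome}|{pos}|{self.gene}"


def _chrom_rank(chrom: str) -> int:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return int(c)
    return {"X": 23, "Y": 24, "MT": 25, "M": 25}.get(c.upper(), 26)


def frequency_filter(v: VariantRecord, cfg: FilterConfig, dominant_context: bool = False) -> bool:
    """Keep a variant iff its MAF is missing or at most the threshold.

    Missing frequency is treated as rare: novel variants dominate diagnoses.
    In a dominant-gene context an optional stricter threshold applies.
    """
    threshold = cfg.effective_dominant_maf if dominant_context else cfg.maf_threshold
    maf = v.minor_allele_frequency
    return maf is None or maf <= threshold


def genotype_matches_requirement(
    variants: Sequence[VariantRecord], entry: PanelEntry, p: TrioPedigree
) -> bool:
    """Whether the proband's genotypes in this gene can satisfy the entry.

    Monoallelic: any single het/hom-alt carrier variant. Biallelic: a hom-alt
    variant, or at least two hets (a compound-het candidate). X-linked
    recessive: hemizygous alt in males; hom-alt or two hets in females.
    X-linked dominant: any het/hemizygous carrier.
    """
    gts = [v.child_gt for v in variants if v.child_gt is not None]
    req = entry.allelic_requirement
    if req == "monoallelic" or req == "x_linked_dominant":
        return any(g.carries_alt for g in gts)
    if req == "biallelic":
        if any(g.is_hom_alt for g in gts):
            return True
        return sum(1 for g in gts if g.is_het) >= 2
    if req == "x_linked_recessive":
        if p.proband_sex == "male":
            return any(g.carries_alt for g in gts)
        if any(g.is_hom_alt for g in gts):
            return True
        return sum(1 for g in gts if g.is_het) >= 2
    return False


def _possible_origins(call: str) -> frozenset[str]:
    if call == "maternal":
        return frozenset({"M"})
    if call == "paternal":
        return frozenset({"P"})
    # de novo can sit on either copy; ambiguous/uninformative cannot be phased
    return frozenset({"M", "P"})


def find_compound_hets(
    variants: Sequence[VariantRecord],
    p: TrioPedigree,
    cfg: FilterConfig,
) -> list[tuple[VariantRecord, VariantRecord]]:
    """Het pairs in one gene consistent with a trans (two-copy) configuration.

    In trio mode a pair qualifies unless both members are unambiguously from
    the same parent (cis); a de novo member may pair with either inherited
    member. In proband-only mode (or without parental genotypes) all het
    pairs are candidates. Pairs are returned in deterministic position order.
    """
    hets = sorted(
        (v for v in variants if v.child_gt is not None and v.child_gt.is_het),
        key=lambda v: (v.position, v.alt_allele),
    )
    pairs: list[tuple[VariantRecord, VariantRecord]] = []
    if cfg.mode == "trio" and p.is_trio:
        calls = {}
        kept = []
        for v in hets:
            call = classify_inheritance(v, p)
            if call == "mendelian_error":
                continue
            calls[v.key] = call
            kept.append(v)
        for a, b in combinations(kept, 2):
            oa, ob = _possible_origins(calls[a.key]), _possible_origins(calls[b.key])
            if oa == ob and len(oa) == 1:  # unambiguously cis
                continue
            pairs.append((a, b))
    else:
        pairs = list(combinations(hets, 2))
    return pairs


def x_missense_exclusion(v: VariantRecord, call: str, p: TrioPedigree) -> bool:
    """True (exclude) for inherited X-chromosome missense variants.

    The exclusion is lifted when the family has a history of developmental
    disorders or the variant is present in a known-pathogenic database; de
    novo X missense variants are always retained.
    """
    return (
        v.is_x
        and v.consequence == "missense_variant"
        and call in INHERITED_MODES
        and not p.family_history
        and not v.in_known_pathogenic_db
    )


def cnv_panel_filter(c: CnvRecord, panel: PanelVersion) -> list[tuple[CnvRecord, PanelEntry]]:
    """Match one rare CNV against panel genes by mechanism and event type.

    Losses match loss-of-function / dominant-negative genes they fully
    contain; gains match increased-gene-dosage genes they overlap.
    """
    matches: list[tuple[CnvRecord, PanelEntry]] = []
    if c.cnv_type == "loss":
        genes, mechanisms = c.fully_contained_genes, CNV_LOSS_MECHANISMS
    else:
        genes, mechanisms = c.overlapped_genes, {CNV_GAIN_MECHANISM}
    for gene in sorted(genes):
        for entry in panel.entries:
            if entry.reportable and entry.gene_symbol == gene and entry.mutation_consequence in mechanisms:
                matches.append((c, entry))
    return matches


def cnv_size_filter(c: CnvRecord, cfg: FilterConfig) -> bool:
    """Size rule for rare genic CNVs outside the panel (strict inequalities)."""
    if c.inheritance_status in ("de_novo", "inherited_segregating"):
        if c.cnv_type == "loss":
            return c.length > cfg.cnv_loss_min_bp
        return c.length > cfg.cnv_gain_min_bp
    if c.inheritance_status == "unknown":
        return c.length > cfg.cnv_unknown_inheritance_min_bp
    return False  # inherited but not segregating: never flagged on size


def _phenotype_note(entry: PanelEntry, proband_terms: Optional[frozenset[str]]) -> str:
    if entry.required_phenotype_terms and not (entry.required_phenotype_terms & (proband_terms or frozenset())):
        return "phenotype-mismatch"
    return ""


def _benign_missense_excluded(v: VariantRecord, call: str, cfg: FilterConfig) -> bool:
    if cfg.benign_missense_score_cutoff is None:
        return False
    if v.consequence != "missense_variant" or call not in INHERITED_MODES:
        return False
    score = v.pathogenicity_scores.get(cfg.benign_missense_score_key)
    return score is not None and score < cfg.benign_missense_score_cutoff


class _SnvContext:
    """Shared state for the SNV/indel path of one proband's triage."""

    def __init__(self, ped: TrioPedigree, cfg: FilterConfig, diagnostics: Optional[list]):
        self.ped = ped
        self.cfg = cfg
        self.diagnostics = diagnostics if diagnostics is not None else []
        self.trio = cfg.mode == "trio" and ped.is_trio
        if cfg.mode == "trio" and not ped.is_trio:
            logger.info(
                "%s: trio mode requested without both parents; falling back to "
                "proband-only semantics for inheritance rules",
                ped.proband_id,
            )

    def classify(self, v: VariantRecord) -> str:
        if not self.trio:
            return "uninformative"
        return classify_inheritance(v, self.ped)

    def member_excluded(self, v: VariantRecord, call: str, trail: list[str]) -> bool:
        """Inheritance-dependent per-variant exclusions shared by all paths."""
        if self.cfg.apply_x_missense_exclusion and x_missense_exclusion(v, call, self.ped):
            self.diagnostics.append((v, "x_inherited_missense_excluded"))
            return True
        if _benign_missense_excluded(v, call, self.cfg):
            self.diagnostics.append((v, "benign_missense_score_excluded"))
            return True
        trail.append(f"inheritance:{call}")
        return False


def triage_proband(
    variants: Sequence[VariantRecord],
    cnvs: Sequence[CnvRecord],
    panel: PanelVersion,
    pedigree: TrioPedigree,
    cfg: FilterConfig = FilterConfig(),
    consequence_table: ConsequenceTable = DEFAULT_CONSEQUENCES,
    proband_phenotype_terms: Optional[frozenset[str]] = None,
    diagnostics: Optional[list] = None,
) -> list[FlaggedCandidate]:
    """Run the full cascade for one proband and return flagged candidates.

    ``diagnostics``, when given, collects ``(variant, reason)`` pairs for
    variants excluded by Mendelian-error or missense-exclusion rules so that
    genotyping artefacts remain auditable.
    """
    ctx = _SnvContext(pedigree, cfg, diagnostics)
    candidates: list[FlaggedCandidate] = []

    functional = [
        v
        for v in variants
        if v.child_gt is not None and v.child_gt.carries_alt and is_functional(v.consequence, consequence_table)
    ]
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in functional:
        for g in v.gene_symbols:
            by_gene.setdefault(g, []).append(v)

    panel_genes = panel.reportable_genes
    for gene in sorted(set(by_gene) & panel_genes):
        gene_vars = sorted(by_gene[gene], key=lambda v: (v.position, v.alt_allele))
        entries = sorted(
            (e for e in panel.entries_for_gene(gene) if e.reportable),
            key=lambda e: (e.allelic_requirement, e.mutation_consequence),
        )
        for entry in entries:
            kept = [v for v in gene_vars if frequency_filter(v, cfg, entry.is_dominant_context)]
            if not kept or not genotype_matches_requirement(kept, entry, pedigree):
                continue
            base_trail = [
                f"frequency<= {cfg.effective_dominant_maf if entry.is_dominant_context else cfg.maf_threshold:g}",
                "functional_consequence",
                f"panel_gene:{gene}",
                f"requirement:{entry.allelic_requirement}",
            ]
            note = _phenotype_note(entry, proband_phenotype_terms)
            req = entry.allelic_requirement
            if req in ("monoallelic", "x_linked_dominant"):
                candidates.extend(
                    _dominant_candidates(kept, entry, ctx, base_trail, note)
                )
            elif req == "biallelic":
                candidates.extend(
                    _recessive_candidates(kept, entry, ctx, base_trail, note)
                )
            elif req == "x_linked_recessive":
                candidates.extend(
                    _xlr_candidates(kept, entry, ctx, base_trail, note)
                )

    candidates.extend(_cnv_candidates(cnvs, panel, pedigree, cfg))
    candidates.sort(
        key=lambda c: (_chrom_rank(c.chromosome), c.positions, c.category, c.gene)
    )
    return candidates


def _dominant_candidates(kept, entry, ctx: _SnvContext, base_trail, note):
    cfg, ped = ctx.cfg, ctx.ped
    out = []
    category = "autosomal_dominant" if entry.allelic_requirement == "monoallelic" else "x_linked_dominant"
    requires_seg = entry.allelic_requirement == "monoallelic" or cfg.xld_requires_segregation
    for v in kept:
        if not v.child_gt.carries_alt:
            continue
        trail = list(base_trail)
        call = ctx.classify(v)
        if ctx.trio:
            if call == "mendelian_error":
                ctx.diagnostics.append((v, "mendelian_error"))
                continue
            if call == "uninformative":
                trail.append("inheritance:fallback_proband_only")
            else:
                if requires_seg and not segregates_with_disease(call, ped):
                    continue
                if ctx.member_excluded(v, call, trail):
                    continue
        else:
            trail.append("inheritance:not_applied")
        out.append(
            FlaggedCandidate(
                proband_id=ped.proband_id,
                payload=v,
                category=category,
                inheritance=call,
                reason_trail=trail,
                matched_panel_entry=entry,
                phenotype_match_note=note,
            )
        )
    return out


def _recessive_candidates(kept, entry, ctx: _SnvContext, base_trail, note):
    cfg, ped = ctx.cfg, ctx.ped
    out = []
    for v in kept:
        if not v.child_gt.is_hom_alt:
            continue
        trail = list(base_trail) + ["genotype:homozygous_alt"]
        call = ctx.classify(v)
        if ctx.trio:
            if call == "uninformative":
                trail.append("inheritance:fallback_proband_only")
            elif call != "biparental":
                # both parents must carry one alt each; anything else is a
                # transmission inconsistency for a homozygous child
                ctx.diagnostics.append((v, "mendelian_error"))
                continue
            else:
                if ctx.member_excluded(v, call, trail):
                    continue
        else:
            trail.append("inheritance:not_applied")
        out.append(
            FlaggedCandidate(
                proband_id=ped.proband_id,
                payload=v,
                category="autosomal_recessive_homozygous",
                inheritance=call,
                reason_trail=trail,
                matched_panel_entry=entry,
                phenotype_match_note=note,
            )
        )
    out.extend(
        _comphet_candidates(kept, entry, ctx, base_trail, note, "autosomal_recessive_compound_het")
    )
    return out


def _comphet_candidates(kept, entry, ctx: _SnvContext, base_trail, note, category):
    cfg, ped = ctx.cfg, ctx.ped
    hets = [v for v in kept if v.child_gt.is_het]
    if ctx.trio:
        filtered = []
        for v in hets:
            call = ctx.classify(v)
            probe_trail: list[str] = []
            if call != "mendelian_error" and not ctx.member_excluded(v, call, probe_trail):
                filtered.append(v)
        hets = filtered
    pairs = find_compound_hets(hets, ped, cfg)
    out = []
    for a, b in pairs:
        call_a = ctx.classify(a)
        call_b = ctx.classify(b)
        trail = list(base_trail) + [
            "genotype:compound_het_pair",
            f"inheritance:{call_a}+{call_b}" if ctx.trio else "inheritance:not_applied",
        ]
        out.append(
            FlaggedCandidate(
                proband_id=ped.proband_id,
                payload=(a, b),
                category=category,
                inheritance=(call_a, call_b),
                reason_trail=trail,
                matched_panel_entry=entry,
                phenotype_match_note=note,
            )
        )
    return out


def _xlr_candidates(kept, entry, ctx: _SnvContext, base_trail, note):
    cfg, ped = ctx.cfg, ctx.ped
    out = []
    if ped.proband_sex == "male":
        for v in kept:
            if not v.child_gt.carries_alt:
                continue
            trail = list(base_trail) + ["genotype:hemizygous_alt"]
            call = ctx.classify(v)
            if ctx.trio:
                if call == "mendelian_error":
                    ctx.diagnostics.append((v, "mendelian_error"))
                    continue
                if call == "uninformative":
                    trail.append("inheritance:fallback_proband_only")
                elif ctx.member_excluded(v, call, trail):
                    continue
            else:
                trail.append("inheritance:not_applied")
            out.append(
                FlaggedCandidate(
                    proband_id=ped.proband_id,
                    payload=v,
                    category="x_linked_recessive",
                    inheritance=call,
                    reason_trail=trail,
                    matched_panel_entry=entry,
                    phenotype_match_note=note,
                )
            )
        return out
    # female proband: homozygous-alt or compound het, as for recessive genes
    for v in kept:
        if not v.child_gt.is_hom_alt:
            continue
        trail = list(base_trail) + ["genotype:homozygous_alt"]
        call = ctx.classify(v)
        if ctx.trio:
            if call == "uninformative":
                trail.append("inheritance:fallback_proband_only")
            elif call != "biparental":
                ctx.diagnostics.append((v, "mendelian_error"))
                continue
            elif ctx.member_excluded(v, call, trail):
                continue
        else:
            trail.append("inheritance:not_applied")
        out.append(
            FlaggedCandidate(
                proband_id=ped.proband_id,
                payload=v,
                category="x_linked_recessive",
                inheritance=call,
                reason_trail=trail,
                matched_panel_entry=entry,
                phenotype_match_note=note,
            )
        )
    out.extend(_comphet_candidates(kept, entry, ctx, base_trail, note, "x_linked_recessive"))
    return out


def _cnv_candidates(cnvs, panel, pedigree, cfg):
    out = []
    for c in sorted(cnvs, key=lambda c: (_chrom_rank(c.chromosome), c.start, c.end)):
        if c.minor_allele_frequency is not None and c.minor_allele_frequency > cfg.maf_threshold:
            continue
        matches = cnv_panel_filter(c, panel)
        if matches:
            for cnv, entry in matches:
                out.append(
                    FlaggedCandidate(
                        proband_id=pedigree.proband_id,
                        payload=cnv,
                        category="cnv_panel",
                        inheritance=cnv.inheritance_status,
                        reason_trail=[
                            "frequency<=%g" % cfg.maf_threshold,
                            f"cnv_{cnv.cnv_type}_mechanism:{entry.mutation_consequence}",
                            f"panel_gene:{entry.gene_symbol}",
                        ],
                        matched_panel_entry=entry,
                    )
                )
        elif c.overlapped_genes and cnv_size_filter(c, cfg):
            out.append(
                FlaggedCandidate(
                    proband_id=pedigree.proband_id,
                    payload=c,
                    category="cnv_size_rule",
                    inheritance=c.inheritance_status,
                    reason_trail=[
                        "frequency<=%g" % cfg.maf_threshold,
                        "genic",
                        f"size_rule:{c.cnv_type}:{c.length}bp:{c.inheritance_status}",
                    ],
                )
            )
    return out


CNV_COLUMNS = (
    "proband_id",
    "chromosome",
    "start",
    "end",
    "cnv_type",
    "inheritance_status",
    "overlapped_genes",
    "fully_contained_genes",
    "minor_allele_frequency",
)


def read_cnv_table(path: str | Path) -> dict[str, list[CnvRecord]]:
    """Read a BED-like CNV TSV into per-proband record lists."""
    out: dict[str, list[CnvRecord]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            maf = row.get("minor_allele_frequency", "")
            out.setdefault(row["proband_id"], []).append(
                CnvRecord(
                    chromosome=row["chromosome"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    cnv_type=row["cnv_type"],
                    inheritance_status=row["inheritance_status"],
                    overlapped_genes=frozenset(g for g in row["overlapped_genes"].split(";") if g),
                    fully_contained_genes=frozenset(g for g in row["fully_contained_genes"].split(";") if g),
                    minor_allele_frequency=float(maf) if maf else None,
                )
            )
    return out


def write_cnv_table(cnvs_by_proband: dict[str, Sequence[CnvRecord]], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CNV_COLUMNS)
        for proband in sorted(cnvs_by_proband):
            for c in cnvs_by_proband[proband]:
                writer.writerow(
                    [
                        proband,
                        c.chromosome,
                        c.start,
                        c.end,
                        c.cnv_type,
                        c.inheritance_status,
                        ";".join(sorted(c.overlapped_genes)),
                        ";".join(sorted(c.fully_contained_genes)),
                        "" if c.minor_allele_frequency is None else repr(c.minor_allele_frequency),
                    ]
                )
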