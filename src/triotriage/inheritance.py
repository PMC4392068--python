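"""Inheritance classification from trio genotypes.

Given the child's and parents' alt-allele dosages at one decomposed site,
:func:`classify_inheritance` derives which parent (if either) transmitted the
alt allele, by reasoning over the set of (maternal gamete, paternal gamete)
pairs consistent with the parental genotypes. A child allele configuration
impossible under Mendelian transmission is a Mendelian error unless both
parents carry zero alt copies, in which case the variant is de novo. The
classifier is deterministic on the given genotypes: genotype quality and
error posteriors are not modelled (putative de novo calls are validated
externally in practice).

On the X chromosome a male proband is hemizygous: the father's genotype is
ignored for transmission, and the alt is maternal if the mother carries it,
de novo otherwise. Pseudoautosomal regions may be declared via an interval
table, in which case they are treated as autosomal.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .pedigree import TrioPedigree
from .variants import Genotype, VariantRecord

MODES = (
    "de_novo",
    "maternal",
    "paternal",
    "biparental",
    "inherited_ambiguous",
    "uninformative",
    "mendelian_error",
)

#: Inheritance modes compatible with the alt having come from the mother /
#: father / neither (used for compound-het trans-phase reasoning).
INHERITED_MODES = frozenset({"maternal", "paternal", "biparental", "inherited_ambiguous"})


def _gametes(gt: Genotype) -> set[int]:
    """Possible transmitted alt-allele counts (0 or 1) from one parent."""
    if gt.ploidy == 1:
        return {gt.alt_count}
    return {0: {0}, 1: {0, 1}, 2: {1}}[gt.alt_count]


def _in_par(chrom: str, pos: int, par_regions: Optional[Sequence[tuple[str, int, int]]]) -> bool:
    if not par_regions:
        return False
    norm = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return any(
        (c[3:] if c.lower().startswith("chr") else c).upper() == norm.upper() and s <= pos <= e
        for c, s, e in par_regions
    )


def classify_inheritance(
    v: VariantRecord,
    p: TrioPedigree,
    par_regions: Optional[Sequence[tuple[str, int, int]]] = None,
) -> str:
    """Classify one variant's inheritance mode from the trio genotypes.

    Returns one of :data:`MODES`. The child genotype must be present.
    """
    child = v.child_gt
    if child is None:
        raise ValueError("child genotype required for inheritance classification")

    hemizygous_male = (
        v.is_x and p.proband_sex == "male" and not _in_par(v.chromosome, v.position, par_regions)
    )

    if hemizygous_male:
        # Father's genotype is irrelevant to X transmission in males.
        if not child.carries_alt:
            return "uninformative"
        if v.mother_gt is None:
            return "uninformative"
        return "maternal" if v.mother_gt.carries_alt else "de_novo"

    if v.mother_gt is None or v.father_gt is None:
        return "uninformative"
    if not child.carries_alt:
        return "uninformative"

    c = child.alt_count if child.ploidy == 2 else child.alt_count  # dosage
    maternal_gametes = _gametes(v.mother_gt)
    paternal_gametes = _gametes(v.father_gt)
    pairs = [
        (gm, gf)
        for gm in maternal_gametes
        for gf in paternal_gametes
        if gm + gf == c
    ]
    if not pairs:
        if v.mother_gt.alt_count == 0 and v.father_gt.alt_count == 0:
            return "de_novo"
        return "mendelian_error"
    if c >= 2:
        return "biparental"
    origins = {("maternal" if gm else "paternal") for gm, gf in pairs}
    if origins == {"maternal"}:
        return "maternal"
    if origins == {"paternal"}:
        return "paternal"
    return "inherited_ambiguous"


def segregates_with_disease(call: str, p: TrioPedigree) -> bool:
    """Whether a variant with this inheritance call tracks the child's disease.

    De novo variants always do; inherited variants only when a (possible)
    transmitting parent is affected. Uninformative calls and Mendelian errors
    never segregate.
    """
    mother = bool(p.mother_affected)
    father = bool(p.father_affected)
    if call == "de_novo":
        return True
    if call == "maternal":
        return mother
    if call == "paternal":
        return father
    if call in ("biparental", "inherited_ambiguous"):
        return mother or father
    return False
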