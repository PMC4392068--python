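"""Genotype-to-phenotype gene panel: data model, TSV reader/writer, diffs.

The panel emulates a curated developmental-disorder gene database in which
each gene entry carries an *allelic requirement* (how many mutated alleles
are needed: monoallelic/dominant, biallelic/recessive, or an X-linked form)
and a *mutation consequence* (the mechanism by which variants in the gene
cause disease, e.g. loss of function or increased gene dosage). A gene may
appear under several (requirement, consequence) pairs. Only entries marked
reportable take part in triage; entries with insufficient evidence are kept
in the data model but never matched.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

ALLELIC_REQUIREMENTS = (
    "monoallelic",
    "biallelic",
    "x_linked_dominant",
    "x_linked_recessive",
)

MUTATION_CONSEQUENCES = (
    "loss_of_function",
    "dominant_negative",
    "activating",
    "increased_gene_dosage",
    "all_missense_or_in_frame",
    "uncertain",
)

# Common synonyms found in published panel exports.
_REQUIREMENT_ALIASES = {
    "autosomal_dominant": "monoallelic",
    "autosomal_recessive": "biallelic",
}

PANEL_COLUMNS = (
    "gene_symbol",
    "chromosome",
    "gene_interval",
    "allelic_requirement",
    "mutation_consequence",
    "reportable",
    "required_phenotype_terms",
    "notes",
)


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel content."""


def _norm_token(token: str) -> str:
    return token.strip().lower().replace("-", "_").replace(" ", "_")


@dataclass(frozen=True)
class PanelEntry:
    """One gene × mechanism record of the panel."""

    gene_symbol: str
    chromosome: str
    allelic_requirement: str
    mutation_consequence: str
    reportable: bool = True
    gene_interval: Optional[tuple[int, int]] = None  # 1-based closed
    required_phenotype_terms: frozenset[str] = frozenset()
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise PanelError("gene_symbol must be non-empty")
        if self.allelic_requirement not in ALLELIC_REQUIREMENTS:
            raise PanelError(
                f"unknown allelic_requirement token {self.allelic_requirement!r}"
            )
        if self.mutation_consequence not in MUTATION_CONSEQUENCES:
            raise PanelError(
                f"unknown mutation_consequence token {self.mutation_consequence!r}"
            )
        if self.allelic_requirement.startswith("x_linked") and self.norm_chromosome.upper() != "X":
            raise PanelError(
                f"{self.gene_symbol}: {self.allelic_requirement} requires chromosome X, "
                f"got {self.chromosome!r}"
            )
        if self.gene_interval is not None:
            start, end = self.gene_interval
            if start > end or start < 1:
                raise PanelError(f"{self.gene_symbol}: invalid gene_interval {self.gene_interval}")

    @property
    def norm_chromosome(self) -> str:
        c = self.chromosome
        return c[3:] if c.lower().startswith("chr") else c

    @property
    def is_dominant_context(self) -> bool:
        """Entries a stricter dominant-variant frequency threshold applies to."""
        return self.allelic_requirement in ("monoallelic", "x_linked_dominant")


@dataclass
class PanelVersion:
    """One dated release of the gene panel."""

    label: str
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for e in self.entries:
            triple = (e.gene_symbol, e.allelic_requirement, e.mutation_consequence)
            if triple in seen:
                raise PanelError(f"duplicate panel entry {triple}")
            seen.add(triple)

    @property
    def reportable_genes(self) -> set[str]:
        return {e.gene_symbol for e in self.entries if e.reportable}

    @property
    def reportable_gene_count(self) -> int:
        return len(self.reportable_genes)

    def entries_for_gene(self, gene: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.gene_symbol == gene]


def reportable_entries_for_gene(panel: PanelVersion, gene: str) -> list[PanelEntry]:
    """All reportable entries for *gene* (empty when absent or non-reportable)."""
    return [e for e in panel.entries if e.gene_symbol == gene and e.reportable]


def diff_panels(old: PanelVersion, new: PanelVersion) -> tuple[set[str], set[str]]:
    """Reportable genes added and removed between two panel versions."""
    old_genes = old.reportable_genes
    new_genes = new.reportable_genes
    return new_genes - old_genes, old_genes - new_genes


def _parse_bool(raw: str, row: int) -> bool:
    t = raw.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise PanelError(f"row {row}: cannot parse boolean {raw!r}")


def _parse_interval(raw: str, row: int) -> Optional[tuple[int, int]]:
    raw = raw.strip()
    if not raw:
        return None
    try:
        start_s, end_s = raw.split("-", 1)
        return int(start_s), int(end_s)
    except ValueError as exc:
        raise PanelError(f"row {row}: cannot parse gene_interval {raw!r}") from exc


def load_panel(path: str | Path, label: Optional[str] = None) -> PanelVersion:
    """Load and validate a panel TSV.

    Raises :class:`PanelError` with a row number for malformed rows, unknown
    enumeration tokens, or duplicate (gene, requirement, consequence) triples.
    """
    path = Path(path)
    entries: list[PanelEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(PANEL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise PanelError(f"panel header missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                requirement = _norm_token(row["allelic_requirement"])
                requirement = _REQUIREMENT_ALIASES.get(requirement, requirement)
                consequence = _norm_token(row["mutation_consequence"])
                terms = frozenset(
                    t.strip()
                    for t in (row.get("required_phenotype_terms") or "").split(";")
                    if t.strip()
                )
                entries.append(
                    PanelEntry(
                        gene_symbol=row["gene_symbol"].strip(),
                        chromosome=row["chromosome"].strip(),
                        gene_interval=_parse_interval(row.get("gene_interval") or "", i),
                        allelic_requirement=requirement,
                        mutation_consequence=consequence,
                        reportable=_parse_bool(row["reportable"], i),
                        required_phenotype_terms=terms,
                        notes=(row.get("notes") or "").strip(),
                    )
                )
            except PanelError as exc:
                raise PanelError(f"{path.name} row {i}: {exc}") from exc
    return PanelVersion(label=label or path.stem, entries=entries)


def write_panel(panel: PanelVersion, path: str | Path) -> None:
    """Serialise a panel to the TSV form :func:`load_panel` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PANEL_COLUMNS)
        for e in panel.entries:
            interval = f"{e.gene_interval[0]}-{e.gene_interval[1]}" if e.gene_interval else ""
            writer.writerow(
                [
                    e.gene_symbol,
                    e.chromosome,
                    interval,
                    e.allelic_requirement,
                    e.mutation_consequence,
                    "true" if e.reportable else "false",
                    ";".join(sorted(e.required_phenotype_terms)),
                    e.notes,
                ]
            )
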