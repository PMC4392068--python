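"""Per-candidate reporting records and cohort-level summary bookkeeping.

Two summary shapes are produced. The *flag table* counts flagged SNVs and
indels per genetic mechanism (autosomal dominant, autosomal recessive
homozygous / compound heterozygous, X-linked dominant / recessive), split
into inherited and de novo columns in trio mode or a single column in
proband-only mode; compound-heterozygote events are counted once per gene
per proband. The *review summary* combines flagged candidates with the
outcome of expert review into predictive values (share of flagged variants
judged likely diagnostic) and diagnostic yields (share of the cohort
diagnosed by each variant class).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .triage import CnvRecord, FlaggedCandidate

SNV_CATEGORIES = (
    "autosomal_dominant",
    "autosomal_recessive_homozygous",
    "autosomal_recessive_compound_het",
    "x_linked_dominant",
    "x_linked_recessive",
)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def predictive_value(reviewed: int, reported: int) -> Optional[int]:
    """Percentage of reviewed flags judged likely diagnostic (nearest integer).

    Returns ``None`` (rendered ``".."``) when nothing was reviewed.
    """
    if reported > reviewed:
        raise ValueError("reported count cannot exceed reviewed count")
    if reviewed == 0:
        return None
    return _round_half_up(100.0 * reported / reviewed)


def diagnostic_yield(diagnosed_count: int, cohort_size: int) -> float:
    """Percentage of the cohort diagnosed by a variant class.

    Rounded to the nearest integer percent; classes contributing under 1%
    are rendered with one decimal so small contributions stay visible.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if diagnosed_count > cohort_size:
        raise ValueError("diagnosed_count cannot exceed cohort_size")
    pct = 100.0 * diagnosed_count / cohort_size
    if pct < 1.0:
        return round(pct, 1)
    return float(_round_half_up(pct))


def render_percent(value: Optional[Union[int, float]]) -> str:
    if value is None:
        return ".."
    if isinstance(value, float) and not value.is_integer():
        return f"{value:.1f}%"
    return f"{int(value)}%"


@dataclass
class _EventView:
    """Mode-independent view of one flagged event for counting."""

    proband_id: str
    category: str
    de_novo: bool
    gene: str


def _event_views(obj, mode: str) -> list[_EventView]:
    if isinstance(obj, pd.DataFrame):
        views = [
            _EventView(
                proband_id=str(r.proband_id),
                category=str(r.category),
                de_novo=("de_novo" in str(r.inheritance)),
                gene=str(getattr(r, "gene", "")),
            )
            for r in obj.itertuples()
        ]
    else:
        views = []
        for proband, cands in obj.items():
            for c in cands:
                views.append(
                    _EventView(
                        proband_id=proband,
                        category=c.category,
                        de_novo=c.is_de_novo,
                        gene=c.gene,
                    )
                )
    # compound hets: one event per (proband, gene)
    out: list[_EventView] = []
    seen_comphet: set[tuple[str, str, str]] = set()
    for v in views:
        if v.category.endswith("compound_het"):
            key = (v.proband_id, v.category, v.gene)
            if key in seen_comphet:
                continue
            seen_comphet.add(key)
        out.append(v)
    return out


def summarize_flags(
    candidates: Union[Mapping[str, Sequence[FlaggedCandidate]], pd.DataFrame],
    mode: str = "trio",
) -> pd.DataFrame:
    """Count flagged SNV/indel events per mechanism category.

    Accepts either a mapping ``proband_id -> candidates`` or a candidate
    table with ``proband_id``, ``category``, ``inheritance`` (and ``gene``)
    columns. Returns a frame indexed by category plus a ``Total`` row, with
    ``inherited``/``de_novo`` columns in trio mode and a single ``flagged``
    column in proband-only mode. CNV categories are excluded (the flag table
    covers sequence variants).
    """
    views = [v for v in _event_views(candidates, mode) if v.category in SNV_CATEGORIES]
    if mode == "trio":
        frame = pd.DataFrame(0, index=list(SNV_CATEGORIES), columns=["inherited", "de_novo"])
        for v in views:
            frame.loc[v.category, "de_novo" if v.de_novo else "inherited"] += 1
    else:
        frame = pd.DataFrame(0, index=list(SNV_CATEGORIES), columns=["flagged"])
        for v in views:
            frame.loc[v.category, "flagged"] += 1
    frame.loc["Total"] = frame.sum(axis=0)
    return frame


@dataclass(frozen=True)
class ReviewOutcome:
    """Decision of the (out-of-scope) expert review for one candidate."""

    candidate_id: str
    decision: str = "not_reported"  # "reported" | "not_reported"
    reviewer_note: str = ""

    def __post_init__(self) -> None:
        if self.decision not in ("reported", "not_reported"):
            raise ValueError(f"decision must be reported/not_reported, got {self.decision!r}")


def read_review_outcomes(path: str | Path) -> dict[str, ReviewOutcome]:
    out: dict[str, ReviewOutcome] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            o = ReviewOutcome(row["candidate_id"], row["decision"], row.get("reviewer_note", ""))
            out[o.candidate_id] = o
    return out


def write_review_outcomes(outcomes: Iterable[ReviewOutcome], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["candidate_id", "decision", "reviewer_note"])
        for o in outcomes:
            writer.writerow([o.candidate_id, o.decision, o.reviewer_note])


@dataclass
class SummaryRow:
    """One review-summary row: a variant class with its review bookkeeping."""

    label: str
    reviewed: int
    reported: int
    de_novo: bool = False

    def __post_init__(self) -> None:
        if self.reported > self.reviewed and self.reviewed > 0:
            raise ValueError(f"{self.label}: reported {self.reported} > reviewed {self.reviewed}")


@dataclass
class CohortSummary:
    """Cohort-level review summary with derived predictive values and yields.

    ``extra_events`` carries diagnosis classes found outside the automated
    SNV/indel/CNV cascade (e.g. uniparental disomy, mosaic rearrangements)
    so that whole-cohort totals close; they have no reviewed count.
    """

    rows: list[SummaryRow]
    cohort_size: int
    diagnosed_probands: int
    two_finding_probands: int = 0
    extra_events: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosed_probands > self.cohort_size:
            raise ValueError("diagnosed_probands cannot exceed cohort_size")

    @property
    def total_reviewed(self) -> int:
        return sum(r.reviewed for r in self.rows)

    @property
    def total_reported(self) -> int:
        """All reported findings, including the extra (chromosomal) events."""
        return sum(r.reported for r in self.rows) + sum(self.extra_events.values())

    @property
    def reported_variant_total(self) -> int:
        """Reported SNV/indel/CNV findings from the automated cascade."""
        return sum(r.reported for r in self.rows)

    @property
    def de_novo_diagnosis_total(self) -> int:
        return sum(r.reported for r in self.rows if r.de_novo)

    @property
    def overall_predictive_value(self) -> Optional[int]:
        return predictive_value(self.total_reviewed, self.total_reported)

    @property
    def overall_diagnostic_yield(self) -> float:
        return diagnostic_yield(self.diagnosed_probands, self.cohort_size)

    def row(self, label: str) -> SummaryRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def row_predictive_value(self, label: str) -> Optional[int]:
        r = self.row(label)
        return predictive_value(r.reviewed, r.reported)

    def row_diagnostic_yield(self, label: str) -> float:
        r = self.row(label)
        return diagnostic_yield(r.reported, self.cohort_size)

    def extra_event_yield(self, label: str) -> float:
        return diagnostic_yield(self.extra_events[label], self.cohort_size)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append(
                {
                    "class": r.label,
                    "reviewed": r.reviewed,
                    "reported": r.reported,
                    "predictive_value": render_percent(predictive_value(r.reviewed, r.reported)),
                    "diagnostic_yield": render_percent(diagnostic_yield(r.reported, self.cohort_size)),
                }
            )
        for label, n in self.extra_events.items():
            records.append(
                {
                    "class": label,
                    "reviewed": "..",
                    "reported": n,
                    "predictive_value": "..",
                    "diagnostic_yield": render_percent(diagnostic_yield(n, self.cohort_size)),
                }
            )
        records.append(
            {
                "class": "Total",
                "reviewed": self.total_reviewed,
                "reported": self.total_reported,
                "predictive_value": render_percent(self.overall_predictive_value),
                "diagnostic_yield": render_percent(self.overall_diagnostic_yield),
            }
        )
        return pd.DataFrame.from_records(records)


_CLASS_OF_CATEGORY = {
    "autosomal_dominant": "autosomal_dominant",
    "autosomal_recessive_homozygous": "autosomal_recessive",
    "autosomal_recessive_compound_het": "autosomal_recessive",
    "x_linked_dominant": "x_linked",
    "x_linked_recessive": "x_linked",
    "cnv_panel": "uncertain_inheritance",
    "cnv_size_rule": "uncertain_inheritance",
}


def build_cohort_summary(
    candidates_by_proband: Mapping[str, Sequence[FlaggedCandidate]],
    outcomes: Mapping[str, ReviewOutcome],
    cohort_size: int,
    extra_events: Optional[dict[str, int]] = None,
    extra_event_probands: int = 0,
) -> CohortSummary:
    """Aggregate flagged candidates and review outcomes into a cohort summary.

    Candidates are grouped into (class × de novo/inherited) rows; a proband
    is diagnosed when at least one of its candidates (or extra events,
    counted via ``extra_event_probands``) was reported.
    """
    table: dict[tuple[str, bool], list[int]] = {}
    reported_per_proband: dict[str, int] = {}
    for proband, cands in candidates_by_proband.items():
        seen_comphet: set[tuple[str, str]] = set()
        for c in cands:
            if c.category.endswith("compound_het"):
                key = (c.category, c.gene)
                if key in seen_comphet:
                    continue
                seen_comphet.add(key)
            cls = _CLASS_OF_CATEGORY[c.category]
            dn = c.is_de_novo if cls != "uncertain_inheritance" else False
            cell = table.setdefault((cls, dn), [0, 0])
            cell[0] += 1
            outcome = outcomes.get(c.candidate_id)
            if outcome is not None and outcome.decision == "reported":
                cell[1] += 1
                reported_per_proband[proband] = reported_per_proband.get(proband, 0) + 1
    rows = []
    for (cls, dn), (reviewed, reported) in sorted(table.items()):
        label = f"{cls}_{'de_novo' if dn else 'inherited'}" if cls != "uncertain_inheritance" else cls
        rows.append(SummaryRow(label=label, reviewed=reviewed, reported=reported, de_novo=dn))
    diagnosed = len(reported_per_proband) + extra_event_probands
    two_finding = sum(1 for n in reported_per_proband.values() if n >= 2)
    return CohortSummary(
        rows=rows,
        cohort_size=cohort_size,
        diagnosed_probands=diagnosed,
        two_finding_probands=two_finding,
        extra_events=extra_events or {},
    )


REPORT_COLUMNS = (
    "proband_id",
    "event_id",
    "chromosome",
    "position",
    "gene_symbols",
    "allele",
    "genotype",
    "inheritance",
    "most_severe_consequence",
    "category",
    "phenotype_match_note",
)


def _candidate_rows(c: FlaggedCandidate) -> list[list[str]]:
    event_id = c.candidate_id
    payload = c.payload
    if isinstance(payload, CnvRecord):
        return [
            [
                c.proband_id,
                event_id,
                payload.chromosome,
                str(payload.start),
                ";".join(sorted(payload.overlapped_genes)),
                payload.cnv_type,
                payload.cnv_type,
                str(c.inheritance),
                "",
                c.category,
                c.phenotype_match_note,
            ]
        ]
    members = payload if isinstance(payload, tuple) else (payload,)
    calls = c.inheritance if isinstance(c.inheritance, tuple) else (c.inheritance,) * len(members)
    rows = []
    for v, call in zip(members, calls):
        rows.append(
            [
                c.proband_id,
                event_id,
                v.chromosome,
                str(v.position),
                ";".join(sorted(v.gene_symbols)),
                f"{v.ref_allele}/{v.alt_allele}",
                v.child_gt.vcf_string() if v.child_gt else "",
                call,
                v.consequence,
                c.category,
                c.phenotype_match_note,
            ]
        )
    return rows


def write_report_records(
    candidates: Sequence[FlaggedCandidate],
    outcomes: Mapping[str, ReviewOutcome],
    path: str | Path,
) -> int:
    """Write one TSV row per reported candidate member, in deterministic order.

    Compound-het events produce two rows sharing the event identifier (both
    members must be validated together). Returns the number of rows written.
    """
    rows: list[list[str]] = []
    for c in candidates:
        outcome = outcomes.get(c.candidate_id)
        if outcome is None or outcome.decision != "reported":
            continue
        rows.extend(_candidate_rows(c))
    rows.sort(key=lambda r: (r[0], r[2], int(r[3]) if r[3].isdigit() else 0, r[1]))
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        writer.writerows(rows)
    return len(rows)


@dataclass(frozen=True)
class _RowCandidate:
    """Duck-typed stand-in for a FlaggedCandidate parsed back from a TSV."""

    proband_id: str
    candidate_id: str
    category: str
    gene: str
    inheritance: str

    @property
    def is_de_novo(self) -> bool:
        return "de_novo" in self.inheritance


def candidates_from_frame(frame: pd.DataFrame) -> dict[str, list[_RowCandidate]]:
    """Rebuild per-proband candidate stubs from a written candidate table."""
    out: dict[str, list[_RowCandidate]] = {}
    for r in frame.itertuples():
        c = _RowCandidate(
            proband_id=str(r.proband_id),
            candidate_id=str(r.candidate_id),
            category=str(r.category),
            gene=str(r.gene),
            inheritance=str(r.inheritance),
        )
        out.setdefault(c.proband_id, []).append(c)
    return out


def candidates_to_frame(candidates_by_proband: Mapping[str, Sequence[FlaggedCandidate]]) -> pd.DataFrame:
    """Flatten candidates into the table written by the CLI (one row/event)."""
    records = []
    for proband in sorted(candidates_by_proband):
        for c in candidates_by_proband[proband]:
            records.append(
                {
                    "proband_id": proband,
                    "candidate_id": c.candidate_id,
                    "category": c.category,
                    "chromosome": c.chromosome,
                    "positions": ",".join(str(p) for p in c.positions),
                    "gene": c.gene,
                    "inheritance": "+".join(c.inheritance) if isinstance(c.inheritance, tuple) else c.inheritance,
                    "phenotype_match_note": c.phenotype_match_note,
                    "reason_trail": " > ".join(c.reason_trail),
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "proband_id",
            "candidate_id",
            "category",
            "chromosome",
            "positions",
            "gene",
            "inheritance",
            "phenotype_match_note",
            "reason_trail",
        ],
    )
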