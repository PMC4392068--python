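"""PED parsing and the trio data model.

A :class:`TrioPedigree` is one proband with optional parents, proband sex,
parental affected status and a family-history flag. The family-history flag
(needed by the X-linked inherited-missense exclusion) is not expressible in
standard 6-column PED, so it is supplied via a sidecar table.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrioPedigree:
    proband_id: str
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    proband_sex: str = "female"  # "male" | "female"
    mother_affected: Optional[bool] = None
    father_affected: Optional[bool] = None
    family_history: bool = False
    family_id: str = ""

    def __post_init__(self) -> None:
        if self.proband_sex not in ("male", "female"):
            raise ValueError(f"proband_sex must be male/female, got {self.proband_sex!r}")
        if self.proband_id in (self.mother_id, self.father_id):
            raise ValueError(f"proband {self.proband_id!r} listed as its own parent")

    @property
    def has_parents(self) -> bool:
        return self.mother_id is not None or self.father_id is not None

    @property
    def is_trio(self) -> bool:
        return self.mother_id is not None and self.father_id is not None


def n_affected_parents(p: TrioPedigree) -> int:
    """Number of parents flagged affected (missing parents count unaffected)."""
    count = 0
    for parent_id, affected in ((p.mother_id, p.mother_affected), (p.father_id, p.father_affected)):
        if parent_id is None:
            logger.debug("%s: parent missing, counted unaffected", p.proband_id)
            continue
        if affected:
            count += 1
    return count


_SEX_CODES = {"1": "male", "2": "female", "0": None}


def read_ped(path: str | Path) -> list[TrioPedigree]:
    """Parse a 6-column PED file into trios.

    Probands are the individuals never referenced as a parent; their parent
    IDs must either be ``0`` or resolve to lines in the same file. Affected
    status uses the standard coding (2 affected, 1 unaffected, 0 missing,
    treated as unaffected).
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    parents_of: dict[str, tuple[str, str]] = {}
    referenced_as_parent: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path.name} line {lineno}: expected 6 PED columns")
            fam, iid, fid, mid, sex, pheno = fields[:6]
            if sex not in _SEX_CODES:
                raise ValueError(f"{path.name} line {lineno}: bad sex code {sex!r}")
            if iid in (fid, mid) and iid != "0":
                raise ValueError(f"{path.name} line {lineno}: {iid} is its own parent")
            rows[iid] = {
                "family": fam,
                "sex": _SEX_CODES[sex],
                "affected": pheno == "2",
                "father": None if fid == "0" else fid,
                "mother": None if mid == "0" else mid,
            }
            parents_of[iid] = (fid, mid)
            for pid in (fid, mid):
                if pid != "0":
                    referenced_as_parent.add(pid)

    # Cycle check: nobody may be their own ancestor.
    for iid in rows:
        seen = {iid}
        frontier = [p for p in parents_of.get(iid, ()) if p != "0"]
        while frontier:
            cur = frontier.pop()
            if cur in seen:
                raise ValueError(f"{path.name}: circular parentage involving {cur!r}")
            seen.add(cur)
            frontier.extend(p for p in parents_of.get(cur, ()) if p != "0")

    trios: list[TrioPedigree] = []
    for iid, row in rows.items():
        if iid in referenced_as_parent:
            continue
        if row["sex"] is None:
            raise ValueError(f"{path.name}: proband {iid!r} has unknown sex; sex is required")
        mother = row["mother"]
        father = row["father"]
        trios.append(
            TrioPedigree(
                proband_id=iid,
                mother_id=mother,
                father_id=father,
                proband_sex=row["sex"],
                mother_affected=rows[mother]["affected"] if mother and mother in rows else (None if mother is None else False),
                father_affected=rows[father]["affected"] if father and father in rows else (None if father is None else False),
                family_id=row["family"],
            )
        )
    return trios


def read_family_history(path: str | Path) -> dict[str, bool]:
    """Read the ``proband_id<TAB>family_history`` sidecar table."""
    out: dict[str, bool] = {}
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "proband_id":
                continue
            out[row[0]] = row[1].strip().lower() in ("true", "1", "yes")
    return out


def apply_family_history(trios: list[TrioPedigree], history: dict[str, bool]) -> list[TrioPedigree]:
    return [replace(t, family_history=history.get(t.proband_id, t.family_history)) for t in trios]
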