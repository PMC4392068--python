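"""Cohort-level wiring: run the triage cascade over a directory of trio VCFs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .panel import PanelVersion, load_panel
from .pedigree import apply_family_history, read_family_history, read_ped
from .triage import FilterConfig, FlaggedCandidate, read_cnv_table, triage_proband
from .variants import DEFAULT_VCF_CONFIG, VcfAnnotationConfig, read_trio_vcf


def triage_cohort(
    vcf_dir: str | Path,
    ped_path: str | Path,
    panel_path: str | Path,
    cnv_path: Optional[str | Path] = None,
    family_history_path: Optional[str | Path] = None,
    cfg: FilterConfig = FilterConfig(),
    vcf_config: VcfAnnotationConfig = DEFAULT_VCF_CONFIG,
    diagnostics: Optional[list] = None,
) -> dict[str, list[FlaggedCandidate]]:
    """Triage every proband in the pedigree; VCFs are ``<proband_id>.vcf``.

    Returns a mapping ``proband_id -> flagged candidates``. Raises
    ``FileNotFoundError`` naming the missing file when an input is absent.
    """
    vcf_dir = Path(vcf_dir)
    trios = read_ped(ped_path)
    if family_history_path is not None:
        trios = apply_family_history(trios, read_family_history(family_history_path))
    panel = load_panel(panel_path)
    cnvs_by_proband = read_cnv_table(cnv_path) if cnv_path is not None else {}
    out: dict[str, list[FlaggedCandidate]] = {}
    for t in trios:
        vcf_path = vcf_dir / f"{t.proband_id}.vcf"
        if not vcf_path.exists():
            raise FileNotFoundError(f"trio VCF not found: {vcf_path}")
        variants = read_trio_vcf(vcf_path, t, vcf_config)
        out[t.proband_id] = triage_proband(
            variants,
            cnvs_by_proband.get(t.proband_id, ()),
            panel,
            t,
            cfg,
            diagnostics=diagnostics,
        )
    return out
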