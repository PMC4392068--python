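"""Seeded synthetic trio-cohort generator and bookkeeping fixtures.

The generator emulates the statistical structure of a large trio-exome
developmental-disorder cohort: each proband carries on average 400 rare
protein-altering variants of which ~30 fall in known panel genes, ~11% of
children have one affected parent and ~2% have two, males are hemizygous on
X, and all genotypes respect Mendelian transmission except deliberately
spiked de novo events. Spike-ins with known expected triage outcomes (both
positive and negative controls) make the whole cascade testable offline, and
a truth table records every spike's expected flag decision in trio and
proband-only modes.

The module also provides *bookkeeping fixtures*: synthetic candidate/outcome
sets whose class counts equal the published summary tables of a 1133-trio
study, used to exercise the report module's predictive-value and
diagnostic-yield arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .panel import PanelEntry, PanelVersion, write_panel
from .pedigree import TrioPedigree
from .report import ReviewOutcome
from .triage import CnvRecord, FlaggedCandidate, write_cnv_table
from .variants import FUNCTIONAL_TERMS, Genotype, LOF_TERMS, VariantRecord

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMS = AUTOSOMES + ("X",)

_GENE_LENGTH = 20_000
_GENE_SPACING = 300_000

SPIKE_CATEGORIES = (
    "de_novo_dominant",
    "inherited_dominant",
    "recessive_hom",
    "comphet_trans",
    "comphet_cis",
    "xlr_hemizygous",
    "x_inherited_missense",
    "common_control",
    "synonymous_control",
    "cnv_panel_loss",
    "cnv_size_loss",
)


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level generator settings (defaults are the emulated study's)."""

    n_trios: int
    seed: int = 0
    mean_rare_functional_per_proband: float = 400.0
    mean_panel_overlapping: float = 30.0
    common_variant_count: int = 100
    rare_synonymous_mean: float = 50.0
    de_novo_rate_per_proband: float = 1.0
    fraction_one_parent_affected: float = 0.11
    fraction_both_parents_affected: float = 0.02
    comphet_gene_rate: float = 0.05
    cnv_count_per_proband: float = 2.0
    cnv_size_range: tuple[int, int] = (10_000, 2_000_000)
    genotyping_error_rate: float = 0.0
    male_fraction: float = 0.51
    n_background_genes: int = 2000
    n_panel_genes: int = 120
    spike_in_diagnoses: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_trios < 0:
            raise ValueError("n_trios must be non-negative")
        for name in (
            "mean_rare_functional_per_proband",
            "mean_panel_overlapping",
            "de_novo_rate_per_proband",
            "comphet_gene_rate",
            "cnv_count_per_proband",
            "genotyping_error_rate",
            "rare_synonymous_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fraction_one_parent_affected + self.fraction_both_parents_affected > 1:
            raise ValueError("affected-parent fractions must sum to at most 1")
        for category, count in self.spike_in_diagnoses:
            if category not in SPIKE_CATEGORIES:
                raise ValueError(f"unknown spike category {category!r}")
            if count < 0:
                raise ValueError("spike counts must be non-negative")


@dataclass
class GeneMap:
    """Synthetic gene intervals (1-based closed) keyed by symbol."""

    intervals: dict[str, tuple[str, int, int]]
    by_chrom: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_chrom:
            for gene, (chrom, start, end) in self.intervals.items():
                self.by_chrom.setdefault(chrom, []).append((start, end, gene))
            for chrom in self.by_chrom:
                self.by_chrom[chrom].sort()

    def overlapping(self, chrom: str, start: int, end: int) -> tuple[frozenset[str], frozenset[str]]:
        over, contained = set(), set()
        for gstart, gend, gene in self.by_chrom.get(chrom, ()):
            if gstart <= end and gend >= start:
                over.add(gene)
                if gstart >= start and gend <= end:
                    contained.add(gene)
        return frozenset(over), frozenset(contained)


def build_gene_map(params: SimulationParams) -> tuple[GeneMap, PanelVersion, list[str]]:
    """Deterministic synthetic genome: panel genes, background genes, panel.

    Panel composition cycles through allelic requirements (monoallelic 55%,
    biallelic 30%, X-linked recessive 10%, X-linked dominant 5%) and
    mechanisms; X-linked entries are placed on X. A few genes carry two
    entries and a couple of non-reportable entries are included.
    """
    intervals: dict[str, tuple[str, int, int]] = {}
    next_pos = {c: 1_000_000 for c in CHROMS}

    def place(gene: str, chrom: str) -> None:
        start = next_pos[chrom]
        intervals[gene] = (chrom, start, start + _GENE_LENGTH - 1)
        next_pos[chrom] = start + _GENE_SPACING

    n = params.n_panel_genes
    n_xlr = max(1, round(0.10 * n))
    n_xld = max(1, round(0.05 * n))
    n_biallelic = max(1, round(0.30 * n))
    n_mono = n - n_xlr - n_xld - n_biallelic
    mechanisms = (
        "loss_of_function",
        "all_missense_or_in_frame",
        "loss_of_function",
        "dominant_negative",
        "loss_of_function",
        "activating",
        "increased_gene_dosage",
    )
    entries: list[PanelEntry] = []
    idx = 0
    for kind, count in (
        ("monoallelic", n_mono),
        ("biallelic", n_biallelic),
        ("x_linked_recessive", n_xlr),
        ("x_linked_dominant", n_xld),
    ):
        for k in range(count):
            gene = f"PG{idx:04d}"
            chrom = "X" if kind.startswith("x_linked") else AUTOSOMES[idx % len(AUTOSOMES)]
            place(gene, chrom)
            mech = mechanisms[idx % len(mechanisms)]
            if kind == "x_linked_dominant" and mech == "increased_gene_dosage":
                mech = "loss_of_function"
            entries.append(
                PanelEntry(
                    gene_symbol=gene,
                    chromosome=chrom,
                    gene_interval=intervals[gene][1:],
                    allelic_requirement=kind,
                    mutation_consequence=mech,
                    reportable=True,
                )
            )
            if kind == "monoallelic" and k % 17 == 0:
                # some genes act through more than one mode
                entries.append(
                    PanelEntry(
                        gene_symbol=gene,
                        chromosome=chrom,
                        gene_interval=intervals[gene][1:],
                        allelic_requirement="biallelic",
                        mutation_consequence="loss_of_function",
                        reportable=True,
                    )
                )
            idx += 1
    # non-reportable (insufficient-evidence) entries kept out of triage
    for k in range(3):
        gene = f"NR{k:04d}"
        chrom = AUTOSOMES[(idx + k) % len(AUTOSOMES)]
        place(gene, chrom)
        entries.append(
            PanelEntry(
                gene_symbol=gene,
                chromosome=chrom,
                gene_interval=intervals[gene][1:],
                allelic_requirement="monoallelic",
                mutation_consequence="uncertain",
                reportable=False,
            )
        )
    background: list[str] = []
    for k in range(params.n_background_genes):
        gene = f"BG{k:04d}"
        chrom = CHROMS[k % len(CHROMS)]
        place(gene, chrom)
        background.append(gene)
    panel = PanelVersion(label="synthetic-panel", entries=entries)
    return GeneMap(intervals), panel, background


# ---------------------------------------------------------------------------
# variant construction helpers

_BASES = ("A", "C", "G", "T")

_NONFUNCTIONAL_TERMS = ("synonymous_variant", "intron_variant", "intergenic_variant")

_ALTERING_NON_LOF = ("missense_variant", "in_frame_deletion", "in_frame_insertion")


@dataclass
class _SimVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    maf: Optional[float]
    child: str
    mother: str
    father: str
    known_db: bool = False
    polyphen: Optional[float] = None


class _TrioBuilder:
    """Accumulates one trio's variants with unique positions per chromosome."""

    def __init__(self, rng: np.random.Generator, gene_map: GeneMap, male: bool):
        self.rng = rng
        self.gene_map = gene_map
        self.male = male
        self.used: set[tuple[str, int]] = set()
        self.variants: list[_SimVariant] = []

    def position_in(self, gene: str) -> tuple[str, int]:
        chrom, start, end = self.gene_map.intervals[gene]
        for _ in range(100):
            pos = int(self.rng.integers(start, end + 1))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos
        raise RuntimeError(f"could not place a unique position in {gene}")

    def alleles(self) -> tuple[str, str]:
        ref, alt = self.rng.choice(len(_BASES), size=2, replace=False)
        return _BASES[ref], _BASES[alt]

    def hemizygous_x(self, chrom: str) -> bool:
        return chrom == "X" and self.male

    def add(self, gene: str, consequence: str, maf: Optional[float],
            child: str, mother: str, father: str, known_db: bool = False) -> _SimVariant:
        chrom, pos = self.position_in(gene)
        ref, alt = self.alleles()
        if self.hemizygous_x(chrom):
            child = {"0/0": "0", "0/1": "1", "1/1": "1"}.get(child, child)
            father = {"0/0": "0", "0/1": "1", "1/1": "1"}.get(father, father)
        elif chrom == "X":
            father = {"0/0": "0", "0/1": "1", "1/1": "1"}.get(father, father)
        polyphen = None
        if consequence == "missense_variant" and self.rng.random() < 0.8:
            polyphen = float(np.round(self.rng.random(), 3))
        v = _SimVariant(chrom, pos, ref, alt, gene, consequence, maf, child, mother, father,
                        known_db=known_db, polyphen=polyphen)
        self.variants.append(v)
        return v

    def add_inherited_het(self, gene: str, consequence: str, maf: Optional[float],
                          from_mother: bool, known_db: bool = False) -> _SimVariant:
        chrom = self.gene_map.intervals[gene][0]
        if chrom == "X" and self.male:
            # males receive X only from the mother
            return self.add(gene, consequence, maf, "1", "0/1", "0", known_db)
        if from_mother:
            return self.add(gene, consequence, maf, "0/1", "0/1", "0/0", known_db)
        return self.add(gene, consequence, maf, "0/1", "0/0", "0/1", known_db)

    def add_de_novo(self, gene: str, consequence: str) -> _SimVariant:
        return self.add(gene, consequence, None, "0/1", "0/0", "0/0")


def _rare_maf(rng: np.random.Generator) -> Optional[float]:
    if rng.random() < 0.2:
        return None  # novel variant, absent from reference populations
    return float(np.round(10 ** rng.uniform(-5, -2.01), 7))


def _draw_consequence(rng: np.random.Generator) -> str:
    u = rng.random()
    if u < 0.75:
        return "missense_variant"
    if u < 0.90:
        return str(rng.choice(sorted(LOF_TERMS)))
    return str(rng.choice(_ALTERING_NON_LOF))


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortPaths:
    outdir: Path
    panel_path: Path
    ped_path: Path
    family_history_path: Path
    cnv_path: Path
    truth_path: Path
    config_path: Path
    vcf_paths: dict[str, Path]
    params: SimulationParams


def _vcf_header(sample_ids: Sequence[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=triotriage-synth"]
    for c in CHROMS:
        lines.append(f"##contig=<ID={c}>")
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Annotated gene symbol(s)">',
        '##INFO=<ID=CQ,Number=A,Type=String,Description="Most severe consequence">',
        '##INFO=<ID=AF_POPA,Number=A,Type=Float,Description="Allele frequency, population A">',
        '##INFO=<ID=AF_POPB,Number=A,Type=Float,Description="Allele frequency, population B">',
        '##INFO=<ID=KNOWN_PATH,Number=0,Type=Flag,Description="Present in a known-pathogenic database">',
        '##INFO=<ID=PolyPhen,Number=A,Type=Float,Description="Pass-through pathogenicity score">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    return "\n".join(lines) + "\n"


def _chrom_rank(chrom: str) -> int:
    return int(chrom) if chrom.isdigit() else 23


def _write_trio_vcf(path: Path, sample_ids: Sequence[str], variants: list[_SimVariant]) -> None:
    rows = sorted(variants, key=lambda v: (_chrom_rank(v.chrom), v.pos))
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_vcf_header(sample_ids))
        for v in rows:
            info = [f"GENE={v.gene}", f"CQ={v.consequence}"]
            if v.maf is not None:
                info.append(f"AF_POPA={v.maf:.7g}")
                info.append(f"AF_POPB={max(v.maf / 2, 0.0):.7g}")
            if v.known_db:
                info.append("KNOWN_PATH")
            if v.polyphen is not None:
                info.append(f"PolyPhen={v.polyphen:.3f}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                + ";".join(info)
                + f"\tGT\t{v.child}\t{v.mother}\t{v.father}\n"
            )


@dataclass
class _SpikePlan:
    spike_id: str
    category: str
    proband_id: str


def _assign_parent_status(rng: np.random.Generator, params: SimulationParams) -> tuple[bool, bool]:
    u = rng.random()
    if u < params.fraction_both_parents_affected:
        return True, True
    if u < params.fraction_both_parents_affected + params.fraction_one_parent_affected:
        return (True, False) if rng.random() < 0.5 else (False, True)
    return False, False


def generate_cohort(params: SimulationParams, outdir: str | Path) -> CohortPaths:
    """Write a complete synthetic cohort (VCFs, PED, panel, CNVs, truth).

    Deterministic given ``params.seed``: rerunning with the same parameters
    produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_dir = outdir / "trios"
    vcf_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(params.seed)

    gene_map, panel, background_genes = build_gene_map(params)
    panel_path = outdir / "panel.tsv"
    write_panel(panel, panel_path)

    mono_genes = sorted({e.gene_symbol for e in panel.entries if e.reportable and e.allelic_requirement == "monoallelic"})
    mono_lof_genes = sorted(
        {e.gene_symbol for e in panel.entries
         if e.reportable and e.allelic_requirement == "monoallelic" and e.mutation_consequence == "loss_of_function"}
    )
    biallelic_genes = sorted({e.gene_symbol for e in panel.entries if e.reportable and e.allelic_requirement == "biallelic"})
    xlr_genes = sorted({e.gene_symbol for e in panel.entries if e.reportable and e.allelic_requirement == "x_linked_recessive"})
    panel_genes = sorted(panel.reportable_genes)
    all_genes = panel_genes + background_genes
    cnv_loss_genes = sorted(
        {e.gene_symbol for e in panel.entries
         if e.reportable and e.mutation_consequence in ("loss_of_function", "dominant_negative")
         and not e.allelic_requirement.startswith("x_linked")}
    )

    # trio skeletons
    trios: list[TrioPedigree] = []
    for i in range(params.n_trios):
        fam = f"FAM{i:05d}"
        male = rng.random() < params.male_fraction
        mother_aff, father_aff = _assign_parent_status(rng, params)
        trios.append(
            TrioPedigree(
                proband_id=f"{fam}_c",
                mother_id=f"{fam}_m",
                father_id=f"{fam}_f",
                proband_sex="male" if male else "female",
                mother_affected=mother_aff,
                father_affected=father_aff,
                family_id=fam,
            )
        )

    # spike plan: assign each spike instance to a compatible proband, round robin
    males = [t for t in trios if t.proband_sex == "male"]
    spike_plans: list[_SpikePlan] = []
    counters = {"any": 0, "male": 0}
    for category, count in params.spike_in_diagnoses:
        for k in range(count):
            if category in ("xlr_hemizygous", "x_inherited_missense"):
                if not males:
                    raise ValueError(f"spike {category} needs at least one male proband")
                t = males[counters["male"] % len(males)]
                counters["male"] += 1
            else:
                t = trios[counters["any"] % len(trios)]
                counters["any"] += 1
            spike_plans.append(_SpikePlan(f"{category}_{k:03d}", category, t.proband_id))
    spikes_by_proband: dict[str, list[_SpikePlan]] = {}
    for sp in spike_plans:
        spikes_by_proband.setdefault(sp.proband_id, []).append(sp)

    truth_rows: list[dict] = []
    cnvs_by_proband: dict[str, list[CnvRecord]] = {}
    vcf_paths: dict[str, Path] = {}
    spike_gene_cycle = {"mono": 0, "mono_lof": 0, "biallelic": 0, "xlr": 0, "cnv_loss": 0, "bg": 0}

    for t in trios:
        builder = _TrioBuilder(rng, gene_map, male=(t.proband_sex == "male"))
        # --- background rare protein-altering variants
        n_total = int(rng.poisson(params.mean_rare_functional_per_proband))
        n_panel = int(rng.poisson(params.mean_panel_overlapping))
        n_dn = int(rng.poisson(params.de_novo_rate_per_proband))
        has_comphet = rng.random() < params.comphet_gene_rate
        n_bg = max(n_total - n_panel - n_dn - (2 if has_comphet else 0), 0)
        for _ in range(n_bg):
            gene = background_genes[int(rng.integers(len(background_genes)))]
            builder.add_inherited_het(gene, _draw_consequence(rng), _rare_maf(rng), rng.random() < 0.5)
        for _ in range(n_panel):
            gene = panel_genes[int(rng.integers(len(panel_genes)))]
            builder.add_inherited_het(gene, _draw_consequence(rng), _rare_maf(rng), rng.random() < 0.5)
        for _ in range(n_dn):
            gene = all_genes[int(rng.integers(len(all_genes)))]
            builder.add_de_novo(gene, _draw_consequence(rng))
        if has_comphet:
            gene = biallelic_genes[int(rng.integers(len(biallelic_genes)))]
            builder.add_inherited_het(gene, _draw_consequence(rng), _rare_maf(rng), True)
            builder.add_inherited_het(gene, _draw_consequence(rng), _rare_maf(rng), False)
        # --- rare non-functional background
        for _ in range(int(rng.poisson(params.rare_synonymous_mean))):
            gene = background_genes[int(rng.integers(len(background_genes)))]
            term = _NONFUNCTIONAL_TERMS[int(rng.integers(len(_NONFUNCTIONAL_TERMS)))]
            builder.add_inherited_het(gene, term, _rare_maf(rng), rng.random() < 0.5)
        # --- common background (Mendelian draws from population frequencies)
        for _ in range(params.common_variant_count):
            gene = all_genes[int(rng.integers(len(all_genes)))]
            chrom = gene_map.intervals[gene][0]
            maf = float(np.round(rng.uniform(0.011, 0.3), 6))
            m = int(rng.binomial(2, maf))
            hemi_father = chrom == "X"
            f = int(rng.binomial(1 if hemi_father else 2, maf))
            gm = int(rng.random() < 0.5) if m == 1 else m // 2
            if builder.hemizygous_x(chrom):
                child = str(gm)
            else:
                gf = f if hemi_father else (int(rng.random() < 0.5) if f == 1 else f // 2)
                child = {0: "0/0", 1: "0/1", 2: "1/1"}[gm + gf]
            term = _draw_consequence(rng) if rng.random() < 0.5 else _NONFUNCTIONAL_TERMS[0]
            mother_gt = {0: "0/0", 1: "0/1", 2: "1/1"}[m]
            father_gt = str(f) if hemi_father else {0: "0/0", 1: "0/1", 2: "1/1"}[f]
            builder.add(gene, term, maf, child, mother_gt, father_gt)
        # --- optional genotype noise to exercise Mendelian-error handling
        if params.genotyping_error_rate > 0:
            for v in builder.variants:
                if v.chrom != "X" and rng.random() < params.genotyping_error_rate and v.child == "0/1":
                    v.mother, v.father = "0/1", "0/0"
                    v.child = "1/1"  # impossible: father transmits no alt
        # --- spikes for this proband
        for sp in spikes_by_proband.get(t.proband_id, ()):
            truth_rows.extend(
                _apply_spike(sp, t, builder, rng, gene_map, cnvs_by_proband,
                             mono_genes, mono_lof_genes, biallelic_genes, xlr_genes,
                             cnv_loss_genes, background_genes, spike_gene_cycle)
            )
        # --- background CNVs
        cnvs = cnvs_by_proband.setdefault(t.proband_id, [])
        for _ in range(int(rng.poisson(params.cnv_count_per_proband))):
            chrom = CHROMS[int(rng.integers(len(CHROMS)))]
            lo, hi = params.cnv_size_range
            size = int(round(10 ** rng.uniform(math.log10(lo), math.log10(hi))))
            start = int(rng.integers(1_000_000, 25_000_000))
            end = start + size - 1
            over, contained = gene_map.overlapping(chrom, start, end)
            u = rng.random()
            status = ("de_novo" if u < 0.10 else "inherited_segregating" if u < 0.15
                      else "inherited_non_segregating" if u < 0.60 else "unknown")
            um = rng.random()
            maf = None if um < 0.7 else (float(np.round(rng.uniform(1e-4, 0.009), 6)) if um < 0.9
                                         else float(np.round(rng.uniform(0.02, 0.1), 6)))
            cnvs.append(
                CnvRecord(
                    chromosome=chrom,
                    start=start,
                    end=end,
                    cnv_type="loss" if rng.random() < 0.5 else "gain",
                    inheritance_status=status,
                    overlapped_genes=over,
                    fully_contained_genes=contained,
                    minor_allele_frequency=maf,
                )
            )
        path = vcf_dir / f"{t.proband_id}.vcf"
        _write_trio_vcf(path, (t.proband_id, t.mother_id, t.father_id), builder.variants)
        vcf_paths[t.proband_id] = path

    # --- PED, sidecar, CNV table, truth, config
    ped_path = outdir / "cohort.ped"
    with ped_path.open("w", encoding="utf-8") as fh:
        for t in trios:
            fh.write(f"{t.family_id} {t.father_id} 0 0 1 {2 if t.father_affected else 1}\n")
            fh.write(f"{t.family_id} {t.mother_id} 0 0 2 {2 if t.mother_affected else 1}\n")
            sex = 1 if t.proband_sex == "male" else 2
            fh.write(f"{t.family_id} {t.proband_id} {t.father_id} {t.mother_id} {sex} 2\n")

    family_history_path = outdir / "family_history.tsv"
    with family_history_path.open("w", encoding="utf-8") as fh:
        fh.write("proband_id\tfamily_history\n")
        for t in trios:
            fh.write(f"{t.proband_id}\tfalse\n")

    cnv_path = outdir / "cnvs.tsv"
    write_cnv_table(cnvs_by_proband, cnv_path)

    truth_path = outdir / "truth.tsv"
    truth_df = pd.DataFrame.from_records(
        truth_rows,
        columns=["spike_id", "proband_id", "category", "chromosome", "positions",
                 "gene", "expect_flag_trio", "expect_flag_proband_only"],
    )
    truth_df.to_csv(truth_path, sep="\t", index=False)

    config_path = outdir / "cohort_config.yaml"
    cfg = asdict(params)
    cfg["spike_in_diagnoses"] = [list(x) for x in params.spike_in_diagnoses]
    cfg["cnv_size_range"] = list(params.cnv_size_range)
    with config_path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    return CohortPaths(
        outdir=outdir,
        panel_path=panel_path,
        ped_path=ped_path,
        family_history_path=family_history_path,
        cnv_path=cnv_path,
        truth_path=truth_path,
        config_path=config_path,
        vcf_paths=vcf_paths,
        params=params,
    )


def _apply_spike(sp: _SpikePlan, t: TrioPedigree, builder: _TrioBuilder,
                 rng: np.random.Generator, gene_map: GeneMap,
                 cnvs_by_proband: dict[str, list[CnvRecord]],
                 mono_genes, mono_lof_genes, biallelic_genes, xlr_genes,
                 cnv_loss_genes, background_genes, cycle: dict[str, int]) -> list[dict]:
    """Insert one spike and return its truth row(s)."""

    def pick(genes: list[str], key: str) -> str:
        g = genes[cycle[key] % len(genes)]
        cycle[key] += 1
        return g

    def row(category, variants, gene, trio_flag, po_flag):
        return {
            "spike_id": sp.spike_id,
            "proband_id": t.proband_id,
            "category": category,
            "chromosome": variants[0].chrom if variants else "",
            "positions": ";".join(str(v.pos) for v in variants),
            "gene": gene,
            "expect_flag_trio": trio_flag,
            "expect_flag_proband_only": po_flag,
        }

    cat = sp.category
    if cat == "de_novo_dominant":
        gene = pick(mono_lof_genes, "mono_lof")
        v = builder.add_de_novo(gene, "stop_gained")
        return [row(cat, [v], gene, True, True)]
    if cat == "inherited_dominant":
        gene = pick(mono_genes, "mono")
        from_mother = bool(rng.random() < 0.5)
        v = builder.add_inherited_het(gene, "missense_variant", _rare_maf(rng), from_mother)
        parent_affected = bool(t.mother_affected if from_mother else t.father_affected)
        return [row(cat, [v], gene, parent_affected, True)]
    if cat == "recessive_hom":
        gene = pick(biallelic_genes, "biallelic")
        v = builder.add(gene, "missense_variant", _rare_maf(rng), "1/1", "0/1", "0/1")
        return [row(cat, [v], gene, True, True)]
    if cat == "comphet_trans":
        gene = pick(biallelic_genes, "biallelic")
        v1 = builder.add_inherited_het(gene, "missense_variant", _rare_maf(rng), True)
        v2 = builder.add_inherited_het(gene, "stop_gained", _rare_maf(rng), False)
        return [row(cat, [v1, v2], gene, True, True)]
    if cat == "comphet_cis":
        gene = pick(biallelic_genes, "biallelic")
        v1 = builder.add_inherited_het(gene, "missense_variant", _rare_maf(rng), True)
        v2 = builder.add_inherited_het(gene, "stop_gained", _rare_maf(rng), True)
        return [row(cat, [v1, v2], gene, False, True)]
    if cat == "xlr_hemizygous":
        gene = pick(xlr_genes, "xlr")
        v = builder.add(gene, "stop_gained", _rare_maf(rng), "1", "0/1", "0")
        return [row(cat, [v], gene, True, True)]
    if cat == "x_inherited_missense":
        gene = pick(xlr_genes, "xlr")
        v = builder.add(gene, "missense_variant", _rare_maf(rng), "1", "0/1", "0")
        return [row(cat, [v], gene, False, True)]
    if cat == "common_control":
        gene = pick(mono_genes, "mono")
        v = builder.add_inherited_het(gene, "missense_variant", 0.05, bool(rng.random() < 0.5))
        return [row(cat, [v], gene, False, False)]
    if cat == "synonymous_control":
        gene = pick(mono_genes, "mono")
        v = builder.add_inherited_het(gene, "synonymous_variant", _rare_maf(rng), bool(rng.random() < 0.5))
        return [row(cat, [v], gene, False, False)]
    if cat == "cnv_panel_loss":
        gene = pick(cnv_loss_genes, "cnv_loss")
        chrom, gstart, gend = gene_map.intervals[gene]
        start, end = gstart - 30_000, gend + 30_000  # 80 kb loss containing the gene
        over, contained = gene_map.overlapping(chrom, start, end)
        cnv = CnvRecord(chrom, start, end, "loss", "de_novo", over, contained, None)
        cnvs_by_proband.setdefault(t.proband_id, []).append(cnv)
        return [{
            "spike_id": sp.spike_id, "proband_id": t.proband_id, "category": cat,
            "chromosome": chrom, "positions": f"{start};{end}", "gene": gene,
            "expect_flag_trio": True, "expect_flag_proband_only": True,
        }]
    if cat == "cnv_size_loss":
        gene = pick(background_genes, "bg")
        chrom, gstart, gend = gene_map.intervals[gene]
        start = gstart - 10_000
        end = start + 150_000 - 1
        over, contained = gene_map.overlapping(chrom, start, end)
        cnv = CnvRecord(chrom, start, end, "loss", "de_novo", over, contained, None)
        cnvs_by_proband.setdefault(t.proband_id, []).append(cnv)
        return [{
            "spike_id": sp.spike_id, "proband_id": t.proband_id, "category": cat,
            "chromosome": chrom, "positions": f"{start};{end}", "gene": "",
            "expect_flag_trio": True, "expect_flag_proband_only": True,
        }]
    raise ValueError(f"unknown spike category {cat!r}")


# ---------------------------------------------------------------------------
# truth evaluation

def _candidate_matches(c: FlaggedCandidate, truth_positions: set[int]) -> bool:
    return truth_positions <= set(c.positions)


def truth_eval(
    candidates_by_proband: dict[str, list[FlaggedCandidate]],
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category confusion summary of triage output against spiked truth.

    A truth row counts as flagged when some candidate for the same proband
    covers all its positions. Raises when the truth table references probands
    absent from the triage output (mismatched cohorts).
    """
    if len(truth) == 0:
        return pd.DataFrame(columns=["category", "n_expected", "n_recovered", "sensitivity",
                                     "n_negative", "n_false_flag", "specificity"])
    missing = set(truth["proband_id"]) - set(candidates_by_proband)
    if missing:
        raise ValueError(f"truth table references probands absent from triage output: {sorted(missing)[:5]}")
    rows = []
    for category, group in truth.groupby("category", sort=True):
        n_exp = n_rec = n_neg = n_fp = 0
        for r in group.itertuples():
            positions = {int(x) for x in str(r.positions).split(";") if x}
            flagged = any(
                _candidate_matches(c, positions)
                for c in candidates_by_proband.get(r.proband_id, ())
            )
            expected = bool(r.expect_flag_trio) if "expect_flag_trio" in group.columns else True
            if expected:
                n_exp += 1
                n_rec += int(flagged)
            else:
                n_neg += 1
                n_fp += int(flagged)
        rows.append({
            "category": category,
            "n_expected": n_exp,
            "n_recovered": n_rec,
            "sensitivity": n_rec / n_exp if n_exp else float("nan"),
            "n_negative": n_neg,
            "n_false_flag": n_fp,
            "specificity": 1 - n_fp / n_neg if n_neg else float("nan"),
        })
    return pd.DataFrame(rows)


def truth_eval_mode(candidates_by_proband, truth: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Like :func:`truth_eval` but selecting the expectation column for *mode*."""
    col = "expect_flag_trio" if mode == "trio" else "expect_flag_proband_only"
    renamed = truth.copy()
    renamed["expect_flag_trio"] = renamed[col]
    return truth_eval(candidates_by_proband, renamed)


# ---------------------------------------------------------------------------
# bookkeeping fixtures (synthetic stand-ins shaped like the published tables)

#: Review bookkeeping of the emulated 1133-trio study: class -> (reviewed,
#: reported). Values are inputs to the arithmetic, not outputs of it.
REVIEW_LEDGER_COUNTS: dict[str, tuple[int, int]] = {
    "autosomal_dominant_de_novo": (242, 184),
    "autosomal_dominant_inherited": (528, 27),
    "autosomal_recessive_de_novo": (6, 0),
    "autosomal_recessive_inherited": (425, 52),
    "x_linked_de_novo": (41, 31),
    "x_linked_inherited": (371, 23),
    "uncertain_inheritance": (83, 0),
}

CHROMOSOMAL_EVENT_COUNTS: dict[str, int] = {"uniparental_disomy": 6, "mosaicism": 5}

_LEDGER_CATEGORY = {
    "autosomal_dominant_de_novo": ("autosomal_dominant", "de_novo"),
    "autosomal_dominant_inherited": ("autosomal_dominant", "maternal"),
    "autosomal_recessive_de_novo": ("autosomal_recessive_homozygous", "de_novo"),
    "autosomal_recessive_inherited": ("autosomal_recessive_homozygous", "biparental"),
    "x_linked_de_novo": ("x_linked_recessive", "de_novo"),
    "x_linked_inherited": ("x_linked_recessive", "maternal"),
    "uncertain_inheritance": ("cnv_size_rule", "unknown"),
}

#: Flagged SNV/indel counts per mechanism of the emulated study:
#: category -> (trio inherited, trio de novo, proband-only).
FLAG_TABLE_COUNTS: dict[str, tuple[int, int, int]] = {
    "autosomal_dominant": (473, 193, 9529),
    "autosomal_recessive_homozygous": (83, 0, 191),
    "autosomal_recessive_compound_het": (341, 6, 1071),
    "x_linked_dominant": (38, 21, 269),
    "x_linked_recessive": (322, 15, 387),
}


def _stub_variant(chrom: str, pos: int, gene: str, hom: bool = False, hemi: bool = False) -> VariantRecord:
    gt = Genotype(1, 1) if hemi else Genotype(2 if hom else 1, 2)
    return VariantRecord(
        chromosome=chrom,
        position=pos,
        ref_allele="A",
        alt_allele="T",
        gene_symbols=frozenset({gene}),
        consequence="missense_variant",
        child_gt=gt,
    )


def _stub_candidate(proband: str, category: str, inheritance, chrom: str, pos: int, gene: str) -> FlaggedCandidate:
    if category == "cnv_size_rule":
        payload: object = CnvRecord(chrom, pos, pos + 600_000, "loss", "unknown",
                                    frozenset({gene}), frozenset({gene}))
    elif category == "autosomal_recessive_compound_het":
        payload = (_stub_variant(chrom, pos, gene), _stub_variant(chrom, pos + 1, gene))
    else:
        hom = category == "autosomal_recessive_homozygous"
        payload = _stub_variant(chrom, pos, gene, hom=hom, hemi=(chrom == "X" and not hom))
    return FlaggedCandidate(
        proband_id=proband,
        payload=payload,
        category=category,
        inheritance=inheritance,
        reason_trail=["fixture"],
    )


def review_ledger_fixture(
    counts: Optional[dict[str, tuple[int, int]]] = None,
    extra_events: Optional[dict[str, int]] = None,
    cohort_size: int = 1133,
    two_finding_probands: int = 17,
):
    """Synthetic candidate/outcome set with the study-shaped review ledger.

    Returns ``(candidates_by_proband, outcomes, extra_events,
    extra_event_probands, cohort_size)`` ready for
    :func:`triotriage.report.build_cohort_summary`. Reported findings are
    laid out so that exactly ``two_finding_probands`` probands carry two
    reported cascade findings each and every chromosomal event diagnoses a
    proband of its own.
    """
    counts = dict(REVIEW_LEDGER_COUNTS if counts is None else counts)
    extra = dict(CHROMOSOMAL_EVENT_COUNTS if extra_events is None else extra_events)
    probands = [f"P{i:04d}" for i in range(cohort_size)]
    candidates_by_proband: dict[str, list[FlaggedCandidate]] = {p: [] for p in probands}
    outcomes: dict[str, ReviewOutcome] = {}

    # Slots for reported cascade findings: the first `two_finding_probands`
    # probands get two each, the rest one each.
    reported_slots: list[str] = []
    for p in probands[:two_finding_probands]:
        reported_slots.extend([p, p])
    reported_slots.extend(probands[two_finding_probands:])

    pos_counter = 1_000
    slot_idx = 0
    spread_idx = 0
    for label in sorted(counts):
        reviewed, reported = counts[label]
        category, inheritance = _LEDGER_CATEGORY[label]
        chrom = "X" if label.startswith("x_linked") else ("2" if label == "uncertain_inheritance" else "1")
        for j in range(reviewed):
            pos_counter += 10
            if j < reported:
                proband = reported_slots[slot_idx]
                slot_idx += 1
            else:
                # non-reported reviews spread across the cohort
                proband = probands[spread_idx % cohort_size]
                spread_idx += 1
            cand = _stub_candidate(proband, category, inheritance, chrom, pos_counter, f"G{pos_counter}")
            candidates_by_proband[proband].append(cand)
            decision = "reported" if j < reported else "not_reported"
            outcomes[cand.candidate_id] = ReviewOutcome(cand.candidate_id, decision)
    extra_event_probands = sum(extra.values())
    return candidates_by_proband, outcomes, extra, extra_event_probands, cohort_size


def flag_table_fixture(mode: str, counts: Optional[dict[str, tuple[int, int, int]]] = None):
    """Synthetic flagged-candidate set matching the study's flag table.

    Returns a ``proband_id -> candidates`` mapping whose
    :func:`triotriage.report.summarize_flags` output reproduces the encoded
    per-mechanism counts for the requested mode.
    """
    counts = dict(FLAG_TABLE_COUNTS if counts is None else counts)
    candidates_by_proband: dict[str, list[FlaggedCandidate]] = {}
    pos_counter = 1_000
    for category in sorted(counts):
        inherited_n, de_novo_n, po_n = counts[category]
        chrom = "X" if category.startswith("x_linked") else "1"
        if mode == "trio":
            cells = [("maternal", inherited_n), ("de_novo", de_novo_n)]
        else:
            cells = [("uninformative", po_n)]
        for inheritance, n in cells:
            for j in range(n):
                pos_counter += 10
                proband = f"P{j % 1133:04d}"
                inh = (inheritance, "paternal") if category.endswith("compound_het") else inheritance
                cand = _stub_candidate(proband, category, inh, chrom, pos_counter, f"G{pos_counter}")
                candidates_by_proband.setdefault(proband, []).append(cand)
    return candidates_by_proband


def panel_history_fixture() -> tuple[PanelVersion, PanelVersion]:
    """Two synthetic panel releases sized like consecutive curation rounds.

    The older release carries 1075 reportable genes; the newer one removes 7
    and adds 60, for 1128 reportable genes.
    """

    def entry(gene: str) -> PanelEntry:
        return PanelEntry(
            gene_symbol=gene,
            chromosome="1",
            allelic_requirement="monoallelic",
            mutation_consequence="loss_of_function",
            reportable=True,
        )

    old_genes = [f"G{i:04d}" for i in range(1075)]
    removed = set(old_genes[:7])
    added = [f"H{i:04d}" for i in range(60)]
    new_genes = [g for g in old_genes if g not in removed] + added
    old = PanelVersion(label="2013-07", entries=[entry(g) for g in old_genes])
    new = PanelVersion(label="2013-11", entries=[entry(g) for g in new_genes])
    return old, new
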