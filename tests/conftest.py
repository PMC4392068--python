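import sys
from dataclasses import replace
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from triotriage.panel import PanelEntry, PanelVersion
from triotriage.pedigree import TrioPedigree
from triotriage.pipeline import triage_cohort
from triotriage.synth import SimulationParams, generate_cohort
from triotriage.triage import FilterConfig
from triotriage.variants import Genotype, VariantRecord


@pytest.fixture
def mini_panel() -> PanelVersion:
    """Small hand-built panel covering every allelic requirement."""
    return PanelVersion(
        label="mini",
        entries=[
            PanelEntry("DOMG", "1", "monoallelic", "loss_of_function",
                       gene_interval=(1_000_000, 1_020_000)),
            PanelEntry("RECG", "2", "biallelic", "loss_of_function",
                       gene_interval=(2_000_000, 2_020_000)),
            PanelEntry("XLRG", "X", "x_linked_recessive", "loss_of_function",
                       gene_interval=(3_000_000, 3_020_000)),
            PanelEntry("XLDG", "X", "x_linked_dominant", "all_missense_or_in_frame",
                       gene_interval=(4_000_000, 4_020_000)),
            PanelEntry("DOSG", "5", "monoallelic", "increased_gene_dosage",
                       gene_interval=(5_000_000, 5_020_000)),
            PanelEntry("PHEN", "6", "monoallelic", "loss_of_function",
                       gene_interval=(6_000_000, 6_020_000),
                       required_phenotype_terms=frozenset({"HP:0000365"})),
            PanelEntry("NOPE", "7", "monoallelic", "uncertain", reportable=False),
        ],
    )


@pytest.fixture
def trio() -> TrioPedigree:
    return TrioPedigree(
        proband_id="C1", mother_id="M1", father_id="F1",
        proband_sex="female", mother_affected=False, father_affected=False,
    )


def make_variant(
    chrom="1", pos=1_000_100, gene="DOMG", consequence="missense_variant",
    maf=None, child=(1, 2), mother=(0, 2), father=(0, 2), **kwargs,
):
    def gt(spec):
        return None if spec is None else Genotype(*spec)

    return VariantRecord(
        chromosome=chrom, position=pos, ref_allele="A", alt_allele="G",
        gene_symbols=frozenset({gene}), consequence=consequence,
        minor_allele_frequency=maf, child_gt=gt(child), mother_gt=gt(mother),
        father_gt=gt(father), **kwargs,
    )


@pytest.fixture
def variant_factory():
    return make_variant


# ---------------------------------------------------------------------------
# One seeded 200-trio cohort with spiked truth, shared across the suite.
# All parents are unaffected so trio-mode flags are a subset of proband-only.

COHORT_SPIKES = (
    ("de_novo_dominant", 25),
    ("inherited_dominant", 10),
    ("recessive_hom", 10),
    ("comphet_trans", 10),
    ("comphet_cis", 10),
    ("xlr_hemizygous", 10),
    ("x_inherited_missense", 10),
    ("common_control", 25),
    ("synonymous_control", 25),
    ("cnv_panel_loss", 5),
    ("cnv_size_loss", 5),
)

COHORT_PARAMS = dict(
    n_trios=200,
    seed=1,
    fraction_one_parent_affected=0.0,
    fraction_both_parents_affected=0.0,
    spike_in_diagnoses=COHORT_SPIKES,
)


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return generate_cohort(SimulationParams(**COHORT_PARAMS), outdir)


def _run_cohort(paths, mode):
    return triage_cohort(
        paths.outdir / "trios",
        paths.ped_path,
        paths.panel_path,
        cnv_path=paths.cnv_path,
        family_history_path=paths.family_history_path,
        cfg=FilterConfig(mode=mode),
    )


@pytest.fixture(scope="session")
def cohort_trio_candidates(study_cohort):
    return _run_cohort(study_cohort, "trio")


@pytest.fixture(scope="session")
def cohort_proband_only_candidates(study_cohort):
    return _run_cohort(study_cohort, "proband_only")
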