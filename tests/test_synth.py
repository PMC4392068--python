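import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from conftest import COHORT_PARAMS
from triotriage.panel import load_panel
from triotriage.pedigree import read_family_history, read_ped
from triotriage.synth import (
    SimulationParams,
    generate_cohort,
    truth_eval,
    truth_eval_mode,
)
from triotriage.triage import read_cnv_table
from triotriage.variants import is_functional, read_trio_vcf


def file_hashes(outdir: Path) -> dict[str, str]:
    return {
        str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.rglob("*"))
        if p.is_file()
    }


def test_params_validation():
    with pytest.raises(ValueError, match="non-negative"):
        SimulationParams(n_trios=1, de_novo_rate_per_proband=-1)
    with pytest.raises(ValueError, match="sum"):
        SimulationParams(n_trios=1, fraction_one_parent_affected=0.8,
                         fraction_both_parents_affected=0.3)
    with pytest.raises(ValueError, match="spike"):
        SimulationParams(n_trios=1, spike_in_diagnoses=(("not_a_category", 1),))


def test_empty_cohort_has_valid_headers(tmp_path):
    paths = generate_cohort(SimulationParams(n_trios=0, seed=5), tmp_path / "empty")
    assert read_ped(paths.ped_path) == []
    assert load_panel(paths.panel_path).reportable_gene_count > 0
    assert read_cnv_table(paths.cnv_path) == {}
    assert len(pd.read_csv(paths.truth_path, sep="\t")) == 0


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    params = SimulationParams(n_trios=3, seed=11,
                              spike_in_diagnoses=(("de_novo_dominant", 1),))
    a = generate_cohort(params, tmp_path / "a")
    b = generate_cohort(params, tmp_path / "b")
    assert file_hashes(a.outdir) == file_hashes(b.outdir)


def test_different_seed_changes_outputs(tmp_path):
    a = generate_cohort(SimulationParams(n_trios=3, seed=1), tmp_path / "a")
    b = generate_cohort(SimulationParams(n_trios=3, seed=2), tmp_path / "b")
    assert file_hashes(a.outdir) != file_hashes(b.outdir)


def test_generated_files_parse_through_readers(study_cohort):
    trios = read_ped(study_cohort.ped_path)
    assert len(trios) == COHORT_PARAMS["n_trios"]
    history = read_family_history(study_cohort.family_history_path)
    assert set(history) == {t.proband_id for t in trios}
    panel = load_panel(study_cohort.panel_path)
    assert panel.reportable_gene_count > 0
    cnvs = read_cnv_table(study_cohort.cnv_path)
    assert set(cnvs) <= {t.proband_id for t in trios}
    t = trios[0]
    records = read_trio_vcf(study_cohort.vcf_paths[t.proband_id], t)
    assert len(records) > 100
    assert all(r.child_gt is not None for r in records)


def test_rare_functional_count_matches_configured_mean(study_cohort):
    """Per-proband rare protein-altering count ~ the configured mean of 400."""
    trios = read_ped(study_cohort.ped_path)
    counts = []
    for t in trios:
        records = read_trio_vcf(study_cohort.vcf_paths[t.proband_id], t)
        n = sum(
            1
            for r in records
            if r.child_gt.carries_alt
            and is_functional(r.consequence)
            and (r.minor_allele_frequency is None or r.minor_allele_frequency <= 0.01)
        )
        counts.append(n)
    mean = float(np.mean(counts))
    target = study_cohort.params.mean_rare_functional_per_proband
    se = math.sqrt(target / len(counts))
    # spikes add a handful of variants per cohort; stay within 3 SE + spike slack
    assert abs(mean - target) < 3 * se + 1.0


def test_male_probands_are_hemizygous_on_x(study_cohort):
    trios = read_ped(study_cohort.ped_path)
    male = next(t for t in trios if t.proband_sex == "male")
    records = read_trio_vcf(study_cohort.vcf_paths[male.proband_id], male)
    x_records = [r for r in records if r.is_x]
    assert x_records, "male proband should carry X variants"
    assert all(r.child_gt.ploidy == 1 for r in x_records)
    assert all(r.father_gt.ploidy == 1 for r in x_records)
    female = next(t for t in trios if t.proband_sex == "female")
    f_records = [r for r in read_trio_vcf(study_cohort.vcf_paths[female.proband_id], female) if r.is_x]
    assert all(r.child_gt.ploidy == 2 for r in f_records)


def test_mendelian_transmission_respected_except_spiked_de_novos(study_cohort):
    """Background genotypes never violate transmission from stated parents."""
    from triotriage.inheritance import classify_inheritance

    trios = read_ped(study_cohort.ped_path)
    for t in trios[:20]:
        records = read_trio_vcf(study_cohort.vcf_paths[t.proband_id], t)
        for r in records:
            assert classify_inheritance(r, t) != "mendelian_error"


def test_genotype_error_rate_produces_mendelian_errors(tmp_path):
    from triotriage.inheritance import classify_inheritance

    params = SimulationParams(n_trios=3, seed=7, genotyping_error_rate=0.02)
    paths = generate_cohort(params, tmp_path / "noisy")
    trios = read_ped(paths.ped_path)
    calls = [
        classify_inheritance(r, t)
        for t in trios
        for r in read_trio_vcf(paths.vcf_paths[t.proband_id], t)
    ]
    assert "mendelian_error" in calls


class TestTruthEval:
    def test_perfect_recovery_by_construction(self, study_cohort, cohort_trio_candidates):
        truth = pd.read_csv(study_cohort.truth_path, sep="\t")
        summary = truth_eval_mode(cohort_trio_candidates, truth, "trio").set_index("category")
        assert summary.loc["de_novo_dominant", "sensitivity"] == 1.0
        assert summary.loc["common_control", "specificity"] == 1.0

    def test_mismatched_cohorts_rejected(self, cohort_trio_candidates, study_cohort):
        truth = pd.read_csv(study_cohort.truth_path, sep="\t")
        truth = truth.assign(proband_id="NOT_A_PROBAND")
        with pytest.raises(ValueError, match="absent"):
            truth_eval(cohort_trio_candidates, truth)

    def test_shuffled_truth_collapses_sensitivity(self, study_cohort, cohort_trio_candidates):
        """Permutation control: reassigning spikes to random probands destroys recovery."""
        rng = np.random.default_rng(0)
        truth = pd.read_csv(study_cohort.truth_path, sep="\t")
        shuffled = truth.copy()
        shuffled["proband_id"] = rng.permutation(truth["proband_id"].values)
        moved = shuffled["proband_id"] != truth["proband_id"]
        summary = truth_eval_mode(
            cohort_trio_candidates, shuffled[moved], "trio"
        ).set_index("category")
        if "de_novo_dominant" in summary.index and summary.loc["de_novo_dominant", "n_expected"] > 0:
            assert summary.loc["de_novo_dominant", "sensitivity"] < 0.5
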