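from dataclasses import replace

import pytest

from conftest import make_variant
from triotriage.panel import PanelEntry, PanelVersion
from triotriage.pedigree import TrioPedigree
from triotriage.triage import (
    CnvRecord,
    FilterConfig,
    cnv_panel_filter,
    cnv_size_filter,
    find_compound_hets,
    frequency_filter,
    genotype_matches_requirement,
    triage_proband,
    x_missense_exclusion,
)

TRIO_CFG = FilterConfig(mode="trio")
PO_CFG = FilterConfig(mode="proband_only")


class TestFrequencyFilter:
    @pytest.mark.parametrize("maf, keep", [(0.02, False), (0.01, True), (0.0099, True), (None, True)])
    def test_threshold_boundary_inclusive(self, maf, keep):
        v = make_variant(maf=maf)
        assert frequency_filter(v, TRIO_CFG) is keep

    def test_stricter_dominant_threshold(self):
        cfg = FilterConfig(dominant_maf_threshold=0.001)
        v = make_variant(maf=0.005)
        assert frequency_filter(v, cfg, dominant_context=False)
        assert not frequency_filter(v, cfg, dominant_context=True)


class TestGenotypeRequirement:
    def entry(self, req, chrom="1"):
        return PanelEntry("G", chrom if not req.startswith("x_") else "X",
                          req, "loss_of_function")

    def test_single_het_fails_biallelic(self, trio):
        vs = [make_variant(gene="G")]
        assert not genotype_matches_requirement(vs, self.entry("biallelic"), trio)

    def test_hom_alt_satisfies_biallelic(self, trio):
        vs = [make_variant(gene="G", child=(2, 2), mother=(1, 2), father=(1, 2))]
        assert genotype_matches_requirement(vs, self.entry("biallelic"), trio)

    def test_two_hets_are_comphet_candidate(self, trio):
        vs = [make_variant(gene="G", pos=100), make_variant(gene="G", pos=200)]
        assert genotype_matches_requirement(vs, self.entry("biallelic"), trio)

    def test_single_het_satisfies_monoallelic(self, trio):
        assert genotype_matches_requirement([make_variant(gene="G")], self.entry("monoallelic"), trio)

    def test_hemizygous_male_satisfies_xlr(self):
        male = TrioPedigree(proband_id="C", mother_id="M", father_id="F", proband_sex="male")
        vs = [make_variant(chrom="X", gene="G", child=(1, 1), father=(0, 1))]
        assert genotype_matches_requirement(vs, self.entry("x_linked_recessive"), male)

    def test_het_female_fails_xlr(self, trio):
        vs = [make_variant(chrom="X", gene="G", father=(0, 1))]
        assert not genotype_matches_requirement(vs, self.entry("x_linked_recessive"), trio)


class TestCompoundHets:
    def test_trans_pair_found(self, trio):
        a = make_variant(pos=100, mother=(1, 2), father=(0, 2))
        b = make_variant(pos=200, mother=(0, 2), father=(1, 2))
        assert find_compound_hets([a, b], trio, TRIO_CFG) == [(a, b)]

    def test_cis_pair_excluded_in_trio_mode(self, trio):
        a = make_variant(pos=100, mother=(1, 2), father=(0, 2))
        b = make_variant(pos=200, mother=(1, 2), father=(0, 2))
        assert find_compound_hets([a, b], trio, TRIO_CFG) == []

    def test_de_novo_member_pairs_with_inherited(self, trio):
        a = make_variant(pos=100, mother=(0, 2), father=(0, 2))  # de novo
        b = make_variant(pos=200, mother=(1, 2), father=(0, 2))  # maternal
        assert find_compound_hets([a, b], trio, TRIO_CFG) == [(a, b)]

    def test_proband_only_mode_enumerates_all_pairs(self, trio):
        vs = [make_variant(pos=p, mother=None, father=None) for p in (100, 200, 300)]
        pairs = find_compound_hets(vs, trio, PO_CFG)
        assert len(pairs) == 3  # C(3,2) pairs of unknown phase


class TestXMissenseExclusion:
    def var(self, **kw):
        defaults = dict(chrom="X", gene="XLRG", consequence="missense_variant",
                        mother=(1, 2), father=(0, 1))
        defaults.update(kw)
        return make_variant(**defaults)

    def ped(self, family_history=False):
        return TrioPedigree(proband_id="C", mother_id="M", father_id="F",
                            proband_sex="female", family_history=family_history)

    def test_inherited_x_missense_excluded(self):
        assert x_missense_exclusion(self.var(), "maternal", self.ped())

    def test_de_novo_x_missense_retained(self):
        assert not x_missense_exclusion(self.var(), "de_novo", self.ped())

    def test_family_history_lifts_exclusion(self):
        assert not x_missense_exclusion(self.var(), "maternal", self.ped(family_history=True))

    def test_known_database_membership_lifts_exclusion(self):
        v = self.var(in_known_pathogenic_db=True)
        assert not x_missense_exclusion(v, "maternal", self.ped())


class TestCnvPanelFilter:
    def test_loss_fully_containing_lof_gene_flagged(self, mini_panel):
        c = CnvRecord("1", 990_000, 1_070_000, "loss", "de_novo",
                      frozenset({"DOMG"}), frozenset({"DOMG"}))
        matches = cnv_panel_filter(c, mini_panel)
        assert [e.gene_symbol for _, e in matches] == ["DOMG"]

    def test_gain_overlapping_dosage_gene_flagged(self, mini_panel):
        c = CnvRecord("5", 5_010_000, 5_400_000, "gain", "unknown",
                      frozenset({"DOSG"}), frozenset())
        matches = cnv_panel_filter(c, mini_panel)
        assert [e.gene_symbol for _, e in matches] == ["DOSG"]

    def test_partial_loss_not_flagged_by_panel_rule(self, mini_panel):
        c = CnvRecord("1", 1_010_000, 1_400_000, "loss", "de_novo",
                      frozenset({"DOMG"}), frozenset())
        assert cnv_panel_filter(c, mini_panel) == []

    def test_gain_containing_lof_gene_not_matched(self, mini_panel):
        c = CnvRecord("1", 990_000, 1_070_000, "gain", "de_novo",
                      frozenset({"DOMG"}), frozenset({"DOMG"}))
        assert cnv_panel_filter(c, mini_panel) == []


class TestCnvSizeFilter:
    def cnv(self, length, cnv_type="loss", status="de_novo"):
        return CnvRecord("1", 1_000_000, 1_000_000 + length - 1, cnv_type, status,
                         frozenset({"BG1"}), frozenset())

    def test_de_novo_loss_above_threshold_flagged(self):
        assert cnv_size_filter(self.cnv(120_000), TRIO_CFG)

    def test_gain_below_gain_threshold_dropped(self):
        assert not cnv_size_filter(self.cnv(200_000, "gain"), TRIO_CFG)

    def test_non_segregating_inherited_never_size_flagged(self):
        assert not cnv_size_filter(self.cnv(2_000_000, status="inherited_non_segregating"), TRIO_CFG)


class TestTriageProband:
    def test_de_novo_lof_in_dominant_gene_flagged(self, mini_panel, trio):
        v = make_variant(gene="DOMG", consequence="stop_gained")
        (cand,) = triage_proband([v], [], mini_panel, trio, TRIO_CFG)
        assert cand.category == "autosomal_dominant"
        assert cand.inheritance == "de_novo"
        assert cand.reason_trail[0].startswith("frequency")

    def test_inherited_dominant_het_dropped_in_trio_kept_in_proband_only(self, mini_panel, trio):
        v = make_variant(gene="DOMG", mother=(1, 2))
        assert triage_proband([v], [], mini_panel, trio, TRIO_CFG) == []
        (cand,) = triage_proband([v], [], mini_panel, trio, PO_CFG)
        assert cand.category == "autosomal_dominant"

    def test_affected_transmitting_parent_rescues_dominant_het(self, mini_panel, trio):
        affected = replace(trio, mother_affected=True)
        v = make_variant(gene="DOMG", mother=(1, 2))
        (cand,) = triage_proband([v], [], mini_panel, affected, TRIO_CFG)
        assert cand.inheritance == "maternal"

    def test_common_and_synonymous_variants_never_flagged(self, mini_panel, trio):
        common = make_variant(gene="DOMG", consequence="stop_gained", maf=0.02)
        silent = make_variant(gene="DOMG", pos=1_000_200, consequence="synonymous_variant")
        assert triage_proband([common, silent], [], mini_panel, trio, TRIO_CFG) == []
        assert triage_proband([common, silent], [], mini_panel, trio, PO_CFG) == []

    def test_non_panel_gene_not_flagged(self, mini_panel, trio):
        v = make_variant(gene="RANDOM", consequence="stop_gained")
        assert triage_proband([v], [], mini_panel, trio, TRIO_CFG) == []

    def test_recessive_hom_requires_carrier_parents(self, mini_panel, trio):
        good = make_variant(chrom="2", pos=2_000_100, gene="RECG",
                            child=(2, 2), mother=(1, 2), father=(1, 2))
        diagnostics = []
        (cand,) = triage_proband([good], [], mini_panel, trio, TRIO_CFG,
                                 diagnostics=diagnostics)
        assert cand.category == "autosomal_recessive_homozygous"
        assert cand.inheritance == "biparental"
        # hom child with a non-carrier father is a transmission inconsistency
        bad = make_variant(chrom="2", pos=2_000_200, gene="RECG",
                           child=(2, 2), mother=(1, 2), father=(0, 2))
        assert triage_proband([bad], [], mini_panel, trio, TRIO_CFG,
                              diagnostics=diagnostics) == []
        assert any(reason == "mendelian_error" for _, reason in diagnostics)

    def test_x_inherited_missense_excluded_unless_family_history(self, mini_panel):
        male = TrioPedigree(proband_id="C", mother_id="M", father_id="F",
                            proband_sex="male")
        v = make_variant(chrom="X", pos=3_000_100, gene="XLRG",
                         child=(1, 1), mother=(1, 2), father=(0, 1))
        assert triage_proband([v], [], mini_panel, male, TRIO_CFG) == []
        with_history = replace(male, family_history=True)
        (cand,) = triage_proband([v], [], mini_panel, with_history, TRIO_CFG)
        assert cand.category == "x_linked_recessive"

    def test_comphet_flagged_with_trans_members(self, mini_panel, trio):
        a = make_variant(chrom="2", pos=2_000_100, gene="RECG", mother=(1, 2))
        b = make_variant(chrom="2", pos=2_000_200, gene="RECG", father=(1, 2))
        (cand,) = triage_proband([a, b], [], mini_panel, trio, TRIO_CFG)
        assert cand.category == "autosomal_recessive_compound_het"
        assert cand.inheritance == ("maternal", "paternal")

    def test_phenotype_mismatch_annotated_not_removed(self, mini_panel, trio):
        v = make_variant(chrom="6", pos=6_000_100, gene="PHEN", consequence="stop_gained")
        (cand,) = triage_proband([v], [], mini_panel, trio, TRIO_CFG,
                                 proband_phenotype_terms=frozenset({"HP:9999999"}))
        assert cand.phenotype_match_note == "phenotype-mismatch"
        (matched,) = triage_proband([v], [], mini_panel, trio, TRIO_CFG,
                                    proband_phenotype_terms=frozenset({"HP:0000365"}))
        assert matched.phenotype_match_note == ""

    def test_benign_missense_score_exclusion_when_enabled(self, mini_panel, trio):
        affected = replace(trio, mother_affected=True)
        v = make_variant(gene="DOMG", mother=(1, 2),
                         pathogenicity_scores={"PolyPhen": 0.05})
        cfg = FilterConfig(mode="trio", benign_missense_score_cutoff=0.15)
        assert triage_proband([v], [], mini_panel, affected, cfg) == []
        # de novo missense is never removed by the benign-score rule
        dn = make_variant(gene="DOMG", pathogenicity_scores={"PolyPhen": 0.05})
        assert len(triage_proband([dn], [], mini_panel, affected, cfg)) == 1

    def test_missing_parental_genotypes_fall_back_to_proband_only(self, mini_panel):
        solo = TrioPedigree(proband_id="C", proband_sex="female")
        v = make_variant(gene="DOMG", mother=None, father=None)
        (cand,) = triage_proband([v], [], mini_panel, solo, TRIO_CFG)
        assert cand.inheritance == "uninformative"

    def test_output_is_deterministic_and_replayable(self, mini_panel, trio):
        vs = [
            make_variant(gene="DOMG", consequence="stop_gained"),
            make_variant(chrom="2", pos=2_000_100, gene="RECG",
                         child=(2, 2), mother=(1, 2), father=(1, 2)),
        ]
        first = triage_proband(vs, [], mini_panel, trio, TRIO_CFG)
        second = triage_proband(list(reversed(vs)), [], mini_panel, trio, TRIO_CFG)
        assert [c.candidate_id for c in first] == [c.candidate_id for c in second]
        assert [c.reason_trail for c in first] == [c.reason_trail for c in second]
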