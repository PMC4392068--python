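import pytest

from conftest import make_variant
from triotriage.report import (
    ReviewOutcome,
    build_cohort_summary,
    candidates_from_frame,
    candidates_to_frame,
    diagnostic_yield,
    predictive_value,
    read_review_outcomes,
    render_percent,
    summarize_flags,
    write_report_records,
    write_review_outcomes,
)
from triotriage.triage import FlaggedCandidate


class TestPredictiveValue:
    @pytest.mark.parametrize("reviewed, reported, expected", [
        (1696, 328, 19),
        (528, 27, 5),
        (10, 10, 100),
        (425, 52, 12),
    ])
    def test_rounded_percent(self, reviewed, reported, expected):
        assert predictive_value(reviewed, reported) == expected

    def test_zero_reviewed_is_undefined(self):
        assert predictive_value(0, 0) is None
        assert render_percent(None) == ".."

    def test_reported_cannot_exceed_reviewed(self):
        with pytest.raises(ValueError):
            predictive_value(5, 6)


class TestDiagnosticYield:
    @pytest.mark.parametrize("diagnosed, cohort, expected", [
        (311, 1133, 27),
        (184, 1133, 16),
        (31, 1133, 3),
        (6, 1133, 0.5),  # sub-1% classes keep one decimal
    ])
    def test_rounded_percent(self, diagnosed, cohort, expected):
        assert diagnostic_yield(diagnosed, cohort) == expected

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            diagnostic_yield(1, 0)


def cand(proband, category, inheritance, pos, gene):
    hom = category == "autosomal_recessive_homozygous"
    if category == "autosomal_recessive_compound_het":
        payload = (
            make_variant(pos=pos, gene=gene),
            make_variant(pos=pos + 1, gene=gene),
        )
    else:
        payload = make_variant(pos=pos, gene=gene, child=(2, 2) if hom else (1, 2))
    return FlaggedCandidate(
        proband_id=proband, payload=payload, category=category,
        inheritance=inheritance, reason_trail=["test"],
    )


class TestSummarizeFlags:
    def test_empty_cohort_all_zero(self):
        frame = summarize_flags({}, "trio")
        assert (frame == 0).all().all()
        assert list(frame.columns) == ["inherited", "de_novo"]

    def test_counts_match_independent_recount(self, cohort_trio_candidates):
        frame = summarize_flags(cohort_trio_candidates, "trio")
        # brute-force recount with its own compound-het dedup
        expected = {}
        for proband, cands in cohort_trio_candidates.items():
            genes_seen = set()
            for c in cands:
                if c.category.startswith("cnv"):
                    continue
                if c.category.endswith("compound_het"):
                    key = (proband, c.gene)
                    if key in genes_seen:
                        continue
                    genes_seen.add(key)
                col = "de_novo" if c.is_de_novo else "inherited"
                expected[(c.category, col)] = expected.get((c.category, col), 0) + 1
        for (category, col), n in expected.items():
            assert frame.loc[category, col] == n
        assert frame.loc["Total"].sum() == sum(expected.values())

    def test_comphet_counted_once_per_gene(self):
        pairs = [cand("P1", "autosomal_recessive_compound_het", ("maternal", "paternal"), p, "G1")
                 for p in (100, 200, 300)]
        frame = summarize_flags({"P1": pairs}, "trio")
        assert frame.loc["autosomal_recessive_compound_het", "inherited"] == 1

    def test_totals_invariant_to_proband_order(self, cohort_trio_candidates):
        forward = summarize_flags(cohort_trio_candidates, "trio")
        reversed_map = dict(reversed(list(cohort_trio_candidates.items())))
        backward = summarize_flags(reversed_map, "trio")
        assert forward.equals(backward)


class TestCohortSummary:
    def test_diagnosed_probands_counts_unique_probands(self):
        cands = {
            "P1": [cand("P1", "autosomal_dominant", "de_novo", 100, "G1"),
                   cand("P1", "autosomal_dominant", "maternal", 200, "G2")],
            "P2": [cand("P2", "autosomal_dominant", "de_novo", 300, "G3")],
            "P3": [cand("P3", "autosomal_dominant", "de_novo", 400, "G4")],
        }
        outcomes = {}
        for plist in cands.values():
            for c in plist:
                outcomes[c.candidate_id] = ReviewOutcome(c.candidate_id, "reported")
        # P3's candidate is reviewed but not reported
        last = cands["P3"][0].candidate_id
        outcomes[last] = ReviewOutcome(last, "not_reported")
        summary = build_cohort_summary(cands, outcomes, cohort_size=10)
        assert summary.diagnosed_probands == 2
        assert summary.two_finding_probands == 1
        assert summary.total_reviewed == 4
        assert summary.total_reported == 3


class TestReportRecords:
    def test_zero_reported_writes_header_only(self, tmp_path):
        path = tmp_path / "report.tsv"
        assert write_report_records([], {}, path) == 0
        assert path.read_text().count("\n") == 1

    def test_single_snv_row(self, tmp_path):
        c = cand("P1", "autosomal_dominant", "de_novo", 100, "G1")
        outcomes = {c.candidate_id: ReviewOutcome(c.candidate_id, "reported")}
        path = tmp_path / "report.tsv"
        assert write_report_records([c], outcomes, path) == 1
        header, row = path.read_text().strip().split("\n")
        fields = dict(zip(header.split("\t"), row.split("\t")))
        assert fields["genotype"] == "0/1"
        assert fields["inheritance"] == "de_novo"
        assert fields["allele"] == "A/G"
        assert fields["most_severe_consequence"] == "missense_variant"

    def test_comphet_emits_two_rows_sharing_event_id(self, tmp_path):
        c = cand("P1", "autosomal_recessive_compound_het", ("maternal", "paternal"), 100, "G1")
        outcomes = {c.candidate_id: ReviewOutcome(c.candidate_id, "reported")}
        path = tmp_path / "report.tsv"
        assert write_report_records([c], outcomes, path) == 2
        lines = path.read_text().strip().split("\n")[1:]
        event_ids = {line.split("\t")[1] for line in lines}
        assert len(lines) == 2 and len(event_ids) == 1

    def test_unreported_candidates_omitted(self, tmp_path):
        c = cand("P1", "autosomal_dominant", "de_novo", 100, "G1")
        path = tmp_path / "report.tsv"
        assert write_report_records([c], {}, path) == 0


def test_review_outcomes_round_trip(tmp_path):
    outcomes = [
        ReviewOutcome("id1", "reported", "clear fit"),
        ReviewOutcome("id2", "not_reported", ""),
    ]
    path = tmp_path / "outcomes.tsv"
    write_review_outcomes(outcomes, path)
    loaded = read_review_outcomes(path)
    assert loaded == {o.candidate_id: o for o in outcomes}


def test_candidate_frame_round_trip_preserves_counting(cohort_trio_candidates):
    frame = candidates_to_frame(cohort_trio_candidates)
    rebuilt = candidates_from_frame(frame)
    direct = summarize_flags(cohort_trio_candidates, "trio")
    via_frame = summarize_flags(rebuilt, "trio")
    assert direct.equals(via_frame)
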