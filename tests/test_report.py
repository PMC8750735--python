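import pytest
from hypothesis import given, strategies as st

from mbrisk.learner import InteractionResult, MarkovBlanketResult
from mbrisk.report import (
    InteractionRecord,
    PUBLISHED_ALPHAS,
    count_focus_frequency,
    load_published_interactions,
    load_published_table,
    merge_variables,
    records_from_results,
    render_causal_set_report,
    render_frequency_table,
    tabulate_partner_frequencies,
)


class TestMergeVariables:
    @pytest.mark.parametrize(
        "name,merged",
        [
            ("Ethnicity", "Race/ethnicity"),
            ("Race", "Race/ethnicity"),
            ("race", "Race/ethnicity"),
            ("Smoking", "Smoking/alcohol"),
            ("Alcohol usage", "Smoking/alcohol"),
            ("Alcohol/smoking", "Smoking/alcohol"),
            ("Lymph_nodes_positive", "LN positive/status"),
            ("Lymph_node_status", "LN positive/status"),
            ("HER2", "HER2"),
            ("n_tnm_stage", "n-TNM"),
            ("Surgical_margins", "Surgical margins"),
        ],
    )
    def test_known_mappings(self, name, merged):
        assert merge_variables(name) == merged

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            merge_variables("not_a_variable")


class TestPublishedTables:
    def test_row_counts(self):
        assert len(load_published_table(1)) == 29
        assert len(load_published_table(120)) == 36
        assert len(load_published_table(480)) == 33

    @pytest.mark.parametrize("alpha", PUBLISHED_ALPHAS)
    def test_every_printed_cell_reproduced(self, alpha):
        per_focus = load_published_interactions(alpha)
        for row in load_published_table(alpha):
            focus = merge_variables(row["focus"])
            rows = tabulate_partner_frequencies(per_focus[focus], focus, float(alpha))
            match = [r for r in rows if r.partner == merge_variables(row["partner"])]
            assert len(match) == 1
            assert match[0].n_times == row["n_times"]
            assert match[0].total == row["total"]
            assert match[0].percent == row["percent"]

    @pytest.mark.parametrize("alpha", PUBLISHED_ALPHAS)
    def test_totals_and_percent_sums(self, alpha):
        per_focus = load_published_interactions(alpha)
        for focus, records in per_focus.items():
            rows = tabulate_partner_frequencies(records, focus, float(alpha))
            assert sum(r.n_times for r in rows) == rows[0].total
            assert 99.9 <= sum(r.percent for r in rows) <= 100.1

    @pytest.mark.parametrize("alpha", PUBLISHED_ALPHAS)
    def test_count_partition_identity(self, alpha):
        per_focus = load_published_interactions(alpha)
        for focus, records in per_focus.items():
            by_horizon = sum(
                count_focus_frequency(records, focus, float(alpha), h) for h in (5, 10, 15)
            )
            assert by_horizon == len(records)

    def test_her2_alpha1_year5_count(self):
        # manual token count over the transcribed alpha-1 HER2 rows:
        # 2 (Stage) + 1 + 1 + 1 + 1 (Histology) + 2 (Grade) + 1 + 1 (ER,
        # truncated to n_times) + 1 (PR) = 11
        records = load_published_interactions(1)["HER2"]
        assert count_focus_frequency(records, "HER2", 1.0, 5) == 11

    def test_empty_records_zero(self):
        assert count_focus_frequency([], "HER2", 1.0, 5) == 0
        assert tabulate_partner_frequencies([], "HER2", 1.0) == []


class TestTabulation:
    def test_er_ntnm_row_alpha1(self):
        per_focus = load_published_interactions(1)
        rows = tabulate_partner_frequencies(per_focus["ER"], "ER", 1.0)
        row = next(r for r in rows if r.partner == "n-TNM")
        assert (row.n_times, row.total, row.percent) == (2, 6, 33.33)
        assert sorted(row.years) == [5, 10]

    def test_smoking_alcohol_single_row_alpha1(self):
        per_focus = load_published_interactions(1)
        rows = tabulate_partner_frequencies(
            per_focus["Smoking/alcohol"], "Alcohol/smoking", 1.0
        )
        assert len(rows) == 1
        assert rows[0].partner == "LN positive/status"
        assert (rows[0].n_times, rows[0].total, rows[0].percent) == (1, 1, 100.00)

    def test_triple_contributes_two_partner_occurrences(self):
        rec = InteractionRecord(
            frozenset({"ER", "n_tnm_stage", "Surgical_margins"}), 5, 120.0
        )
        rows = tabulate_partner_frequencies([rec], "ER", 120.0)
        assert {r.partner for r in rows} == {"n-TNM", "Surgical margins"}
        assert all(r.total == 2 and r.percent == 50.0 for r in rows)

    def test_symmetry_of_shared_record_lists(self):
        records = [
            InteractionRecord(frozenset({"ER", "HER2"}), 5, 1.0),
            InteractionRecord(frozenset({"ER", "HER2"}), 15, 1.0),
            InteractionRecord(frozenset({"ER", "Stage", "HER2"}), 10, 1.0),
        ]
        er_rows = tabulate_partner_frequencies(records, "ER", 1.0)
        her2_rows = tabulate_partner_frequencies(records, "HER2", 1.0)
        er_as_partner = next(r.n_times for r in her2_rows if r.partner == "ER")
        her2_as_partner = next(r.n_times for r in er_rows if r.partner == "HER2")
        assert er_as_partner == her2_as_partner == 3

    def test_wrong_alpha_filtered_out(self):
        rec = InteractionRecord(frozenset({"ER", "HER2"}), 5, 120.0)
        assert tabulate_partner_frequencies([rec], "ER", 1.0) == []

    @given(st.lists(st.sampled_from(["HER2", "Stage", "Grade", "Side"]), min_size=1, max_size=30))
    def test_percent_definition_and_total(self, partners):
        from mbrisk.report import _round2

        records = [
            InteractionRecord(frozenset({"ER", p}), 5, 1.0) for p in partners
        ]
        rows = tabulate_partner_frequencies(records, "ER", 1.0)
        total = len(partners)
        assert all(r.total == total for r in rows)
        assert sum(r.n_times for r in rows) == total
        for r in rows:
            assert r.percent == _round2(100 * r.n_times / r.total)
            assert len(r.years) == r.n_times

    def test_printed_rounding_examples(self):
        # 2/7 -> 28.57, 6/23 -> 26.09 under round-half-away-from-zero
        from mbrisk.report import _round2

        assert _round2(100 * 2 / 7) == 28.57
        assert _round2(100 * 6 / 23) == 26.09
        assert _round2(100 * 1 / 12) == 8.33
        assert _round2(0.125 * 100 / 1) == 12.5


class TestRendering:
    @staticmethod
    def _results():
        single = InteractionResult(
            variables=frozenset({"Stage"}), log_score=-10.0,
            gain_over_best_subset=2.0, classification="single",
            alpha=480.0, horizon=5,
        )
        triple = InteractionResult(
            variables=frozenset({"ER", "n_tnm_stage", "Surgical_margins"}),
            log_score=-12.0, gain_over_best_subset=1.0,
            classification="interactive", alpha=480.0, horizon=5,
        )
        return {
            (5, 480.0): MarkovBlanketResult(
                direct_sets=[single, triple], other_interactions=[],
                horizon=5, alpha=480.0, log_score=-8.0,
            )
        }

    def test_empty_results_headers_only(self):
        text = render_causal_set_report({})
        assert "Direct causal sets" in text
        assert "alpha" not in text.splitlines()[-1]

    def test_triple_rendered_with_separators(self):
        text = render_causal_set_report(self._results())
        assert "ER × Surgical margins × n-TNM" in text
        assert "Stage" in text

    def test_deterministic(self):
        assert render_causal_set_report(self._results()) == render_causal_set_report(
            self._results()
        )

    def test_markdown_table(self):
        per_focus = load_published_interactions(1)
        rows = tabulate_partner_frequencies(per_focus["ER"], "ER", 1.0)
        text = render_frequency_table(rows)
        assert "| ER | n-TNM | 2 | 5, 10 | 6 | 33.33% |" in text

    def test_records_from_results(self):
        records = records_from_results(self._results())
        assert len(records) == 1  # singles are not interaction records
        assert records[0].variables == frozenset({"ER", "n_tnm_stage", "Surgical_margins"})
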