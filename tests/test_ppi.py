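"""PPI loading filters, set-semantic merging and network statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from e3prio.errors import InputError
from e3prio.ppi import (
    BIOGRID,
    STRING,
    UBIBROWSER_LIT,
    UBIBROWSER_PRED,
    TractabilitySet,
    e3_per_target,
    load_source_edges,
    merge_edges,
    percent_increase,
    target_space,
)


def _string_rows(scores):
    return pd.DataFrame(
        {"protein1": ["A"] * len(scores),
         "protein2": [f"B{i}" for i in range(len(scores))],
         "species": [9606] * len(scores),
         "combined_score": scores}
    )


class TestLoadFilters:
    def test_string_score_cutoff_is_strict(self):
        edges = load_source_edges(_string_rows([700, 701, 950]), STRING)
        assert sorted(edges["b"]) == ["B1", "B2"]
        assert (edges["score"] > 700).all()

    def test_predicted_esi_cutoff_is_strict(self):
        rows = pd.DataFrame(
            {"e3": ["E", "E"], "substrate": ["S1", "S2"],
             "species": ["Homo sapiens"] * 2, "confidence_score": [0.70, 0.71]}
        )
        edges = load_source_edges(rows, UBIBROWSER_PRED)
        assert edges["b"].tolist() == ["S2"]

    def test_literature_esis_kept_unconditionally(self):
        rows = pd.DataFrame(
            {"e3": ["E"], "substrate": ["S"], "species": ["Homo sapiens"]}
        )
        assert len(load_source_edges(rows, UBIBROWSER_LIT)) == 1

    def test_non_human_rows_dropped(self):
        rows = pd.DataFrame(
            {"symbol_a": ["A", "A"], "symbol_b": ["B", "C"],
             "organism_a": [9606, 9606], "organism_b": [9606, 10090],
             "experimental_system": ["Two hybrid", "Two hybrid"]}
        )
        edges = load_source_edges(rows, BIOGRID)
        assert edges["b"].tolist() == ["B"]

    def test_physical_flag_from_method_vocabulary(self):
        rows = pd.DataFrame(
            {"symbol_a": ["A", "A"], "symbol_b": ["B", "C"],
             "organism_a": [9606] * 2, "organism_b": [9606] * 2,
             "experimental_system": ["Two hybrid", "Co-fractionation"]}
        )
        edges = load_source_edges(rows, BIOGRID).set_index("b")
        assert bool(edges.loc["B", "physical"])
        assert not bool(edges.loc["C", "physical"])

    def test_malformed_row_skipped_with_warning(self, caplog):
        rows = pd.DataFrame(
            {"protein1": ["A"], "protein2": ["B"], "species": [9606],
             "combined_score": ["not-a-number"]}
        )
        with caplog.at_level("WARNING"):
            edges = load_source_edges(rows, STRING)
        assert edges.empty
        assert any("skipped" in r.message for r in caplog.records)

    def test_unknown_source_rejected(self):
        with pytest.raises(InputError):
            load_source_edges(pd.DataFrame(), "MYSTERY")


def _raw(rows):
    return pd.DataFrame(rows, columns=["a", "b", "source", "score", "physical"])


class TestMerge:
    def test_unordered_dedup_and_provenance_union(self):
        raw = _raw(
            [("VHL", "EGFR", STRING, 800.0, False),
             ("EGFR", "VHL", BIOGRID, np.nan, True)]
        )
        merged = merge_edges(raw)
        assert len(merged) == 1
        assert merged.loc[0, "sources"] == frozenset({STRING, BIOGRID})
        assert bool(merged.loc[0, "physical"])  # OR across sources

    def test_self_loops_removed_by_default(self):
        merged = merge_edges(_raw([("X", "X", STRING, 900.0, False)]))
        assert merged.empty
        kept = merge_edges(_raw([("X", "X", STRING, 900.0, False)]), keep_self_loops=True)
        assert len(kept) == 1

    def test_ten_row_fixture_matches_set_oracle(self):
        rows = [
            ("A", "B", STRING, 800.0, False), ("B", "A", BIOGRID, np.nan, True),
            ("A", "B", UBIBROWSER_LIT, np.nan, False), ("A", "C", STRING, 750.0, False),
            ("C", "A", STRING, 760.0, False), ("B", "C", BIOGRID, np.nan, False),
            ("D", "D", STRING, 900.0, False), ("A", "D", BIOGRID, np.nan, False),
            ("D", "A", BIOGRID, np.nan, False), ("C", "B", UBIBROWSER_LIT, np.nan, False),
        ]
        oracle = {frozenset(p) for a, b, *_ in rows if a != b for p in [(a, b)]}
        merged = merge_edges(_raw(rows))
        assert len(merged) == len(oracle)
        three_source = merged.set_index(["u", "v"]).loc[("A", "B"), "n_sources"]
        assert three_source == 3

    def test_order_invariance(self):
        rows = _raw(
            [("A", "B", STRING, 800.0, False), ("C", "A", BIOGRID, np.nan, True),
             ("B", "C", UBIBROWSER_LIT, np.nan, False)]
        )
        forward = merge_edges(rows)
        shuffled = merge_edges(rows.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(forward, shuffled)


class TestTargetSpace:
    def _edges(self):
        return merge_edges(
            _raw(
                [("E1", "T1", STRING, 800.0, False), ("E1", "T2", STRING, 800.0, False),
                 ("E2", "T2", BIOGRID, np.nan, False), ("E2", "E1", BIOGRID, np.nan, False),
                 ("E3", "T3", BIOGRID, np.nan, False)]
            )
        )

    def test_partners_of_set(self):
        edges = self._edges()
        assert target_space(edges, {"E1"}) == {"T1", "T2", "E2"} - {"E1"}
        assert target_space(edges, {"E1", "E2"}) == {"T1", "T2"}

    def test_empty_inputs(self):
        assert target_space(self._edges(), set()) == set()
        assert target_space(merge_edges(_raw([])), {"E1"}) == set()

    @settings(deadline=None, max_examples=40)
    @given(
        pairs=st.lists(
            st.tuples(st.sampled_from("ABCDE"), st.sampled_from("VWXYZ")), max_size=15
        ),
        s1=st.sets(st.sampled_from("ABCDE"), max_size=3),
        extra=st.sets(st.sampled_from("ABCDE"), max_size=2),
    )
    def test_monotone_in_the_e3_set(self, pairs, s1, extra):
        edges = merge_edges(
            _raw([(a, b, STRING, 800.0, False) for a, b in pairs])
        )
        small = target_space(edges, s1)
        big = target_space(edges, s1 | extra)
        assert len(small) <= len(big)


class TestStatistics:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(10930, 19248, 76.1), (100, 100, 0.0), (100, 250, 150.0), (3, 2, -33.3)],
    )
    def test_percent_increase(self, before, after, expected):
        assert percent_increase(before, after) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(InputError):
            percent_increase(0, 10)

    def test_e3_counts_and_median(self):
        edges = merge_edges(
            _raw(
                [("A", "T1", STRING, 800.0, False), ("B", "T1", STRING, 800.0, False),
                 ("C", "T1", STRING, 800.0, False), ("A", "T2", STRING, 800.0, False),
                 ("A", "T3", STRING, 800.0, False), ("B", "T3", STRING, 800.0, False),
                 ("D", "T3", STRING, 800.0, False)]
            )
        )
        counts, median = e3_per_target(edges, {"A", "C"})
        assert counts.to_dict() == {"T1": 2, "T2": 1, "T3": 1}
        assert median == 1

    def test_universe_includes_zero_count_targets(self):
        edges = merge_edges(_raw([("A", "T1", STRING, 800.0, False)]))
        counts, median = e3_per_target(edges, {"A"}, targets=["T1", "T2", "T3"])
        assert counts.to_dict() == {"T1": 1, "T2": 0, "T3": 0}
        assert median == 0

    def test_tractability_overlap_and_union(self):
        ts = TractabilitySet(frozenset("ABC"), frozenset("BCD"))
        assert ts.overlap == {"B", "C"}
        assert ts.union == {"A", "B", "C", "D"}
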