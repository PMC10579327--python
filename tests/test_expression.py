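"""Expression classification, selectivity integration and composition."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from e3prio.errors import ConfigError, InputError
from e3prio.expression import (
    HIGH,
    LOW,
    bulk_tissue_level,
    bulk_tissue_medians,
    classify_bulk,
    classify_hpa,
    classify_sc_tissue,
    composition_from_counts,
    derive_sc_thresholds,
    expression_flags,
    low_in_majority,
    tumor_selectivity,
)


class TestBulk:
    def test_median_levels(self):
        matrix = pd.DataFrame(
            [[3.0, 4.0, 5.0, 3.0, 5.0, 7.2]],
            index=["G"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = pd.Series(
            ["liver", "liver", "liver", "lung", "lung", "skin"],
            index=matrix.columns,
        )
        assert bulk_tissue_level(matrix, labels, "G", "liver") == 4.0
        assert bulk_tissue_level(matrix, labels, "G", "lung") == 4.0
        assert bulk_tissue_level(matrix, labels, "G", "skin") == 7.2
        medians = bulk_tissue_medians(matrix, labels)
        assert medians.loc["G"].tolist() == [4.0, 4.0, 7.2]

    def test_unlabeled_tissue_is_an_error(self):
        matrix = pd.DataFrame([[1.0]], index=["G"], columns=["s0"])
        with pytest.raises(InputError):
            bulk_tissue_level(matrix, pd.Series({"s0": "liver"}), "G", "brain")

    @pytest.mark.parametrize(
        "level, call", [(4.0, LOW), (4.01, HIGH), (0.0, LOW), (9.9, HIGH)]
    )
    def test_high_call_is_strictly_above_four(self, level, call):
        assert classify_bulk(level) == call


class TestHpa:
    def test_printed_examples(self):
        # 10 of 11 and 11 of 12 medium/high samples are High
        assert classify_hpa(["high"] * 10 + ["low"]) == HIGH
        assert classify_hpa(["high"] * 11 + ["not_detected"]) == HIGH
        assert classify_hpa(["medium"] + ["low"] * 9) == LOW

    def test_twenty_percent_boundary_inclusive_by_default(self):
        calls = ["medium", "high"] + ["low"] * 8
        assert classify_hpa(calls) == HIGH
        assert classify_hpa(calls, strict=True) == LOW

    def test_empty_or_unknown_calls_rejected(self):
        with pytest.raises(InputError):
            classify_hpa([])
        with pytest.raises(InputError):
            classify_hpa(["strong"])


class TestScThresholds:
    def test_reference_pattern_scaling(self):
        thr = derive_sc_thresholds(17, 3.1, 0.75)
        assert thr.frac_pct_threshold == pytest.approx(12.75)
        assert thr.mean_threshold == pytest.approx(2.325)

    @pytest.mark.parametrize(
        "frac, mean, scale, expected",
        [(17, 3.1, 1.0, (17, 3.1)), (10, 2, 0.5, (5.0, 1.0))],
    )
    def test_scaling_examples(self, frac, mean, scale, expected):
        thr = derive_sc_thresholds(frac, mean, scale)
        assert (thr.frac_pct_threshold, thr.mean_threshold) == pytest.approx(expected)

    def test_scaling_is_linear(self):
        one = derive_sc_thresholds(13, 2.0, 0.4)
        two = derive_sc_thresholds(13, 2.0, 0.8)
        assert two.frac_pct_threshold == pytest.approx(2 * one.frac_pct_threshold)
        assert two.mean_threshold == pytest.approx(2 * one.mean_threshold)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ConfigError):
            derive_sc_thresholds(0, 3.1, 0.75)
        with pytest.raises(ConfigError):
            derive_sc_thresholds(17, 3.1, -1)


class TestScClassification:
    def test_both_criteria_above(self):
        cells = np.concatenate([np.full(13, 2.4), np.zeros(87)])
        assert classify_sc_tissue(cells) == HIGH

    def test_fraction_boundary_is_strict(self):
        cells = np.concatenate([np.full(51, 3.0), np.zeros(349)])  # exactly 12.75%
        assert classify_sc_tissue(cells) == LOW

    def test_mean_must_exceed_threshold(self):
        cells = np.concatenate([np.full(50, 2.0), np.zeros(50)])
        assert classify_sc_tissue(cells) == LOW

    def test_empty_vector_rejected(self):
        with pytest.raises(InputError):
            classify_sc_tissue(np.array([]))

    @settings(deadline=None, max_examples=40)
    @given(
        k=st.integers(min_value=1, max_value=40),
        mean=st.floats(min_value=0.5, max_value=5.0),
        bump=st.floats(min_value=0.0, max_value=2.0),
    )
    def test_monotone_in_fraction_and_mean(self, k, mean, bump):
        base = np.concatenate([np.full(k, mean), np.zeros(40 - k)]) if k < 40 else np.full(40, mean)
        call = classify_sc_tissue(base)
        if call == HIGH:
            # raising the mean or filling in another cell keeps the call High
            assert classify_sc_tissue(np.where(base > 0, base + bump, 0.0)) == HIGH
            more = base.copy()
            if (more == 0).any():
                more[np.argmin(more > 0)] = mean + bump
                assert classify_sc_tissue(more) == HIGH


class TestIntegration:
    def test_low_majority_rule(self):
        assert low_in_majority({f"t{i}": LOW for i in range(7)} | {f"u{i}": HIGH for i in range(3)})
        assert not low_in_majority(
            {f"t{i}": LOW for i in range(6)} | {f"u{i}": HIGH for i in range(4)}
        )
        assert low_in_majority({"a": LOW, "b": LOW})

    def test_empty_profile_is_false_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert low_in_majority({}) is False
        assert caplog.records

    def test_selectivity_requires_all_four_conditions(self):
        high1 = {"c1": HIGH, "c2": LOW}
        all_low = {f"t{i}": LOW for i in range(10)}
        all_high = {f"t{i}": HIGH for i in range(10)}
        assert tumor_selectivity(high1, high1, all_low, all_low)
        assert not tumor_selectivity(high1, high1, all_high, all_low)
        assert not tumor_selectivity({"c1": LOW}, high1, all_low, all_low)
        assert not tumor_selectivity(high1, None, all_low, all_low)

    @settings(deadline=None, max_examples=40)
    @given(st.tuples(*[st.booleans()] * 4))
    def test_selective_flag_equals_conjunction(self, flags):
        any_tcga, any_hpa, low_gtex, low_tabula = flags
        tcga = {"c": HIGH if any_tcga else LOW}
        hpa = {"c": HIGH if any_hpa else LOW}
        gtex = {f"t{i}": (LOW if low_gtex else HIGH) for i in range(10)}
        tabula = {f"t{i}": (LOW if low_tabula else HIGH) for i in range(10)}
        assert tumor_selectivity(tcga, hpa, gtex, tabula) == all(flags)

    def test_flag_table_matches_direct_recomputation(self):
        calls = lambda d: pd.DataFrame(d).T  # noqa: E731
        tcga = calls({"G1": {"c1": HIGH, "c2": LOW}, "G2": {"c1": LOW, "c2": LOW}})
        hpa = calls({"G1": {"c1": HIGH, "c2": HIGH}, "G2": {"c1": HIGH, "c2": LOW}})
        gtex = calls({"G1": {f"t{i}": LOW for i in range(10)},
                      "G2": {f"t{i}": HIGH for i in range(10)}})
        tabula = calls({"G1": {f"t{i}": LOW for i in range(10)},
                        "G2": {f"t{i}": LOW for i in range(10)}})
        flags = expression_flags(tcga, hpa, gtex, tabula)
        for g in ("G1", "G2"):
            assert flags.loc[g, "tumor_selective"] == tumor_selectivity(
                tcga.loc[g], hpa.loc[g], gtex.loc[g], tabula.loc[g]
            )
        assert flags.loc["G1", "tumor_selective"]
        assert not flags.loc["G2", "tumor_selective"]


class TestComposition:
    def test_breast_cancer_worked_example(self):
        """Counts printed for a malignant-enriched demethylase-type ligase:
        2448/4099 malignant, 25/241 immune, 5/35 other expressing cells."""
        comp = composition_from_counts(
            {"malignant": (2448, 4099), "immune": (25, 241), "other": (5, 35)}
        )
        assert comp.loc["malignant", "pct_of_expressing"] == 98.8
        assert comp.loc["malignant", "pct_within_group"] == 59.7
        assert comp.loc["immune", "pct_within_group"] == 10.4
        assert comp.loc["other", "pct_within_group"] == 14.3
        assert comp["pct_of_expressing"].sum() == pytest.approx(100.0, abs=0.1)

    def test_all_expressing_cells_in_one_group(self):
        comp = composition_from_counts({"malignant": (10, 20), "immune": (0, 30)})
        assert comp.loc["malignant", "pct_of_expressing"] == 100.0

    def test_zero_expressing_cells_flagged(self):
        comp = composition_from_counts({"malignant": (0, 20), "immune": (0, 30)})
        assert comp.attrs["no_expressing_cells"]
        assert comp["pct_of_expressing"].isna().all()

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(50, 100)), min_size=2, max_size=5
        )
    )
    def test_shares_sum_to_hundred(self, counts):
        groups = {f"g{i}": kn for i, kn in enumerate(counts)}
        comp = composition_from_counts(groups)
        if not comp.attrs["no_expressing_cells"]:
            assert comp["pct_of_expressing"].sum() == pytest.approx(100.0, abs=0.1 * len(groups))
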