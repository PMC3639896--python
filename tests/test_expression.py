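"""Abundance, fold-change (n.d. rule), DE calling, and pathway summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirtarget import (
    ND,
    UNDEFINED,
    ExpressionRecord,
    InputError,
    SimulationConfig,
    annotate_expression,
    classify_de,
    fold_change,
    relative_abundance,
    simulate_counts,
    summarize_pathways,
)


class TestRelativeAbundance:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 5], [500_000, 500_000]), ([1, 0, 3], [250_000, 0, 750_000])],
    )
    def test_per_million_scaling(self, counts, expected):
        np.testing.assert_allclose(relative_abundance(counts), expected)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            relative_abundance([0, 0])

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            relative_abundance([1, -2])

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=50).filter(lambda x: sum(x) > 0))
    def test_sums_to_one_million(self, counts):
        assert relative_abundance(counts).sum() == pytest.approx(1e6, rel=1e-6)


class TestFoldChange:
    def test_zero_control_is_nd(self):
        assert fold_change(10, 0) is ND

    def test_ordinary_ratio(self):
        assert fold_change(4, 2) == 2.0

    def test_zero_both_is_undefined(self):
        assert fold_change(0, 0) is UNDEFINED

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            fold_change(-1, 2)

    @given(
        st.floats(0.001, 1e6),
        st.floats(0.001, 1e6),
    )
    def test_nd_never_with_positive_control(self, e, n):
        assert fold_change(e, n) == e / n  # finite, never a sentinel


def _rec(non, eli, p=None):
    return ExpressionRecord("x", non, eli, p)


class TestClassifyDE:
    @pytest.mark.parametrize(
        "non,eli,p,expected",
        [
            (10, 20, 0.04, "up"),          # fold exactly 2.0, inclusive
            (10, 19, 0.001, "unchanged"),  # fold 1.9 below threshold
            (10, 4, 0.01, "down"),         # fold 0.4 <= 1/2
            (10, 5, 0.01, "down"),         # fold 0.5 boundary, inclusive
            (10, 20, 0.05, "up"),          # p boundary inclusive
            (10, 20, 0.051, "unchanged"),  # p criterion fails
            (0, 7, 0.01, "up"),            # n.d. counts as up
            (0, 7, 0.5, "unchanged"),      # n.d. still needs the p criterion
            (0, 0, 0.01, "unchanged"),     # undefined excluded
        ],
    )
    def test_twofold_convention(self, non, eli, p, expected):
        assert classify_de(_rec(non, eli, p)) == expected

    def test_p_criterion_skipped_when_absent(self):
        assert classify_de(_rec(10, 20)) == "up"
        assert classify_de(_rec(10, 5)) == "down"

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            classify_de(_rec(10, 20, 1.2))

    @given(
        st.floats(0.1, 1e4),
        st.floats(0, 1e4),
        st.floats(1.001, 100),
    )
    def test_scale_invariance(self, non, eli, scale):
        base = classify_de(_rec(non, eli, 0.01))
        scaled = classify_de(_rec(non * scale, eli * scale, 0.01))
        assert base == scaled


class TestAnnotateExpression:
    def test_columns_and_flags(self):
        df = pd.DataFrame(
            {
                # both libraries total 500, so folds equal the count ratios
                "id": ["a", "b", "c", "d", "e"],
                "count_nonelicited": [100, 0, 50, 0, 350],
                "count_elicited": [400, 30, 25, 0, 45],
                "adjusted_p": [0.01, 0.01, 0.01, 0.01, 0.01],
            }
        )
        out = annotate_expression(df)
        assert list(out["direction"]) == ["up", "up", "down", "unchanged", "down"]
        assert list(out["fold_status"]) == ["ok", "nd", "ok", "undefined", "ok"]
        assert list(out["nd_flag"]) == [False, True, False, False, False]
        assert out["p_criterion_used"].all()
        assert math.isnan(out.loc[1, "fold"])

    def test_abundance_input_mode(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "abundance_nonelicited": [100.0, 10.0],
                "abundance_elicited": [300.0, 10.0],
            }
        )
        out = annotate_expression(df, input_is_counts=False)
        assert list(out["direction"]) == ["up", "unchanged"]
        assert not out["p_criterion_used"].any()

    def test_missing_column_rejected(self):
        with pytest.raises(InputError, match="count_elicited"):
            annotate_expression(pd.DataFrame({"id": ["a"], "count_nonelicited": [1]}))


def _toy_pathways():
    """Five pathways with hand-computed labels at the fourfold threshold."""
    df = pd.DataFrame(
        {
            "id": list("abcdefghijk"),
            "count_nonelicited": [10, 10, 10, 40, 80, 10, 0, 10, 10, 10, 100],
            "count_elicited": [50, 62, 2, 10, 8, 30, 12, 35, 11, 0, 80],
            "adjusted_p": [0.01] * 11,
        }
    )
    # both libraries total 300, so per-million folds equal the count ratios:
    # a 5.0, b 6.2, c 0.2, d 0.25, e 0.1, f 3.0, g n.d., h 3.5, i 1.1, j 0.0, k 0.8
    annotated = annotate_expression(df)
    pathway_map = pd.DataFrame(
        [
            ("pw_up", "a"), ("pw_up", "b"),          # both >= 4x up  -> increased
            ("pw_down", "c"), ("pw_down", "d"),      # 0.2, 0.25 down -> decreased
            ("pw_mix", "b"), ("pw_mix", "e"),        # 6.2x up + 0.1x down -> mixed
            ("pw_sub", "f"), ("pw_sub", "h"),        # 3.0/3.5: DE but < 4x -> none
            ("pw_nd", "g"), ("pw_nd", "i"),          # n.d. counts as up -> increased
        ],
        columns=["pathway_id", "member_id"],
    )
    expected = {
        "pw_up": ("increased", 2, 0),
        "pw_down": ("decreased", 0, 2),
        "pw_mix": ("mixed", 1, 1),
        "pw_sub": ("none", 0, 0),
        "pw_nd": ("increased", 1, 0),
    }
    return annotated, pathway_map, expected


class TestSummarizePathways:
    def test_hand_computed_labels(self):
        annotated, pathway_map, expected = _toy_pathways()
        out = summarize_pathways(annotated, pathway_map)
        for row in out.itertuples(index=False):
            cls, n_up, n_down = expected[row.pathway_id]
            assert row.classification == cls, row.pathway_id
            assert (row.n_up, row.n_down) == (n_up, n_down)
            assert row.n_up + row.n_down <= row.n_members

    def test_missing_members_counted(self):
        annotated, pathway_map, _ = _toy_pathways()
        pathway_map = pd.concat(
            [pathway_map, pd.DataFrame([("pw_up", "zz")], columns=pathway_map.columns)]
        )
        out = summarize_pathways(annotated, pathway_map)
        row = out[out.pathway_id == "pw_up"].iloc[0]
        assert row.n_missing == 1 and row.n_members == 3

    def test_shared_member_counts_in_both_pathways(self):
        annotated, pathway_map, _ = _toy_pathways()
        out = summarize_pathways(annotated, pathway_map)
        # member "b" belongs to pw_up and pw_mix and is counted in both
        assert out[out.pathway_id == "pw_up"].iloc[0].n_up == 2
        assert out[out.pathway_id == "pw_mix"].iloc[0].n_up == 1


class TestParameterRecovery:
    def test_fold4_recovery_on_observed_counts(self):
        """Planted 4x genes are recovered from NB counts at low dispersion."""
        # keep the regulated mass small: per-million normalization is
        # composition-sensitive, so heavy one-sided regulation would deflate
        # every observed fold (no TMM-style correction in this convention)
        cfg = SimulationConfig(
            seed=101,
            n_genes=200,
            fold_tiers=((1.0, 180), (4.0, 20)),
            mean_range=(500.0, 5000.0),
            dispersion=0.01,
        )
        table, truth = simulate_counts(cfg)
        annotated = annotate_expression(table)
        merged = annotated.merge(truth, on="id")
        planted = merged[merged.true_fold == 4.0]
        nulls = merged[merged.true_fold == 1.0]
        recovery = (planted.direction == "up").mean()
        false_rate = (nulls.direction != "unchanged").mean()
        assert recovery >= 0.95
        assert false_rate <= 0.05
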