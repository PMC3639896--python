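"""Duplex scoring and the four-rule verdict engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirtarget import (
    ConfigError,
    InputError,
    MiRNA,
    PairState,
    RuleConfig,
    build_site,
    evaluate_rules,
    normalize_sequence,
    pair_state,
    reverse_complement,
    score_duplex,
)

from _rule_oracle import brute_force_flags
from conftest import random_mirna

rna = st.text(alphabet="ACGU", min_size=12, max_size=24)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [("acgt", "ACGU"), ("ACGU", "ACGU"), ("AcGuTn", "ACGUUN")],
    )
    def test_case_and_alphabet(self, raw, expected):
        assert normalize_sequence(raw) == expected

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            normalize_sequence("")

    def test_illegal_character_names_position(self):
        with pytest.raises(InputError, match="position 3"):
            normalize_sequence("ACXG")


class TestPairState:
    @pytest.mark.parametrize(
        "m,t,state",
        [
            ("A", "U", PairState.MATCH),
            ("U", "A", PairState.MATCH),
            ("G", "C", PairState.MATCH),
            ("C", "G", PairState.MATCH),
            ("G", "U", PairState.GU),
            ("U", "G", PairState.GU),
            ("A", "C", PairState.MISMATCH),
            ("A", "A", PairState.MISMATCH),
            ("N", "A", PairState.MISMATCH),
            ("G", "N", PairState.MISMATCH),
        ],
    )
    def test_classification(self, m, t, state):
        assert pair_state(m, t) is state

    def test_unnormalized_base_rejected(self):
        with pytest.raises(InputError):
            pair_state("T", "A")


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self, gu_rich_mirna):
        site = reverse_complement(gu_rich_mirna.sequence)
        d = score_duplex(gu_rich_mirna, site)
        assert d.score == 0.0
        assert all(s is PairState.MATCH for s in d.states)
        assert (d.n_match, d.n_gu, d.n_mismatch) == (21, 0, 0)

    def test_two_mismatch_one_gu_scores_two_point_five(self, gu_rich_mirna):
        site = build_site(gu_rich_mirna, {13, 15}, {2})
        d = score_duplex(gu_rich_mirna, site)
        assert (d.n_mismatch, d.n_gu) == (2, 1)
        assert d.score == 2.5

    def test_length_mismatch_rejected(self, gu_rich_mirna):
        with pytest.raises(InputError):
            score_duplex(gu_rich_mirna, "ACGU")

    def test_antiparallel_orientation(self):
        # miRNA 5' base pairs the site's 3' base
        m = MiRNA("m", "AAAAAAAAAAAG")
        site = "C" + "U" * 11  # site 3' end is U, pairing miRNA pos 1 (A)
        d = score_duplex(m, site)
        assert d.states[0] is PairState.MATCH  # A:U at miRNA pos 1
        assert d.states[11] is PairState.MATCH  # G:C at miRNA pos 12


# Boundary suite: mismatch/G:U configurations built on the G/U-rich miRNA.
# Flags tuple is (pass_total, pass_contiguous, pass_seed, pass_central).
BOUNDARY_CASES = [
    # rule i: weighted total score, inclusive at 4.0 (G:U = 0.5)
    ("score_4.0_passes", {13, 15, 17}, {2, 5}, (True, True, True, True)),
    ("score_4.0_alt", {13, 16, 19}, {2, 5}, (True, True, True, True)),
    ("score_4.5_fails", {13, 15, 17, 19}, {2}, (False, True, True, True)),
    ("score_5.0_fails", {13, 15, 17, 19}, {2, 5}, (False, True, True, True)),
    ("eight_gu_score_4.0", set(), {1, 2, 3, 4, 5, 6, 8, 9}, (True, True, True, True)),
    ("nine_gu_score_4.5", set(), {1, 2, 3, 4, 5, 6, 8, 9, 12}, (False, True, True, True)),
    # rule ii: contiguous mismatches, at most 2
    ("run_of_2_passes", {13, 14}, set(), (True, True, True, True)),
    ("run_of_3_fails", {13, 14, 15}, set(), (True, False, True, True)),
    ("run_of_3_alt", {14, 15, 16}, set(), (True, False, True, True)),
    # rule iii: seed (positions 1-9), at most 1 mismatch
    ("one_seed_mm_passes", {5}, set(), (True, True, True, True)),
    ("two_seed_mm_fail", {2, 5}, set(), (True, True, False, True)),
    # rule iv context: wobbles do not count positionally by default
    ("seed_gu_not_counted", set(), {2, 5}, (True, True, True, True)),
    # central positions 10-11: no mismatch at all
    ("mm_at_10_fails", {10}, set(), (True, True, True, False)),
    ("mm_at_11_fails", {11}, set(), (True, True, True, False)),
    ("gu_at_11_passes", set(), {11}, (True, True, True, True)),
    ("perfect_passes", set(), set(), (True, True, True, True)),
    ("seed_and_central_fail", {2, 5, 10}, set(), (True, True, False, False)),
]


class TestRuleBoundaries:
    @pytest.mark.parametrize(
        "label,mm,gu,flags", BOUNDARY_CASES, ids=[c[0] for c in BOUNDARY_CASES]
    )
    def test_boundary(self, gu_rich_mirna, label, mm, gu, flags):
        d = score_duplex(gu_rich_mirna, build_site(gu_rich_mirna, mm, gu))
        v = evaluate_rules(d)
        assert (v.pass_total, v.pass_contiguous, v.pass_seed, v.pass_central) == flags
        assert v.passed == all(flags)
        # cross-check against the independent brute-force checker
        assert brute_force_flags(d.states, RuleConfig()) == flags

    def test_gu_counts_in_positional_rules_flag(self, gu_rich_mirna):
        cfg = RuleConfig(gu_counts_in_positional_rules=True)
        d = score_duplex(gu_rich_mirna, build_site(gu_rich_mirna, set(), {2, 5}))
        v = evaluate_rules(d, cfg)
        assert not v.pass_seed  # two seed wobbles now count as mismatches
        assert evaluate_rules(d).pass_seed  # default reading tolerates them

    def test_region_beyond_mirna_length_rejected(self):
        m = MiRNA("m", "ACGUACGUACGU")  # 12 nt
        d = score_duplex(m, reverse_complement(m.sequence))
        with pytest.raises(ConfigError):
            evaluate_rules(d, RuleConfig(central_region=(13, 14)))


class TestRuleConfig:
    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            RuleConfig(max_total_score=-1)

    def test_mapping_round_trip(self):
        cfg = RuleConfig(max_total_score=3.5, gu_counts_in_positional_rules=True)
        assert RuleConfig.from_mapping(cfg.to_mapping()) == cfg


class TestProperties:
    @given(data=st.data())
    def test_recount_from_states(self, data):
        """Stored counts and score are recomputable from the states."""
        mseq = data.draw(rna)
        m = MiRNA("m", mseq)
        site = data.draw(
            st.text(alphabet="ACGUN", min_size=len(mseq), max_size=len(mseq))
        )
        d = score_duplex(m, site)
        L = len(mseq)
        n_match = sum(s is PairState.MATCH for s in d.states)
        n_gu = sum(s is PairState.GU for s in d.states)
        n_mm = sum(s is PairState.MISMATCH for s in d.states)
        assert (d.n_match, d.n_gu, d.n_mismatch) == (n_match, n_gu, n_mm)
        assert n_match + n_gu + n_mm == L
        assert d.score == n_mm + 0.5 * n_gu >= 0
        assert d.max_run_mismatch <= d.n_mismatch

    @given(data=st.data())
    def test_match_to_mismatch_monotone(self, data):
        """Breaking a match never lowers the score or revives a failing duplex."""
        mseq = data.draw(st.text(alphabet="ACGU", min_size=12, max_size=24))
        m = MiRNA("m", mseq)
        site = list(reverse_complement(mseq))
        L = len(mseq)
        # degrade a few random positions first
        for p in data.draw(
            st.lists(st.integers(1, L), max_size=6, unique=True)
        ):
            b = mseq[p - 1]
            site[L - p] = {"A": "C", "C": "A", "G": "G", "U": "U"}[b]
        before = score_duplex(m, "".join(site))
        match_positions = [
            i + 1 for i, s in enumerate(before.states) if s is PairState.MATCH
        ]
        if not match_positions:
            return
        p = data.draw(st.sampled_from(match_positions))
        site[L - p] = {"A": "C", "C": "A", "G": "G", "U": "U"}[mseq[p - 1]]
        after = score_duplex(m, "".join(site))
        assert after.score >= before.score
        if not evaluate_rules(before).passed:
            assert not evaluate_rules(after).passed

    @given(data=st.data())
    def test_gu_only_duplexes(self, data):
        """No-mismatch duplexes pass all positional rules; total iff n_gu <= 8."""
        mseq = data.draw(st.text(alphabet="GU", min_size=12, max_size=24))
        m = MiRNA("m", mseq)
        gu = data.draw(
            st.sets(st.integers(1, len(mseq)), max_size=len(mseq))
        )
        d = score_duplex(m, build_site(m, set(), gu))
        assert d.n_mismatch == 0
        v = evaluate_rules(d)
        assert v.pass_contiguous and v.pass_seed and v.pass_central
        assert v.pass_total == (d.n_gu <= 8)

    def test_agreement_with_brute_force_on_random_duplexes(self):
        """Verdict engine matches the independent checker on 10^4 duplexes."""
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGUN"))
        cfgs = [RuleConfig(), RuleConfig(gu_counts_in_positional_rules=True)]
        for _ in range(10_000):
            m = random_mirna(rng)
            site = "".join(rng.choice(bases, len(m), p=[0.3, 0.3, 0.2, 0.15, 0.05]))
            d = score_duplex(m, site)
            for cfg in cfgs:
                v = evaluate_rules(d, cfg)
                assert (
                    v.pass_total,
                    v.pass_contiguous,
                    v.pass_seed,
                    v.pass_central,
                ) == brute_force_flags(d.states, cfg)
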