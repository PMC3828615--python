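"""Differential-expression callers: DS vote rule, SSH and MA thresholds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mirmarker.diffexp import (
    ArraySignalTable,
    RatioProfile,
    SshPair,
    Status,
    Tier,
    load_array_signals,
    load_ssh_pairs,
    location_test,
    ma_differential,
    per_sample_ratios,
    save_array_signals,
    save_ssh_pairs,
    ssh_differential,
    vote_classify,
)
from mirmarker.smallrna import CountTable


def vote_oracle(ratios, tier):
    """Direct enumeration of the vote rule, independent of vote_classify."""
    up = len([r for r in ratios if r > tier.up_cut])
    down = len([r for r in ratios if r < tier.down_cut])
    if up > down:
        return Status.UP, up, down
    if down > up:
        return Status.DOWN, up, down
    if up > 0:
        return Status.MIXED, up, down
    return Status.NEUTRAL, up, down


def make_profile(ratios, mirna="mirx"):
    return RatioProfile(mirna_id=mirna, ratios={f"s{i}": r for i, r in enumerate(ratios)})


class TestPerSampleRatios:
    @pytest.fixture
    def counts(self):
        raw = pd.DataFrame(
            {
                "t1": {"mira": 40.0, "mirb": 7.0, "mirc": 0.0},
                "t2": {"mira": 10.0, "mirb": 0.0, "mirc": 0.0},
                "normal_pool": {"mira": 10.0, "mirb": 0.0, "mirc": 0.0},
            }
        )
        # equal totals so RPM ratios equal raw ratios
        totals = pd.Series({"t1": 100.0, "t2": 100.0, "normal_pool": 100.0})
        return CountTable.from_raw(raw, total_mapped=totals)

    def test_plain_ratio(self, counts):
        profiles = per_sample_ratios(counts, ["t1", "t2"], "normal_pool")
        assert profiles["mira"].ratios["t1"] == pytest.approx(4.0)

    def test_zero_denominator_gives_infinity(self, counts):
        prof = per_sample_ratios(counts, ["t1", "t2"], "normal_pool")["mirb"]
        assert math.isinf(prof.ratios["t1"])
        assert "t1" in prof.denominator_zero

    def test_both_zero_excluded(self, counts):
        prof = per_sample_ratios(counts, ["t1", "t2"], "normal_pool")["mirc"]
        assert not prof.assessed
        assert prof.excluded == {"t1", "t2"}

    def test_unknown_sample_rejected(self, counts):
        with pytest.raises(KeyError):
            per_sample_ratios(counts, ["t1", "nope"], "normal_pool")


class TestVoteClassify:
    def test_majority_up(self):
        call = vote_classify(make_profile([3, 4, 0.2]), Tier.SOFT)
        assert (call.status, call.up_votes, call.down_votes) == (Status.UP, 2, 1)

    def test_tied_votes_mixed(self):
        assert vote_classify(make_profile([3, 0.2]), Tier.SOFT).status == Status.MIXED

    def test_tier_changes_the_call(self):
        profile = make_profile([2.5, 2.5, 0.2])
        assert vote_classify(profile, Tier.SOFT).status == Status.UP
        assert vote_classify(profile, Tier.MEDIUM).status == Status.DOWN

    def test_infinite_ratio_votes_up_at_every_tier(self):
        for tier in Tier:
            call = vote_classify(make_profile([math.inf]), tier)
            assert call.status == Status.UP and call.up_votes == 1

    def test_unassessed_profile_returns_none(self):
        prof = RatioProfile(mirna_id="m", excluded={"s0"})
        assert vote_classify(prof, Tier.SOFT) is None

    def test_vote_accounting_partitions_samples(self):
        call = vote_classify(make_profile([3, 1.0, 0.2, 5, 0.7]), Tier.SOFT)
        assert call.up_votes + call.down_votes + call.neutral_votes == 5

    @given(
        st.lists(
            st.one_of(
                st.floats(min_value=0, max_value=10, allow_nan=False),
                st.just(math.inf),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_enumeration_and_votes_shrink_with_stricter_tiers(self, ratios):
        profile = make_profile(ratios)
        prev_up = prev_down = None
        for tier in [Tier.SOFT, Tier.MEDIUM, Tier.STRICT]:
            call = vote_classify(profile, tier)
            status, up, down = vote_oracle(ratios, tier)
            assert (call.status, call.up_votes, call.down_votes) == (status, up, down)
            if prev_up is not None:
                assert call.up_votes <= prev_up and call.down_votes <= prev_down
            prev_up, prev_down = call.up_votes, call.down_votes


class TestSshDifferential:
    def test_up_call(self):
        call = ssh_differential(SshPair("m", 12, 4))
        assert call.status == Status.UP and call.fold == pytest.approx(3.0)

    def test_below_total_threshold_not_assessed(self):
        assert ssh_differential(SshPair("m", 8, 1)) is None

    def test_ratio_one_neutral(self):
        assert ssh_differential(SshPair("m", 6, 6)).status == Status.NEUTRAL

    def test_exact_fold_boundaries_inclusive(self):
        assert ssh_differential(SshPair("m", 6, 4)).status == Status.UP  # 1.5 exactly
        assert ssh_differential(SshPair("m", 4, 6)).status == Status.DOWN

    def test_zero_normal_counts_as_up(self):
        assert ssh_differential(SshPair("m", 10, 0)).status == Status.UP

    def test_each_mode_is_stricter(self):
        pair = SshPair("m", 25, 5)
        assert ssh_differential(pair, total_mode="sum") is not None
        assert ssh_differential(pair, total_mode="each") is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            SshPair("m", -1, 5)

    @given(st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, c):
        base = SshPair("m", 30, 12)
        scaled = SshPair("m", 30 * c, 12 * c)
        # scale far enough above the gate that both stay assessed
        if 30 * c + 12 * c >= 10:
            assert ssh_differential(scaled, min_total=0).status == \
                ssh_differential(base, min_total=0).status


class TestLocationTest:
    def test_degenerate_equal_groups(self):
        assert location_test([100, 100, 100], [100, 100, 100]) == 1.0

    def test_symmetry(self):
        a, b = [200, 210, 190, 205], [100, 95, 105, 100]
        assert location_test(a, b) == pytest.approx(location_test(b, a))

    def test_clear_separation_below_0_01(self):
        a, b = [200, 210, 190, 205], [100, 95, 105, 100]
        p = location_test(a, b)
        # independent Welch computation on log2 values
        la, lb = np.log2(a), np.log2(b)
        va, vb = la.var(ddof=1) / 4, lb.var(ddof=1) / 4
        t = (la.mean() - lb.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        expected = 2 * sps.t.sf(abs(t), df)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p < 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            location_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            location_test([0.0, 1.0], [2.0, 3.0])


class TestMaDifferential:
    def _table(self, tumors, normals, probe="mir21"):
        cols = {f"t{i}": {probe: v} for i, v in enumerate(tumors)}
        cols |= {f"n{i}": {probe: v} for i, v in enumerate(normals)}
        return ArraySignalTable(
            signals=pd.DataFrame(cols),
            tumor_ids=[f"t{i}" for i in range(len(tumors))],
            normal_ids=[f"n{i}" for i in range(len(normals))],
        )

    def test_two_fold_tight_spread_up(self):
        table = self._table([200, 210, 190, 205], [100, 95, 105, 100])
        call = ma_differential(table)["mir21"]
        assert call.status == Status.UP
        assert call.fold == pytest.approx(201.25 / 100)

    def test_high_variance_fails_p_criterion(self):
        table = self._table([600, 20, 900, 40], [100, 95, 105, 100])
        call = ma_differential(table)["mir21"]
        assert call.fold > 1.5 and call.pvalue > 0.01
        assert call.status == Status.NEUTRAL

    def test_small_fold_fails_fold_criterion(self):
        table = self._table([120, 121, 119, 120], [100, 99, 101, 100])
        call = ma_differential(table)["mir21"]
        assert call.pvalue < 0.01 and call.status == Status.NEUTRAL

    def test_per_sample_ratios_reported_for_neutral_probes(self):
        table = self._table([120, 121, 119, 120], [100, 99, 101, 100])
        call = ma_differential(table)["mir21"]
        assert call.ratios == pytest.approx((1.2, 1.21, 1.19, 1.2))

    def test_scale_invariance(self):
        t, n = [200, 210, 190, 205], [100, 95, 105, 100]
        c1 = ma_differential(self._table(t, n))["mir21"]
        c2 = ma_differential(self._table([x * 7 for x in t], [x * 7 for x in n]))["mir21"]
        assert c1.status == c2.status
        assert c1.pvalue == pytest.approx(c2.pvalue)

    def test_group_size_validation(self):
        table = self._table([100, 100], [100])
        with pytest.raises(ValueError):
            ma_differential(table)


def test_ssh_and_array_tsv_round_trips(tmp_path):
    pairs = [SshPair("mir205", 120, 30), SshPair("mir100", 0, 0)]
    save_ssh_pairs(pairs, tmp_path / "ssh.tsv")
    assert load_ssh_pairs(tmp_path / "ssh.tsv") == pairs

    table = ArraySignalTable(
        signals=pd.DataFrame({"t1": {"m": 1.0}, "t2": {"m": 2.0}, "n1": {"m": 3.0}, "n2": {"m": 4.0}}),
        tumor_ids=["t1", "t2"],
        normal_ids=["n1", "n2"],
    )
    save_array_signals(table, tmp_path / "sig.tsv", tmp_path / "cond.tsv")
    back = load_array_signals(tmp_path / "sig.tsv", tmp_path / "cond.tsv")
    assert back.tumor_ids == ["t1", "t2"] and back.normal_ids == ["n1", "n2"]
    pd.testing.assert_frame_equal(back.signals, table.signals, check_names=False)
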