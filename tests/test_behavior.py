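"""Ethogram validation, syllable-behavior assignment, normalized rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupcall.behavior import (BEHAVIORS, BehaviorRates, Ethogram, EthogramError,
                              assign_behavior, behavior_proportions,
                              normalized_behavior_shares, usv_rate_per_behavior)


def _random_ethogram(seed: int, length_s: float = 300.0) -> Ethogram:
    rng = np.random.default_rng(seed)
    intervals, t = [], 0.0
    while t < length_s - 1e-9:
        end = min(t + rng.uniform(2.0, 40.0), length_s)
        intervals.append((t, end, BEHAVIORS[rng.integers(len(BEHAVIORS))]))
        t = end
    return Ethogram(tuple(intervals), length_s)


class TestEthogramValidation:
    def test_gap_rejected_with_offender_listed(self):
        with pytest.raises(EthogramError, match="offending"):
            Ethogram(((0.0, 10.0, "locomotion"), (15.0, 30.0, "grooming")), 30.0)

    def test_overlap_rejected(self):
        with pytest.raises(EthogramError):
            Ethogram(((0.0, 20.0, "locomotion"), (15.0, 30.0, "grooming")), 30.0)

    def test_incomplete_coverage_rejected(self):
        with pytest.raises(EthogramError):
            Ethogram(((0.0, 20.0, "locomotion"),), 30.0)

    def test_round_trip_through_frame(self):
        eth = _random_ethogram(0)
        assert Ethogram.from_frame(eth.to_frame()) == eth


class TestProportions:
    def test_single_interval_is_all(self):
        eth = Ethogram(((0.0, 300.0, "lying_still"),), 300.0)
        p = behavior_proportions(eth)
        assert p["lying_still"] == 1.0
        assert sum(p.values()) == 1.0

    def test_half_and_half(self):
        eth = Ethogram(((0.0, 150.0, "locomotion"), (150.0, 300.0, "lying_still")), 300.0)
        p = behavior_proportions(eth)
        assert p["locomotion"] == pytest.approx(0.5)
        assert p["lying_still"] == pytest.approx(0.5)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_discretized_tally(self, seed):
        """Proportions agree with a brute-force per-millisecond tally."""
        eth = _random_ethogram(seed, length_s=60.0)
        p = behavior_proportions(eth)
        grid = np.arange(0.0005, 60.0, 0.001)
        tally = {b: 0 for b in BEHAVIORS}
        for t in grid:
            tally[eth.behavior_at(t)] += 1
        for b in BEHAVIORS:
            assert p[b] == pytest.approx(tally[b] / len(grid), abs=1e-3)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)


class TestAssignment:
    eth = Ethogram(((0.0, 10.0, "locomotion"), (10.0, 20.0, "lying_still"),
                    (20.0, 30.0, "wriggling")), 30.0)

    def test_interior_onset(self):
        assert assign_behavior(25.0, self.eth) == "wriggling"

    def test_boundary_belongs_to_later_interval(self):
        assert assign_behavior(10.0, self.eth) == "lying_still"

    def test_spanning_syllable_coded_by_onset(self):
        # a syllable from 9.99 s to 10.05 s crosses the transition but its
        # onset is inside the locomotion interval
        assert assign_behavior(9.99, self.eth) == "locomotion"

    def test_onset_outside_coverage_rejected(self):
        with pytest.raises(EthogramError, match="outside"):
            assign_behavior(30.0, self.eth)


class TestRates:
    def test_all_usvs_in_one_behavior(self):
        eth = Ethogram(((0.0, 60.0, "locomotion"), (60.0, 300.0, "lying_still")), 300.0)
        onsets = np.linspace(1.0, 59.0, 30)
        rates = usv_rate_per_behavior(onsets, eth)
        assert rates.usvs_per_second["locomotion"] == pytest.approx(0.5)
        assert rates.usvs_per_second["lying_still"] == 0.0
        assert rates.usv_count["grooming"] == 0

    def test_zero_usvs_all_rates_zero(self):
        eth = _random_ethogram(1)
        rates = usv_rate_per_behavior([], eth)
        assert all(r in (0.0, None) for r in rates.usvs_per_second.values())

    def test_never_performed_behavior_rate_is_null(self):
        eth = Ethogram(((0.0, 300.0, "lying_still"),), 300.0)
        rates = usv_rate_per_behavior([5.0], eth)
        assert rates.usvs_per_second["locomotion"] is None
        assert rates.usvs_per_second["lying_still"] == pytest.approx(1 / 300)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation(self, seed):
        """Sum over behaviors of rate * time equals the total syllable count."""
        rng = np.random.default_rng(seed)
        eth = _random_ethogram(seed)
        onsets = rng.uniform(0.0, 300.0 - 1e-6, size=rng.integers(0, 200))
        rates = usv_rate_per_behavior(onsets, eth)
        total = sum((rates.usvs_per_second[b] or 0.0) * rates.time_s[b]
                    for b in BEHAVIORS)
        assert total == pytest.approx(len(onsets), abs=1e-9)
        assert sum(rates.time_s.values()) == pytest.approx(300.0, abs=1e-9)

    def test_uniform_usvs_give_equal_rates(self):
        """Uniform Poisson onsets over a balanced ethogram: rates agree
        across behaviors within sampling error."""
        rng = np.random.default_rng(7)
        eth = Ethogram(tuple((i * 75.0, (i + 1) * 75.0, b)
                             for i, b in enumerate(BEHAVIORS)), 300.0)
        onsets = rng.uniform(0.0, 300.0, size=4000)
        rates = usv_rate_per_behavior(onsets, eth)
        vals = [rates.usvs_per_second[b] for b in BEHAVIORS]
        assert max(vals) - min(vals) < 4 * np.sqrt(1000) / 75.0


class TestShares:
    @staticmethod
    def _rates(d):
        time = {b: 10.0 if d.get(b) is not None else 0.0 for b in BEHAVIORS}
        count = {b: int((d.get(b) or 0) * 10) for b in BEHAVIORS}
        return BehaviorRates(time_s=time, usv_count=count,
                             usvs_per_second={b: d.get(b) for b in BEHAVIORS})

    def test_two_equal_rates_split_evenly(self):
        shares = normalized_behavior_shares(self._rates(
            {"locomotion": 1.0, "wriggling": 1.0, "lying_still": 0.0, "grooming": 0.0}))
        assert shares["locomotion"] == pytest.approx(0.5)
        assert shares["wriggling"] == pytest.approx(0.5)

    def test_single_nonzero_rate_takes_all(self):
        shares = normalized_behavior_shares(self._rates(
            {"locomotion": 0.7, "wriggling": 0.0, "lying_still": 0.0, "grooming": 0.0}))
        assert shares["locomotion"] == 1.0

    def test_arbitrary_rates_match_hand_computation(self):
        d = {"locomotion": 0.4, "wriggling": 0.1, "lying_still": 0.25, "grooming": None}
        shares = normalized_behavior_shares(self._rates(d))
        total = 0.75
        assert shares["locomotion"] == pytest.approx(0.4 / total)
        assert shares["grooming"] == 0.0
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_all_zero_rates_flagged(self):
        with pytest.raises(ValueError):
            normalized_behavior_shares(self._rates(
                {"locomotion": 0.0, "wriggling": 0.0, "lying_still": 0.0,
                 "grooming": 0.0}))
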