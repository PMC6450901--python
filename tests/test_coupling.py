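import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popcoupling.coupling import (
    BinnedCounts,
    bin_spikes,
    half_session_coupling,
    motion_mask,
    population_coupling,
    split_population_coupling,
)
from popcoupling.data_io import SpikeTrainSet


def naive_population_coupling(counts):
    """Literal double-loop evaluation of the coupling definition (oracle)."""
    counts = np.asarray(counts, dtype=float)
    n, T = counts.shape
    mu = counts.mean(axis=1)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for t in range(T):
            pop = 0.0
            for j in range(n):
                if j != i:
                    pop += counts[j, t] - mu[j]
            acc += counts[i, t] * pop
        out[i] = acc / counts[i].sum()
    return out


def _binned(counts, bw=0.25):
    counts = np.asarray(counts)
    return BinnedCounts(counts, bw, [f"u{i}" for i in range(counts.shape[0])])


class TestBinSpikes:
    def test_direct_counting(self):
        sts = SpikeTrainSet(["u"], [np.array([0.1, 0.26, 0.9])], 1.0)
        b = bin_spikes(sts, 0.25)
        np.testing.assert_array_equal(b.counts[0], [1, 1, 0, 1])

    def test_no_spikes_zero_row(self):
        sts = SpikeTrainSet(["u"], [np.empty(0)], 1.0)
        b = bin_spikes(sts, 0.25)
        np.testing.assert_array_equal(b.counts[0], [0, 0, 0, 0])

    def test_edge_spike_opens_next_bin(self):
        sts = SpikeTrainSet(["u"], [np.array([0.25])], 1.0)
        b = bin_spikes(sts, 0.25)
        np.testing.assert_array_equal(b.counts[0], [0, 1, 0, 0])

    def test_partial_trailing_bin_discarded(self):
        sts = SpikeTrainSet(["u"], [np.array([0.55])], 0.6)
        b = bin_spikes(sts, 0.25)
        assert b.n_bins == 2
        assert b.counts.sum() == 0  # the 0.55 spike fell in the discarded bin

    def test_bin_wider_than_session_errors(self):
        sts = SpikeTrainSet(["u"], [np.array([0.1])], 1.0)
        with pytest.raises(ValueError):
            bin_spikes(sts, 2.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 9.99), min_size=0, max_size=50))
    def test_counts_conserved_within_binned_window(self, times):
        times = np.sort(np.asarray(times))
        sts = SpikeTrainSet(["u"], [times], 10.0)
        b = bin_spikes(sts, 0.25)
        assert b.counts.sum() == np.sum(times < b.n_bins * 0.25)


class TestPopulationCoupling:
    COUNTS = np.array([[2, 0, 2, 0], [1, 0, 1, 0], [0, 1, 0, 1]])

    def test_hand_computed_values(self):
        # unit A: deviations of B and C cancel -> 0; B co-varies with A ->
        # +0.5; C anticorrelated -> -1.5 (all evaluated by hand)
        res = population_coupling(_binned(self.COUNTS))
        np.testing.assert_allclose(res.c_pop, [0.0, 0.5, -1.5])

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            counts = rng.poisson(2.0, size=(10, 100))
            counts[counts.sum(axis=1) == 0, 0] = 1
            res = population_coupling(_binned(counts))
            np.testing.assert_allclose(
                res.c_pop, naive_population_coupling(counts), rtol=1e-10
            )

    def test_silent_unit_rejected(self):
        counts = np.array([[1, 0], [0, 0]])
        with pytest.raises(ValueError, match="zero spikes"):
            population_coupling(_binned(counts))

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError, match="2 units"):
            population_coupling(_binned(np.array([[1, 2]])))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 7))
    def test_constant_offset_of_other_units_is_invariant(self, seed, shift):
        # mean subtraction in the population term removes any constant added
        # to every bin of the *other* units
        r = np.random.default_rng(seed)
        counts = r.poisson(2.0, size=(5, 40)) + 1
        base = population_coupling(_binned(counts)).c_pop
        shifted = counts.copy()
        shifted[1:] += shift
        res = population_coupling(_binned(shifted)).c_pop
        assert np.isclose(res[0], base[0], rtol=1e-9)

    def test_independent_units_mean_coupling_near_zero(self, rng):
        counts = rng.poisson(2.0, size=(20, 5000))
        res = population_coupling(_binned(counts))
        spread = res.c_pop.std()
        assert abs(res.c_pop.mean()) < max(3 * spread / np.sqrt(20), 0.05)


class TestSplits:
    def test_all_true_mask_reproduces_full_session(self, rng):
        counts = rng.poisson(1.5, size=(6, 50)) + 1
        b = _binned(counts)
        full = population_coupling(b)
        on, off = split_population_coupling(b, np.ones(50, dtype=bool))
        np.testing.assert_allclose(on.c_pop, full.c_pop)
        assert np.all(np.isnan(off.c_pop))
        assert off.log  # degenerate partition is logged

    def test_alternating_mask_on_iid_counts_agrees(self, rng):
        counts = rng.poisson(3.0, size=(8, 4000))
        b = _binned(counts)
        mask = np.arange(4000) % 2 == 0
        a, c = split_population_coupling(b, mask)
        r = np.corrcoef(a.c_pop, c.c_pop)[0, 1]
        # both halves measure the same (null) structure; values agree up to
        # sampling error around zero coupling
        np.testing.assert_allclose(a.c_pop, c.c_pop, atol=5 * counts.std())

    def test_silent_unit_in_partition_flagged_not_fatal(self):
        counts = np.array([[1, 1, 0, 0], [1, 2, 1, 2], [2, 1, 1, 1]])
        b = _binned(counts)
        mask = np.array([False, False, True, True])
        on, off = split_population_coupling(b, mask)
        assert np.isnan(on.c_pop[0])
        assert np.isfinite(off.c_pop[0])
        assert any("u0" in line for line in on.log)

    def test_half_session_bin_split(self, rng):
        counts = rng.poisson(2.0, size=(4, 5)) + 1
        first, second = half_session_coupling(_binned(counts))
        assert first.total_spikes.sum() == counts[:, :2].sum()
        assert second.total_spikes.sum() == counts[:, 2:].sum()

    def test_duplicated_half_sessions_identical(self):
        half = np.array([[2, 0, 1, 3], [1, 1, 0, 2], [0, 2, 2, 1]])
        b = _binned(np.hstack([half, half]))
        first, second = half_session_coupling(b)
        np.testing.assert_allclose(first.c_pop, second.c_pop)

    def test_motion_mask_thresholds_on_session_mean(self):
        b = _binned(np.ones((2, 4), dtype=int), bw=0.25)
        speed = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        mask = motion_mask(b, speed, 100.0)
        np.testing.assert_array_equal(mask, [False, False, True, True])


class TestSyntheticSessionProperties:
    def test_half_session_stability(self, retained_spikes):
        b = bin_spikes(retained_spikes)
        first, second = half_session_coupling(b)
        r = np.corrcoef(first.c_pop, second.c_pop)[0, 1]
        assert r >= 0.7

    def test_rest_motion_coupling_correlated_for_stationary_generator(self):
        from popcoupling.data_io import apply_exclusions
        from popcoupling.kinematics import mean_body_speed, preprocess_positions
        from popcoupling.synth import SynthParams, generate_session

        ses, _ = generate_session(
            SynthParams(n_units=25, movement_gains=np.zeros(25)), seed=11
        )
        sp = apply_exclusions(ses).session.spikes
        b = bin_spikes(sp)
        _, vel = preprocess_positions(ses.beads)
        speed = mean_body_speed(np.linalg.norm(vel, axis=2))
        mask = motion_mask(b, speed, 100.0)
        motion, rest = split_population_coupling(b, mask)
        ok = np.isfinite(motion.c_pop) & np.isfinite(rest.c_pop)
        assert ok.sum() >= 20
        assert np.corrcoef(motion.c_pop[ok], rest.c_pop[ok])[0, 1] > 0.7

    def test_bin_width_robustness_rank_correlation(self, retained_spikes):
        from scipy.stats import spearmanr

        c250 = population_coupling(bin_spikes(retained_spikes, 0.25)).c_pop
        for bw in (0.1, 0.05, 0.01):
            c = population_coupling(bin_spikes(retained_spikes, bw)).c_pop
            assert spearmanr(c250, c).statistic > 0.8
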