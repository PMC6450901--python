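import numpy as np
import pytest

from popcoupling.body_coupling import (
    EventSet,
    bcd,
    detect_events,
    mtasr,
    shift_surrogates,
    significance,
    stabs,
)
from popcoupling.kinematics import compute_aspects
from popcoupling.synth import SynthParams, generate_session


class TestDetectEvents:
    def test_toy_crossings(self):
        ev = detect_events(np.array([0, 0, 4, 4, 0, 0.0]), 1.0, edge_s=1.0)
        np.testing.assert_allclose(ev.onset_times_s, [2.0])
        np.testing.assert_allclose(ev.cessation_times_s, [4.0])

    def test_constant_speed_no_events(self):
        ev = detect_events(np.full(600, 3.0), 100.0)
        assert ev.n_onsets == 0 and ev.n_cessations == 0

    def test_monotone_ramp_single_onset(self):
        ev = detect_events(np.linspace(0, 10, 1000), 100.0)
        assert ev.n_onsets == 1
        assert ev.n_cessations == 0
        assert ev.onset_times_s[0] == pytest.approx(5.0, abs=0.02)

    def test_refractory_suppresses_chatter(self):
        # speed oscillating rapidly around its mean: without debouncing this
        # would produce an event every cycle (50 Hz)
        t = np.arange(2000) / 100.0
        speed = 5.0 + np.sin(2 * np.pi * 10 * t)
        ev = detect_events(speed, 100.0)
        assert ev.n_onsets <= len(t) / 100.0 / 0.5 + 1

    def test_dwell_filters_single_sample_blips(self):
        speed = np.zeros(1000)
        speed[300:600] = 10.0
        speed[450] = 0.0  # one-sample dropout must not create events
        ev = detect_events(speed, 100.0)
        assert ev.n_onsets == 1 and ev.n_cessations == 1


class TestMtasr:
    def _events(self, duration, spacing=4.0):
        onsets = np.arange(2.0, duration - 2.0, spacing)
        return EventSet(onsets, onsets + spacing / 2)

    def test_independent_poisson_unit_flat_waveform(self, rng):
        duration = 600.0
        train = np.sort(rng.uniform(0, duration, 3000))
        res = mtasr(train, self._events(duration), duration)
        assert res.onset.values.mean() == pytest.approx(1.0, abs=1e-6)
        assert res.bc_m < 0.1

    def test_onset_locked_unit_has_bump(self, rng):
        duration = 600.0
        ev = self._events(duration)
        train = np.sort(
            np.concatenate([on + rng.uniform(0, 0.5, 5) for on in ev.onset_times_s])
        )
        res = mtasr(train, ev, duration)
        locked = res.onset.values[
            (res.onset.lags_s >= 0) & (res.onset.lags_s <= 0.5)
        ]
        assert locked.mean() > 1.5  # strong excess rate just after onset
        assert res.bc_m > 0.3

    def test_exact_rate_scaling_invariance(self, rng):
        duration = 600.0
        ev = self._events(duration)
        train = np.sort(rng.uniform(0, duration, 2000))
        doubled = np.sort(np.concatenate([train, train]))
        r1 = mtasr(train, ev, duration)
        r2 = mtasr(doubled, ev, duration)
        np.testing.assert_allclose(r1.onset.values, r2.onset.values)
        assert r1.bc_m == pytest.approx(r2.bc_m)

    def test_no_spikes_degenerate(self):
        res = mtasr(np.empty(0), self._events(100.0), 100.0)
        assert res.degenerate and res.bc_m == 0.0


class TestStabs:
    def test_constant_speed_gives_zero(self, rng):
        train = np.sort(rng.uniform(0, 100, 500))
        res = stabs(train, np.full(10000, 7.0))
        assert res.bc_s == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.waveform.values, 1.0)

    def test_spikes_at_speed_peaks(self):
        t = np.arange(60000) / 100.0
        speed = 10.0 + 8.0 * np.sin(2 * np.pi * 0.5 * t)
        peaks = np.arange(0.5, 599.0, 2.0)  # sin peaks at t = 0.5 + 2k
        res = stabs(peaks, speed)
        assert res.bc_s > 0.2
        assert abs(res.waveform.lags_s[np.argmax(res.waveform.values)]) < 0.05

    def test_speed_rescaling_invariance(self, rng):
        t = np.arange(30000) / 100.0
        speed = 10.0 + 5.0 * np.sin(2 * np.pi * 0.3 * t)
        train = np.sort(rng.uniform(2, 297, 400))
        r1 = stabs(train, speed)
        r2 = stabs(train, speed * 3.7)
        assert r1.bc_s == pytest.approx(r2.bc_s, rel=1e-12)


class TestSurrogates:
    def test_spike_count_preserved(self, rng):
        train = np.sort(rng.uniform(0, 500, 700))
        for s in shift_surrogates(train, 500.0, 5, rng):
            assert s.size == train.size
            assert s[0] >= 0 and s[-1] < 500.0

    def test_circular_isi_multiset_preserved(self, rng):
        train = np.sort(rng.uniform(0, 500, 300))

        def circ_isis(t):
            d = np.diff(np.concatenate([t, [t[0] + 500.0]]))
            return np.sort(d)

        for s in shift_surrogates(train, 500.0, 3, rng):
            np.testing.assert_allclose(circ_isis(s), circ_isis(train), atol=1e-9)

    def test_short_session_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            shift_surrogates(np.array([1.0]), 50.0, 2, rng)


class TestSignificance:
    def test_above_all_surrogates(self, rng):
        surr = rng.uniform(0, 1, 1000)
        assert significance(2.0, surr)

    def test_median_not_significant(self, rng):
        surr = rng.uniform(0, 1, 1000)
        assert not significance(float(np.median(surr)), surr)

    def test_tie_at_percentile_not_significant(self):
        surr = np.full(1000, 0.5)
        assert not significance(0.5, surr)


@pytest.fixture(scope="module")
def tuned_session():
    p = SynthParams(
        n_units=2,
        duration_s=600,
        movement_gains=np.array([1.2, 1.2]),
        movement_signs=np.array([1.0, 1.0]),
        preferred_aspects=np.array([2, 1]),
        latent_gains=np.array([0.3, 0.3]),
        rate_median_hz=4.0,
    )
    ses, _ = generate_session(p, seed=1)
    kin = compute_aspects(ses.beads)
    return ses, kin


class TestBcd:
    def test_turn_locked_unit_prefers_turning_family(self, tuned_session):
        # rigid-body turning moves every bead relative to the COM along the
        # right-left axis, so the turning angular speed (aspect 2) and the
        # right-left relative velocities form one collinear family
        ses, kin = tuned_session
        turning_family = {2} | {3 + 3 * b + 2 for b in range(8)}  # 1-based
        res = bcd(ses.spikes.spike_times[0], kin.aspects, 600.0, 50,
                  np.random.default_rng(10))
        assert res.best_aspect_index in turning_family
        rank_of_turn = int((res.aspect_scores > res.aspect_scores[1]).sum()) + 1
        assert rank_of_turn <= 9

    def test_cross_unit_discrimination(self, tuned_session):
        ses, kin = tuned_session
        turn = bcd(ses.spikes.spike_times[0], kin.aspects, 600.0, 50,
                   np.random.default_rng(10))
        speed = bcd(ses.spikes.spike_times[1], kin.aspects, 600.0, 50,
                    np.random.default_rng(11))
        # the turning-locked unit expresses far more turning signal than the
        # speed-locked unit, and vice versa for COM speed
        assert turn.aspect_scores[1] > 2 * speed.aspect_scores[1]
        assert speed.aspect_scores[0] > 2 * turn.aspect_scores[0]

    def test_duplicating_an_aspect_never_decreases_bcd(self, tuned_session):
        ses, kin = tuned_session
        res = bcd(ses.spikes.spike_times[0], kin.aspects, 600.0, 30,
                  np.random.default_rng(5))
        aspects2 = kin.aspects.copy()
        aspects2[12] = kin.aspects[res.best_aspect_index - 1]
        res2 = bcd(ses.spikes.spike_times[0], aspects2, 600.0, 30,
                   np.random.default_rng(5))
        assert res2.bc_d >= res.bc_d - 1e-9

    def test_independent_unit_z_scores_near_unit_scale(self, tuned_session, rng):
        ses, kin = tuned_session
        train = np.sort(rng.uniform(0, 600.0, 2000))
        res = bcd(train, kin.aspects, 600.0, 50, np.random.default_rng(3))
        # z-waveforms of a movement-independent unit should look like
        # correlated unit-scale noise, not outliers
        assert 0.3 < np.median(res.aspect_scores) < 3.0
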