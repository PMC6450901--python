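"""Neuron-to-body coupling: BC_M, BC_S, BC_D and surrogate significance.

Three scalar couplings per unit, all built from triggered-average waveforms
on lags -1 s ... +1 s at 10 ms resolution (201 lag points), low-pass
filtered at 1.5 Hz (zero phase):

* **BC_M** — movement-triggered-average spike rate (MTASR).  Spike rate
  around movement onset and cessation events, each waveform normalized by
  its mean; BC_M is the mean of the onset-waveform SD and the
  cessation-waveform SD.
* **BC_S** — spike-triggered-average body speed (STABS).  Mean body speed
  around the unit's spikes, normalized by its mean; BC_S is the waveform SD.
* **BC_D** — spike-triggered-average detailed body movement (STADBM).  A
  spike-triggered average for each of 27 kinematic aspects, z-scored per lag
  against surrogate waveforms from time-shifted spike trains; BC_D is the
  largest across-aspect SD of the z-scored waveform, and the argmax aspect
  is reported.

Significance of BC_M/BC_S is judged against surrogate spike trains obtained
by circularly shifting all spike times by a random offset of at least 30 s,
which preserves spike count and inter-spike-interval structure while
destroying alignment with the behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "WAVEFORM_FS_HZ",
    "N_LAGS",
    "LAGS_S",
    "EventSet",
    "TriggeredWaveform",
    "MtasrResult",
    "StabsResult",
    "BcdResult",
    "detect_events",
    "mtasr",
    "stabs",
    "bcd",
    "shift_surrogates",
    "significance",
    "bc_m_with_significance",
    "bc_s_with_significance",
]

WAVEFORM_FS_HZ = 100.0  # 10 ms lag resolution
N_LAGS = 100  # lags -N_LAGS .. +N_LAGS
LAGS_S = np.arange(-N_LAGS, N_LAGS + 1) / WAVEFORM_FS_HZ
_LAG_OFFSETS = np.arange(-N_LAGS, N_LAGS + 1)


@dataclass
class EventSet:
    """Movement onset and cessation times (s), sorted."""

    onset_times_s: np.ndarray
    cessation_times_s: np.ndarray

    @property
    def n_onsets(self) -> int:
        return self.onset_times_s.size

    @property
    def n_cessations(self) -> int:
        return self.cessation_times_s.size


@dataclass
class TriggeredWaveform:
    lags_s: np.ndarray
    values: np.ndarray
    n_triggers: int
    normalized: bool
    degenerate: bool = False


@dataclass
class MtasrResult:
    onset: TriggeredWaveform
    cessation: TriggeredWaveform
    bc_m: float
    degenerate: bool


@dataclass
class StabsResult:
    waveform: TriggeredWaveform
    bc_s: float
    degenerate: bool


@dataclass
class BcdResult:
    bc_d: float
    best_aspect_index: int  # 1-based
    aspect_scores: np.ndarray  # (27,)
    z_waveforms: np.ndarray  # (27, 201)
    n_triggers: int
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# movement events
# ---------------------------------------------------------------------------

def detect_events(
    speed: np.ndarray,
    sample_rate_hz: float,
    refractory_s: float = 0.5,
    dwell_s: float = 0.1,
    edge_s: float = 1.0,
) -> EventSet:
    """Threshold-crossing movement events on the mean body speed.

    The threshold is the whole-session mean speed.  Upward crossings are
    onsets, downward crossings cessations.  A crossing only counts if the
    speed dwelt on the old side for ``dwell_s`` before it and stays on the
    new side for ``dwell_s`` after it; same-type events closer
    than ``refractory_s`` to the previous kept event are suppressed; events
    within ``edge_s`` of the session edges are dropped.
    """
    speed = np.asarray(speed, dtype=float)
    thr = speed.mean()
    above = speed > thr
    if above.all() or not above.any():
        return EventSet(np.empty(0), np.empty(0))
    dwell_n = max(1, int(round(dwell_s * sample_rate_hz)))

    def _events(cross_idx: np.ndarray, want: bool) -> np.ndarray:
        kept = []
        last = -np.inf
        for i in cross_idx:
            after = above[i : i + dwell_n]
            before = above[max(i - dwell_n, 0) : i]
            if after.size == 0 or not np.all(after == want):
                continue
            if before.size and not np.all(before == (not want)):
                continue
            t = i / sample_rate_hz
            if t - last < refractory_s:
                continue
            kept.append(t)
            last = t
        times = np.asarray(kept)
        lo, hi = edge_s, speed.size / sample_rate_hz - edge_s
        return times[(times >= lo) & (times <= hi)]

    flips = np.flatnonzero(np.diff(above.astype(np.int8)))
    rises = flips[~above[flips]] + 1
    falls = flips[above[flips]] + 1
    return EventSet(_events(rises, True), _events(falls, False))


# ---------------------------------------------------------------------------
# triggered waveforms
# ---------------------------------------------------------------------------

def _lowpass(values: np.ndarray, cutoff_hz: float = 1.5) -> np.ndarray:
    b, a = signal.butter(4, cutoff_hz / (WAVEFORM_FS_HZ / 2.0))
    return signal.filtfilt(b, a, values, axis=-1)


def _valid_trigger_indices(times_s: np.ndarray, n_samples: int) -> np.ndarray:
    idx = np.round(np.asarray(times_s) * WAVEFORM_FS_HZ).astype(np.int64)
    return idx[(idx - N_LAGS >= 0) & (idx + N_LAGS <= n_samples - 1)]


def _triggered_sum(series: np.ndarray, trig_idx: np.ndarray) -> np.ndarray:
    """Sum of ``series`` windows around each trigger index; (201,)."""
    windows = series[trig_idx[:, None] + _LAG_OFFSETS[None, :]]
    return windows.sum(axis=0)


def mtasr(
    spike_times: np.ndarray,
    events: EventSet,
    duration_s: float,
    lowpass_hz: float = 1.5,
) -> MtasrResult:
    """Movement-triggered-average spike rate waveforms and BC_M.

    The per-lag rate is the spike count across triggers divided by
    ``n_triggers * 10 ms``; each waveform is low-pass filtered and
    normalized by its mean.  BC_M = (SD_onset + SD_cessation) / 2.
    """
    n10 = int(round(duration_s * WAVEFORM_FS_HZ))
    bins = np.floor(np.asarray(spike_times) * WAVEFORM_FS_HZ).astype(np.int64)
    counts = np.bincount(bins[bins < n10], minlength=n10).astype(float)

    waves = []
    sds = []
    degenerate = False
    for times in (events.onset_times_s, events.cessation_times_s):
        trig = _valid_trigger_indices(times, n10)
        if trig.size == 0:
            waves.append(
                TriggeredWaveform(LAGS_S, np.zeros(LAGS_S.size), 0, False, True)
            )
            sds.append(0.0)
            degenerate = True
            continue
        rate = _triggered_sum(counts, trig) / (trig.size / WAVEFORM_FS_HZ)
        rate = _lowpass(rate, lowpass_hz)
        mean = rate.mean()
        if mean == 0:
            waves.append(TriggeredWaveform(LAGS_S, rate, trig.size, False, True))
            sds.append(0.0)
            degenerate = True
            continue
        norm = rate / mean
        waves.append(TriggeredWaveform(LAGS_S, norm, trig.size, True))
        sds.append(float(np.std(norm)))
    bc_m = float((sds[0] + sds[1]) / 2.0)
    return MtasrResult(waves[0], waves[1], bc_m, degenerate)


def stabs(
    spike_times: np.ndarray,
    speed: np.ndarray,
    sample_rate_hz: float = WAVEFORM_FS_HZ,
    lowpass_hz: float = 1.5,
) -> StabsResult:
    """Spike-triggered-average body speed waveform and BC_S.

    Spikes whose +/- 1 s window would extend past the session edges are
    dropped.  The waveform is low-pass filtered and normalized by its mean;
    BC_S is its SD.
    """
    if abs(sample_rate_hz - WAVEFORM_FS_HZ) > 1e-6:
        raise ValueError("speed series must be sampled at 100 Hz")
    trig = _valid_trigger_indices(spike_times, speed.size)
    if trig.size == 0:
        wf = TriggeredWaveform(LAGS_S, np.zeros(LAGS_S.size), 0, False, True)
        return StabsResult(wf, 0.0, True)
    wave = _triggered_sum(np.asarray(speed, dtype=float), trig) / trig.size
    wave = _lowpass(wave, lowpass_hz)
    mean = wave.mean()
    if mean == 0:
        wf = TriggeredWaveform(LAGS_S, wave, trig.size, False, True)
        return StabsResult(wf, 0.0, True)
    norm = wave / mean
    wf = TriggeredWaveform(LAGS_S, norm, trig.size, True)
    return StabsResult(wf, float(np.std(norm)), False)


# ---------------------------------------------------------------------------
# surrogates and significance
# ---------------------------------------------------------------------------

def shift_surrogates(
    spike_times: np.ndarray,
    duration_s: float,
    n_surrogates: int,
    rng: np.random.Generator,
    min_offset_s: float = 30.0,
) -> list[np.ndarray]:
    """Circularly shifted surrogate spike trains.

    Each surrogate shifts all spikes by a uniform random offset in
    ``[min_offset_s, duration - min_offset_s]`` modulo the duration, so the
    spike count and (circular) ISI structure are preserved exactly.
    """
    if duration_s <= 2 * min_offset_s:
        raise ValueError("session too short for the minimum surrogate offset")
    t = np.asarray(spike_times, dtype=float)
    offsets = rng.uniform(min_offset_s, duration_s - min_offset_s, n_surrogates)
    return [np.sort(np.mod(t + off, duration_s)) for off in offsets]


def significance(
    value: float, surrogate_values: np.ndarray, percentile: float = 95.0
) -> bool:
    """True iff ``value`` strictly exceeds the surrogate percentile."""
    return bool(value > np.percentile(np.asarray(surrogate_values), percentile))


def bc_m_with_significance(
    spike_times: np.ndarray,
    events: EventSet,
    duration_s: float,
    n_surrogates: int,
    rng: np.random.Generator,
    percentile: float = 95.0,
) -> tuple[MtasrResult, np.ndarray, bool]:
    res = mtasr(spike_times, events, duration_s)
    surr = np.array(
        [
            mtasr(s, events, duration_s).bc_m
            for s in shift_surrogates(spike_times, duration_s, n_surrogates, rng)
        ]
    )
    return res, surr, significance(res.bc_m, surr, percentile)


def bc_s_with_significance(
    spike_times: np.ndarray,
    speed: np.ndarray,
    duration_s: float,
    n_surrogates: int,
    rng: np.random.Generator,
    percentile: float = 95.0,
) -> tuple[StabsResult, np.ndarray, bool]:
    res = stabs(spike_times, speed)
    surr = np.array(
        [
            stabs(s, speed).bc_s
            for s in shift_surrogates(spike_times, duration_s, n_surrogates, rng)
        ]
    )
    return res, surr, significance(res.bc_s, surr, percentile)


# ---------------------------------------------------------------------------
# BC_D: detailed movement aspects
# ---------------------------------------------------------------------------

def _sta_all_aspects(
    aspects: np.ndarray, trig_idx: np.ndarray, lowpass_hz: float
) -> np.ndarray:
    """Filtered spike-triggered averages for all aspects; (n_aspects, 201)."""
    out = np.empty((aspects.shape[0], LAGS_S.size))
    idx = trig_idx[:, None] + _LAG_OFFSETS[None, :]
    for a in range(aspects.shape[0]):
        out[a] = aspects[a][idx].mean(axis=0)
    return _lowpass(out, lowpass_hz)


def bcd(
    spike_times: np.ndarray,
    aspects: np.ndarray,
    duration_s: float,
    n_surrogates: int = 100,
    rng: np.random.Generator | None = None,
    lowpass_hz: float = 1.5,
) -> BcdResult:
    """BC_D from spike-triggered averages of the 27 movement aspects.

    Each aspect's spike-triggered average (filtered exactly like the
    surrogates) is z-scored per lag against ``n_surrogates`` circular-shift
    surrogate waveforms; the per-aspect score is the SD across lags of the
    z-waveform, BC_D the maximum score, ``best_aspect_index`` its 1-based
    argmax.
    """
    if rng is None:
        rng = np.random.default_rng()
    aspects = np.asarray(aspects, dtype=float)
    log: list[str] = []
    if np.isnan(aspects).any():
        # degenerate kinematic frames: fill with the aspect mean so the STA
        # stays defined; logged so callers can judge the impact
        n_bad = int(np.isnan(aspects).sum())
        log.append(f"filled {n_bad} NaN aspect samples with aspect means")
        means = np.nanmean(aspects, axis=1)
        aspects = np.where(np.isnan(aspects), means[:, None], aspects)

    n_samples = aspects.shape[1]
    trig = _valid_trigger_indices(spike_times, n_samples)
    if trig.size == 0:
        return BcdResult(0.0, 1, np.zeros(aspects.shape[0]),
                         np.zeros((aspects.shape[0], LAGS_S.size)), 0,
                         log + ["no spikes with full windows"])
    real = _sta_all_aspects(aspects, trig, lowpass_hz)

    surr = np.empty((n_surrogates, aspects.shape[0], LAGS_S.size))
    for k, train in enumerate(
        shift_surrogates(spike_times, duration_s, n_surrogates, rng)
    ):
        strig = _valid_trigger_indices(train, n_samples)
        if strig.size == 0:
            surr[k] = 0.0
            continue
        surr[k] = _sta_all_aspects(aspects, strig, lowpass_hz)
    mu = surr.mean(axis=0)
    sd = surr.std(axis=0)
    zero_sd = sd == 0
    if zero_sd.any():
        log.append(f"{int(zero_sd.sum())} lag points with zero surrogate SD")
        sd[zero_sd] = np.inf  # z -> 0 there
    z = (real - mu) / sd
    scores = z.std(axis=1)
    best = int(np.argmax(scores))
    return BcdResult(
        bc_d=float(scores[best]),
        best_aspect_index=best + 1,
        aspect_scores=scores,
        z_waveforms=z,
        n_triggers=int(trig.size),
        log=log,
    )
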