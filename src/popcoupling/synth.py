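"""Synthetic sessions with known population- and body-coupling structure.

A session emulates a 30-minute recording of a freely moving rat: the animal
alternates exponentially distributed rest and movement bouts; during bouts
the body advances at ~50 mm/s along a heading that oscillates (driving the
turning aspect); eight beads ride on a rigid body frame with low-pass
posture jitter.  Each unit is an inhomogeneous Poisson process with
intensity

    lambda_i(t) = r_i * max(0, 1 + a_i * L(t) + s_i * b_i * u(t - latency_i)),

where ``L`` is a shared unit-variance latent (low-pass filtered Gaussian,
~300 ms timescale) whose gain ``a_i`` plants population coupling, and ``u``
is the z-scored movement signal (mean body speed, or turning angular speed
for rotation-tuned units) whose gain magnitude ``b_i`` plants body coupling
with a per-unit response polarity ``s_i`` (movement can raise or lower a
unit's rate, as seen in vivo).  Spikes are drawn by exact thinning against
the piecewise-linear intensity.

`generate_peaked_population` builds a multi-session cohort in which the
body-coupling gain is a hump-shaped function of the latent gain — the
ground-truth analogue of a peaked body-coupling-vs-population-coupling
relationship — with per-session rate jitter to exercise median
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .data_io import BeadTrajectories, Session, SpikeTrainSet

__all__ = ["SynthParams", "generate_session", "generate_peaked_population"]

_FS = 100.0  # motion sample rate, Hz


@dataclass
class SynthParams:
    """Generator settings; defaults emulate one 30-min recording."""

    n_units: int = 20
    duration_s: float = 1800.0
    rate_median_hz: float = 2.0
    rate_sigma: float = 0.7  # lognormal shape of base rates
    min_rate_hz: float = 0.5
    latent_gain_range: tuple[float, float] = (0.0, 2.0)
    movement_gain_range: tuple[float, float] = (0.0, 1.0)
    latent_gains: np.ndarray | None = None  # a_i, overrides the range
    movement_gains: np.ndarray | None = None  # b_i (magnitudes), overrides the range
    movement_signs: np.ndarray | None = None  # +/-1 per unit; default random
    preferred_aspects: np.ndarray | None = None  # 1 = speed, 2 = turning
    latencies_s: np.ndarray | None = None
    latent_tau_s: float = 0.3
    rest_mean_s: float = 5.0
    move_mean_s: float = 3.0
    speed_amplitude_mm_s: float = 50.0
    speed_noise_mm_s: float = 2.0
    turn_freq_hz: float = 0.4
    turn_amplitude_rad_s: float = 1.5
    posture_jitter_mm: float = 1.0
    session_id: str = "synth"
    condition: dict = field(
        default_factory=lambda: {
            "drug": "none",
            "route": "systemic",
            "dose": 0.0,
            "dose_units": "",
        }
    )

    def __post_init__(self) -> None:
        if self.duration_s < 120:
            raise ValueError("duration_s must be at least 120 s")
        if self.rate_median_hz <= 0:
            raise ValueError("rates must be positive")


def _bout_indicator(p: SynthParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Boolean movement indicator at 100 Hz from alternating exponential bouts."""
    ind = np.zeros(n, dtype=bool)
    t = 0.0
    moving = False
    while t < p.duration_s:
        mean = p.move_mean_s if moving else p.rest_mean_s
        dur = rng.exponential(mean)
        if moving:
            i0, i1 = int(t * _FS), min(int((t + dur) * _FS), n)
            ind[i0:i1] = True
        t += dur
        moving = not moving
    return ind


def _lowpass_noise(
    rng: np.random.Generator, n: int, cutoff_hz: float, shape: tuple = ()
) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian noise, shape (*shape, n)."""
    b, a = sps.butter(2, cutoff_hz / (_FS / 2.0))
    x = sps.filtfilt(b, a, rng.standard_normal(shape + (n,)), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


# body-frame bead geometry (mm): rostrocaudal offset and height per bead,
# zero-mean so the generated COM equals the trajectory COM
_BEAD_ALONG = np.array([80.0, 55.0, 35.0, 15.0, -5.0, -25.0, -45.0, -75.0])
_BEAD_ALONG -= _BEAD_ALONG.mean()
_BEAD_HEIGHT = np.array([46.0, 50.0, 52.0, 52.0, 50.0, 48.0, 45.0, 38.0])
_BEAD_HEIGHT -= _BEAD_HEIGHT.mean()


def generate_session(
    params: SynthParams, seed: int | np.random.Generator | None = 0
) -> tuple[Session, pd.DataFrame]:
    """Generate one session plus its ground-truth gain table.

    Deterministic given the seed.  The ground truth is a DataFrame with
    columns ``unit_id, a, b, sign, aspect, latency_s, expected_rate_hz``
    (the last being the time-average of the unit's rectified intensity).
    """
    p = params
    rng = np.random.default_rng(seed)
    n = int(round(p.duration_s * _FS))
    grid_t = np.arange(n) / _FS

    # --- behaviour -------------------------------------------------------
    ind = _bout_indicator(p, rng, n)
    smooth_ind = sps.filtfilt(*sps.butter(2, 2.0 / (_FS / 2.0)), ind.astype(float))
    noise = _lowpass_noise(rng, n, 5.0) * p.speed_noise_mm_s
    speed = np.maximum(smooth_ind * p.speed_amplitude_mm_s + noise, 0.0)

    dpsi = (
        p.turn_amplitude_rad_s
        * np.sin(2 * np.pi * p.turn_freq_hz * grid_t + rng.uniform(0, 2 * np.pi))
        * smooth_ind
    )
    psi = np.cumsum(dpsi) / _FS
    heading = np.stack([np.cos(psi), np.sin(psi)], axis=1)
    com = np.zeros((n, 3))
    com[:, :2] = np.cumsum(speed[:, None] * heading, axis=0) / _FS
    com[:, 2] = 80.0 + 3.0 * _lowpass_noise(rng, n, 0.2)

    jitter = p.posture_jitter_mm * _lowpass_noise(rng, n, 3.0, shape=(8, 3))
    jitter = np.moveaxis(jitter, 2, 1)  # (8, n, 3)
    pos = (
        com[None, :, :]
        + _BEAD_ALONG[:, None, None]
        * np.concatenate([heading, np.zeros((n, 1))], axis=1)[None, :, :]
        + _BEAD_HEIGHT[:, None, None] * np.array([0.0, 0.0, 1.0])[None, None, :]
        + jitter
    )
    beads = BeadTrajectories(pos)

    # --- drive signals ---------------------------------------------------
    latent = _lowpass_noise(rng, n, 1.0 / (2 * np.pi * p.latent_tau_s))
    u_speed = (speed - speed.mean()) / speed.std()
    turn = np.gradient(psi) * _FS
    u_turn = (turn - turn.mean()) / turn.std()

    # --- units -----------------------------------------------------------
    k = p.n_units
    rates = np.maximum(
        rng.lognormal(np.log(p.rate_median_hz), p.rate_sigma, k), p.min_rate_hz
    )
    a = (
        np.asarray(p.latent_gains, float)
        if p.latent_gains is not None
        else rng.uniform(*p.latent_gain_range, k)
    )
    b = (
        np.asarray(p.movement_gains, float)
        if p.movement_gains is not None
        else rng.uniform(*p.movement_gain_range, k)
    )
    # movement responses come in both polarities (units that fire more and
    # units that fire less during movement), so movement-locked firing adds
    # little pairwise covariance; body-coupling magnitudes are unaffected
    signs = (
        np.asarray(p.movement_signs, float)
        if p.movement_signs is not None
        else rng.choice([-1.0, 1.0], k)
    )
    aspects = (
        np.asarray(p.preferred_aspects, int)
        if p.preferred_aspects is not None
        else np.ones(k, dtype=int)
    )
    lags = (
        np.asarray(p.latencies_s, float)
        if p.latencies_s is not None
        else np.zeros(k)
    )
    if np.any(a < -1):
        raise ValueError("latent gains must be >= -1")

    unit_ids = [f"u{j:03d}" for j in range(k)]
    trains = []
    expected_rates = np.zeros(k)
    for j in range(k):
        drive = u_turn if aspects[j] == 2 else u_speed
        if lags[j] != 0:
            shift = int(round(lags[j] * _FS))
            drive = np.roll(drive, shift)
        lam = rates[j] * np.maximum(
            0.0, 1.0 + a[j] * latent + signs[j] * b[j] * drive
        )
        expected_rates[j] = float(lam.mean())
        lam_max = float(lam.max())
        if lam_max == 0:
            trains.append(np.empty(0))
            continue
        n_cand = rng.poisson(lam_max * p.duration_s)
        t_cand = rng.uniform(0.0, p.duration_s, n_cand)
        accept = rng.random(n_cand) < np.interp(t_cand, grid_t, lam) / lam_max
        trains.append(np.sort(t_cand[accept]))

    spikes = SpikeTrainSet(unit_ids, trains, p.duration_s)
    session = Session(p.session_id, spikes, beads, dict(p.condition))
    truth = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "a": a,
            "b": b,
            "sign": signs,
            "aspect": aspects,
            "latency_s": lags,
            "expected_rate_hz": expected_rates,
        }
    )
    return session, truth


def generate_peaked_population(
    n_sessions: int = 5,
    n_units: int = 40,
    peak_frac: float = 0.5,
    hump_width: float = 0.35,
    noise_sd: float = 0.15,
    rate_jitter: tuple[float, float] = (0.5, 2.0),
    duration_s: float = 1800.0,
    seed: int = 0,
) -> tuple[list[tuple[Session, pd.DataFrame]], dict]:
    """Multi-session cohort with a planted peaked b(a) relationship.

    Latent gains a_i span their default range; movement gains follow a
    Gaussian hump centred at ``peak_frac`` of the a-range (width
    ``hump_width``) plus truncation-clipped noise.  Each session's median
    rate is jittered multiplicatively to exercise median normalization.
    Returns the sessions plus a metadata dict with the planted peak.
    """
    if n_sessions < 1:
        raise ValueError("need at least one session")
    ss = np.random.SeedSequence(seed)
    out = []
    base = SynthParams(n_units=n_units, duration_s=duration_s)
    lo, hi = base.latent_gain_range
    a0 = lo + peak_frac * (hi - lo)
    for s, child in enumerate(ss.spawn(n_sessions)):
        rng = np.random.default_rng(child)
        a = rng.uniform(lo, hi, n_units)
        hump = np.exp(-((a - a0) ** 2) / (2 * hump_width**2))
        b = np.clip(hump + rng.normal(0, noise_sd, n_units), 0.0, 1.5)
        params = SynthParams(
            n_units=n_units,
            duration_s=duration_s,
            rate_median_hz=base.rate_median_hz * rng.uniform(*rate_jitter),
            latent_gains=a,
            movement_gains=b,
            session_id=f"synth{s:02d}",
        )
        out.append(generate_session(params, rng))
    meta = {"planted_a0": a0, "a_range": (lo, hi), "hump_width": hump_width}
    return out, meta
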