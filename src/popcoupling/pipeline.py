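"""End-to-end orchestration: session analysis and pooled peak inference.

`analyze_session` chains the full single-session pipeline: exclusions ->
kinematics -> spike binning -> population coupling (full session, halves,
rest vs. motion) -> BC_M / BC_S with surrogate significance -> BC_D, and
collects everything in a per-unit coupling table.  `analyze_pooled` runs the
pooled peak permutation test for each body-coupling metric against
population coupling, the median-normalized variant, the per-session
consistency count test, and moving-quartile summary curves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import body_coupling as bc
from . import coupling as cp
from . import peaks
from .data_io import COUPLING_COLUMNS, ExclusionResult, Session, apply_exclusions
from .kinematics import KinematicsSeries, compute_aspects

__all__ = ["RunConfig", "SessionAnalysis", "PooledAnalysis", "analyze_session", "analyze_pooled"]


@dataclass
class RunConfig:
    """Analysis settings; the defaults are the full-cost study settings."""

    bin_width_s: float = 0.25
    n_surrogates: int = 1000  # BC_M / BC_S significance
    n_bcd_surrogates: int = 100  # BC_D z-scoring
    n_shuffles: int = 1000  # peak permutation test
    n_randomizations: int = 1000  # consistency count test
    min_rate_hz: float = 0.5
    min_units: int = 5
    min_events: int = 5  # per event type, for BC_M
    min_spikes: int = 50  # with full windows, for BC_S / BC_D
    percentile: float = 95.0
    compute_bcd: bool = True
    seed: int = 0

    @classmethod
    def fast(cls, **overrides) -> "RunConfig":
        """Reduced-cost mode: 100 surrogates, 200 shuffles/randomizations."""
        base = dict(
            n_surrogates=100, n_bcd_surrogates=100, n_shuffles=200,
            n_randomizations=200,
        )
        base.update(overrides)
        return cls(**base)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SessionAnalysis:
    session_id: str
    excluded: bool
    log: list[str]
    table: pd.DataFrame
    events: bc.EventSet | None = None
    kinematics: KinematicsSeries | None = None
    c_pop_full: cp.PopulationCouplingResult | None = None
    c_pop_halves: tuple | None = None
    c_pop_motion: cp.PopulationCouplingResult | None = None
    c_pop_rest: cp.PopulationCouplingResult | None = None
    waveforms: dict = field(default_factory=dict)


@dataclass
class PooledAnalysis:
    table: pd.DataFrame
    peak_tests: dict[str, peaks.PeakTestResult]
    normalized_peak_tests: dict[str, peaks.PeakTestResult]
    consistency: dict[str, peaks.ConsistencyCountResult | None]
    summary_curves: dict[str, pd.DataFrame]
    log: list[str]


def analyze_session(
    session: Session,
    config: RunConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SessionAnalysis:
    """Run the full single-session pipeline.

    Sessions failing the exclusion rules return with ``excluded=True`` and
    an empty table; every removal is logged.
    """
    if config is None:
        config = RunConfig()
    rng = np.random.default_rng(config.seed if rng is None else rng)

    excl: ExclusionResult = apply_exclusions(
        session, config.min_rate_hz, config.min_units
    )
    log = list(excl.log)
    if excl.excluded:
        return SessionAnalysis(session.session_id, True, log,
                               pd.DataFrame(columns=COUPLING_COLUMNS))
    ses = excl.session
    if ses.beads is None:
        raise ValueError("session analysis requires bead trajectories")

    kin = compute_aspects(ses.beads)
    speed = kin.mean_speed
    duration = ses.spikes.duration_s

    binned = cp.bin_spikes(ses.spikes, config.bin_width_s)
    c_full = cp.population_coupling(binned)
    halves = cp.half_session_coupling(binned)
    mask = cp.motion_mask(binned, speed, kin.sample_rate_hz)
    c_motion, c_rest = cp.split_population_coupling(binned, mask)
    log += c_motion.log + c_rest.log

    events = bc.detect_events(speed, kin.sample_rate_hz)
    if events.n_onsets < config.min_events or events.n_cessations < config.min_events:
        log.append(
            f"session {ses.session_id}: only {events.n_onsets} onsets / "
            f"{events.n_cessations} cessations, BC_M undefined"
        )

    rows = []
    waveforms: dict[str, dict] = {}
    rates = ses.spikes.rates_hz()
    for i, uid in enumerate(ses.spikes.unit_ids):
        train = ses.spikes.spike_times[i]
        enough_events = (
            events.n_onsets >= config.min_events
            and events.n_cessations >= config.min_events
        )
        if enough_events:
            m_res, _, m_sig = bc.bc_m_with_significance(
                train, events, duration, config.n_surrogates, rng,
                config.percentile,
            )
        else:
            m_res, m_sig = None, False

        n_full = bc._valid_trigger_indices(train, speed.size).size
        if n_full >= config.min_spikes:
            s_res, _, s_sig = bc.bc_s_with_significance(
                train, speed, duration, config.n_surrogates, rng,
                config.percentile,
            )
            if config.compute_bcd:
                d_res = bc.bcd(
                    train, kin.aspects, duration, config.n_bcd_surrogates, rng
                )
                log += [f"unit {uid}: {m}" for m in d_res.log]
            else:
                d_res = None
        else:
            log.append(
                f"unit {uid}: only {n_full} spikes with full windows, "
                "BC_S/BC_D undefined"
            )
            s_res, s_sig, d_res = None, False, None

        waveforms[uid] = {
            "mtasr_onset": m_res.onset if m_res else None,
            "mtasr_cessation": m_res.cessation if m_res else None,
            "stabs": s_res.waveform if s_res else None,
        }
        rows.append(
            {
                "session_id": ses.session_id,
                "unit_id": uid,
                "rate_hz": rates[i],
                "c_pop": c_full.c_pop[i],
                "bc_m": m_res.bc_m if m_res else np.nan,
                "bc_s": s_res.bc_s if s_res else np.nan,
                "bc_d": d_res.bc_d if d_res else np.nan,
                "bc_m_significant": bool(m_sig),
                "bc_s_significant": bool(s_sig),
                "best_aspect_index": d_res.best_aspect_index if d_res else -1,
            }
        )

    table = pd.DataFrame(rows, columns=COUPLING_COLUMNS)
    return SessionAnalysis(
        session_id=ses.session_id,
        excluded=False,
        log=log,
        table=table,
        events=events,
        kinematics=kin,
        c_pop_full=c_full,
        c_pop_halves=halves,
        c_pop_motion=c_motion,
        c_pop_rest=c_rest,
        waveforms=waveforms,
    )


def analyze_pooled(
    analyses: list[SessionAnalysis],
    config: RunConfig | None = None,
    rng: np.random.Generator | int | None = None,
    metrics: tuple[str, ...] = ("bc_m", "bc_s", "bc_d"),
) -> PooledAnalysis:
    """Pooled peak inference across the retained sessions."""
    if config is None:
        config = RunConfig()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    kept = [a for a in analyses if not a.excluded]
    if not kept:
        raise ValueError("no retained sessions to pool")
    table = pd.concat([a.table for a in kept], ignore_index=True)
    log: list[str] = []

    peak_tests: dict[str, peaks.PeakTestResult] = {}
    norm_tests: dict[str, peaks.PeakTestResult] = {}
    consistency: dict[str, peaks.ConsistencyCountResult | None] = {}
    curves: dict[str, pd.DataFrame] = {}

    for metric in metrics:
        sub = table.dropna(subset=["c_pop", metric])
        x = sub["c_pop"].to_numpy()
        y = sub[metric].to_numpy()
        peak_tests[metric] = peaks.peak_permutation_test(
            x, y, config.n_shuffles, rng
        )
        window = max(5, min(x.size, x.size // 5))
        curves[metric] = peaks.moving_quartile_summary(x, y, window)

        per_session = {
            sid: (g["c_pop"].to_numpy(), g[metric].to_numpy())
            for sid, g in sub.groupby("session_id")
        }
        normed, nlog = peaks.median_normalize(per_session)
        log += nlog
        if normed:
            nx = np.concatenate([v[0] for v in normed.values()])
            ny = np.concatenate([v[1] for v in normed.values()])
            norm_tests[metric] = peaks.peak_permutation_test(
                nx, ny, config.n_shuffles, rng
            )
        try:
            consistency[metric] = peaks.consistency_count_test(
                list(per_session.values()),
                config.n_randomizations,
                rng,
                config.min_units,
            )
        except ValueError as err:
            log.append(f"{metric}: consistency test skipped ({err})")
            consistency[metric] = None

    return PooledAnalysis(table, peak_tests, norm_tests, consistency, curves, log)
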