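"""Session data model, delimited-text I/O, and unit/session exclusion rules.

A *session* is one recording: per-unit spike times (seconds from session
start) plus, optionally, 3D trajectories of eight reflective beads tracked at
100 Hz along the animal's head, back, hips, and tail base.  Spike files and
bead files are plain CSV so that synthetic sessions round-trip losslessly.

Exclusion rules applied before any coupling analysis:

* units firing below ``min_rate_hz`` (default 0.5 Hz, whole-session rate) are
  dropped — population and body coupling are poorly estimated for sparse
  trains;
* sessions left with fewer than ``min_units`` (default 5) units are flagged
  excluded — population coupling is meaningless for tiny populations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BEAD_LABELS",
    "SpikeTrainSet",
    "BeadTrajectories",
    "Session",
    "ExclusionResult",
    "read_spikes",
    "write_spikes",
    "read_beads",
    "write_beads",
    "apply_exclusions",
    "COUPLING_COLUMNS",
    "empty_coupling_table",
    "write_coupling_table",
    "read_coupling_table",
]

#: Fixed anatomical ordering of the eight tracking beads.
BEAD_LABELS = (
    "head",
    "neck_base",
    "back_1",
    "back_2",
    "back_3",
    "back_4",
    "hips",
    "tail_base",
)

#: Columns of the per-unit coupling table (one row per retained unit).
COUPLING_COLUMNS = [
    "session_id",
    "unit_id",
    "rate_hz",
    "c_pop",
    "bc_m",
    "bc_s",
    "bc_d",
    "bc_m_significant",
    "bc_s_significant",
    "best_aspect_index",
]


@dataclass
class SpikeTrainSet:
    """Spike times for one session's sorted units.

    ``spike_times[k]`` holds the sorted spike times (s) of ``unit_ids[k]``;
    all times lie in ``[0, duration_s)``.
    """

    unit_ids: list[str]
    spike_times: list[np.ndarray]
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if len(self.unit_ids) != len(self.spike_times):
            raise ValueError("unit_ids and spike_times length mismatch")
        clean = []
        for uid, t in zip(self.unit_ids, self.spike_times):
            t = np.asarray(t, dtype=float)
            if t.ndim != 1:
                raise ValueError(f"unit {uid}: spike times must be 1-D")
            if np.any(~np.isfinite(t)):
                raise ValueError(f"unit {uid}: non-finite spike time")
            if t.size and (t[0] < 0 or t[-1] >= self.duration_s):
                raise ValueError(
                    f"unit {uid}: spike times must lie in [0, duration_s)"
                )
            if np.any(np.diff(t) < 0):
                raise ValueError(f"unit {uid}: spike times not sorted")
            clean.append(t)
        self.spike_times = clean

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def rates_hz(self) -> np.ndarray:
        """Whole-session firing rate (total spikes / duration) per unit."""
        return np.array([t.size for t in self.spike_times]) / self.duration_s

    def subset(self, keep: Sequence[int]) -> "SpikeTrainSet":
        return SpikeTrainSet(
            [self.unit_ids[i] for i in keep],
            [self.spike_times[i] for i in keep],
            self.duration_s,
        )


@dataclass
class BeadTrajectories:
    """3D positions (mm) of the eight beads on a uniform 100 Hz grid.

    ``positions`` has shape ``(8, n_samples, 3)`` ordered as `BEAD_LABELS`.
    """

    positions: np.ndarray
    sample_rate_hz: float = 100.0
    bead_labels: tuple[str, ...] = BEAD_LABELS
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_beads, n_samples, 3)")
        if self.positions.shape[0] != len(self.bead_labels):
            raise ValueError("positions/bead_labels mismatch")
        if len(self.bead_labels) != 8:
            raise ValueError("exactly 8 beads are required")
        if np.any(~np.isfinite(self.positions)):
            raise ValueError("bead positions contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz


def _default_condition() -> dict:
    return {"drug": "none", "route": "systemic", "dose": 0.0, "dose_units": ""}


@dataclass
class Session:
    """One recording: spikes, optional bead trajectories, condition metadata."""

    session_id: str
    spikes: SpikeTrainSet
    beads: BeadTrajectories | None = None
    condition: dict = field(default_factory=_default_condition)

    def __post_init__(self) -> None:
        if self.beads is not None:
            tol = 1.0 / self.beads.sample_rate_hz + 1e-9
            if abs(self.beads.duration_s - self.spikes.duration_s) > tol:
                raise ValueError(
                    "spike duration and bead duration disagree by more than "
                    "one motion sample"
                )


@dataclass
class ExclusionResult:
    """Outcome of `apply_exclusions`: filtered session, flag, and audit log."""

    session: Session
    excluded: bool
    log: list[str]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_spikes(path: str | Path, duration_s: float | None = None) -> SpikeTrainSet:
    """Read a ``unit_id,spike_time_s`` CSV into a `SpikeTrainSet`.

    ``duration_s`` defaults to the maximum spike time rounded up to the next
    whole second.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"unit_id": str}, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no spike rows")
    if list(df.columns[:2]) != ["unit_id", "spike_time_s"]:
        raise ValueError(f"{path}: expected header 'unit_id,spike_time_s'")
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(times.to_numpy()) | (times.to_numpy() < 0))
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(
            f"{path}: invalid spike time at line {bad[0] + 2}: "
            f"{df['spike_time_s'].iloc[bad[0]]!r}"
        )
    df["spike_time_s"] = times
    if duration_s is None:
        duration_s = float(np.ceil(times.max() + 1e-9))
    unit_ids = list(dict.fromkeys(df["unit_id"]))  # first-appearance order
    grouped = df.groupby("unit_id", sort=False)["spike_time_s"]
    by_unit = {uid: np.sort(g.to_numpy()) for uid, g in grouped}
    return SpikeTrainSet(unit_ids, [by_unit[u] for u in unit_ids], duration_s)


def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        (uid, t)
        for uid, ts in zip(spikes.unit_ids, spikes.spike_times)
        for t in ts
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "spike_time_s"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_beads(path: str | Path, max_gap_s: float = 0.1) -> BeadTrajectories:
    """Read a ``time_s,bead_label,x_mm,y_mm,z_mm`` CSV into `BeadTrajectories`.

    The time column must form a uniform 100 Hz grid (tolerance 1e-6 s).  Per
    bead, missing samples spanning at most ``max_gap_s`` are linearly
    interpolated; longer gaps raise an error.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time_s", "bead_label", "x_mm", "y_mm", "z_mm"]
    if list(df.columns[:5]) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    grid = np.unique(df["time_s"].to_numpy(dtype=float))
    if grid.size < 2:
        raise ValueError(f"{path}: too few samples")
    dt = np.diff(grid)
    rate = 1.0 / np.median(dt)
    if np.any(np.abs(dt - np.median(dt)) > 1e-6):
        raise ValueError(f"{path}: non-uniform sampling grid")
    missing = set(BEAD_LABELS) - set(df["bead_label"].unique())
    if missing:
        raise ValueError(f"{path}: missing bead label(s): {sorted(missing)}")
    n = grid.size
    pos = np.full((8, n, 3), np.nan)
    idx_of = {round(t * rate): i for i, t in enumerate(grid - grid[0])}
    max_gap = int(round(max_gap_s * rate))
    for b, label in enumerate(BEAD_LABELS):
        sub = df[df["bead_label"] == label]
        rows = [idx_of[round(t * rate)] for t in sub["time_s"].to_numpy() - grid[0]]
        pos[b, rows, :] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        nanmask = np.isnan(pos[b, :, 0])
        if nanmask[0] or nanmask[-1]:
            raise ValueError(f"{path}: bead {label}: missing edge sample")
        if nanmask.any():
            # locate runs of consecutive missing samples
            edges = np.flatnonzero(np.diff(nanmask.astype(int)))
            starts, stops = edges[::2] + 1, edges[1::2] + 1
            for s, e in zip(starts, stops):
                if (e - s) > max_gap:
                    raise ValueError(
                        f"{path}: bead {label}: gap too long "
                        f"({(e - s) / rate:.3f} s > {max_gap_s} s)"
                    )
            good = ~nanmask
            for c in range(3):
                pos[b, nanmask, c] = np.interp(
                    grid[nanmask], grid[good], pos[b, good, c]
                )
    return BeadTrajectories(pos, sample_rate_hz=rate, start_time_s=float(grid[0]))


def write_beads(beads: BeadTrajectories, path: str | Path) -> None:
    t = beads.times_s()
    frames = []
    for b, label in enumerate(beads.bead_labels):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "bead_label": label,
                    "x_mm": beads.positions[b, :, 0],
                    "y_mm": beads.positions[b, :, 1],
                    "z_mm": beads.positions[b, :, 2],
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

def apply_exclusions(
    session: Session,
    min_rate_hz: float = 0.5,
    min_units: int = 5,
) -> ExclusionResult:
    """Drop low-rate units, then flag the session if too few units survive.

    Idempotent: re-applying to the filtered session changes nothing.
    """
    rates = session.spikes.rates_hz()
    keep = [i for i, r in enumerate(rates) if r >= min_rate_hz]
    log = [
        f"unit {session.spikes.unit_ids[i]}: excluded, rate "
        f"{rates[i]:.4f} Hz < {min_rate_hz} Hz"
        for i in range(len(rates))
        if i not in set(keep)
    ]
    filtered = dataclasses.replace(session, spikes=session.spikes.subset(keep))
    excluded = len(keep) < min_units
    if excluded:
        log.append(
            f"session {session.session_id}: excluded, {len(keep)} units "
            f"< {min_units} after rate filter"
        )
    return ExclusionResult(filtered, excluded, log)


# ---------------------------------------------------------------------------
# coupling table
# ---------------------------------------------------------------------------

def empty_coupling_table() -> pd.DataFrame:
    return pd.DataFrame(columns=COUPLING_COLUMNS)


def write_coupling_table(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, COUPLING_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_coupling_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"session_id": str, "unit_id": str})
    for col in ("bc_m_significant", "bc_s_significant"):
        df[col] = df[col].astype(bool)
    return df
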