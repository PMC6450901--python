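"""Peaked-relationship inference between body coupling and population coupling.

The *peakiness* statistic asks whether y rises and then falls as a function
of x.  Every observed x value — excluding the 10 smallest and 10 largest
points — is tried as a candidate peak location x*.  For each candidate,
``rho_left`` is the Spearman correlation over points with x < x* and
``rho_right`` over points with x > x*; a genuine peak needs rho_left > 0 and
rho_right < 0.  The candidate's peakiness is ``P = min(rho_left,
-rho_right)``, so P = 1 only when both flanks are perfectly monotone, and
the reported x* maximizes P.  When no candidate qualifies, P = 0 and x* is
undefined.  Significance comes from re-running the scan on datasets with y
randomly permuted against x.

The per-session consistency test fits a quadratic to each session's (x, y)
points and deems a session consistent with a pooled peak at x* if either
(1) the fit curves downward with its maximum within 10% of the pooled
x-range from x*, or (2) the session's x values lie mostly on one side of x*
(more than half of the session's x span) and the fit's mean slope on that
side points toward the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PeakScan",
    "PeakTestResult",
    "SessionFitResult",
    "ConsistencyCountResult",
    "peakiness",
    "peak_permutation_test",
    "session_consistency",
    "consistency_count_test",
    "median_normalize",
    "moving_quartile_summary",
]

_MIN_POINTS = 21  # 10 excluded at each extreme + at least one candidate


def _ranks(v: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), mergesort-stable; fast path when tie-free."""
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    ranks = np.empty(v.size)
    ranks[order] = np.arange(1, v.size + 1)
    if (sv[1:] == sv[:-1]).any():
        return rankdata(v)
    return ranks


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if undefined."""
    if a.size < 2:
        return np.nan
    ra = _ranks(a)
    rb = _ranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        return np.nan
    return float((ra @ rb) / denom)


class _PeakScanner:
    """Candidate-scan machinery with the x side precomputed.

    The permutation test re-scans the same x against many permuted y
    vectors; everything that depends only on x (sort order, candidate flank
    boundaries, centred flank x-ranks) is computed once here.
    """

    def __init__(self, x: np.ndarray):
        if np.any(~np.isfinite(x)):
            raise ValueError("x must be finite")
        if x.size < _MIN_POINTS:
            raise ValueError(f"need at least {_MIN_POINTS} points, got {x.size}")
        self.order = np.argsort(x, kind="stable")
        self.xs = x[self.order]
        self.cand = np.unique(self.xs[10:-10])
        self.bounds = [
            (
                int(np.searchsorted(self.xs, c, side="left")),
                int(np.searchsorted(self.xs, c, side="right")),
            )
            for c in self.cand
        ]
        self.left_rx = []
        self.right_rx = []
        for i, j in self.bounds:
            for store, seg in ((self.left_rx, self.xs[:i]), (self.right_rx, self.xs[j:])):
                if seg.size < 2:
                    store.append(None)
                    continue
                r = _ranks(seg)
                r -= r.mean()
                ss = float(r @ r)
                store.append((r, ss) if ss > 0 else None)

    def _flank_rho(self, side, k: int, yseg: np.ndarray) -> float:
        pre = side[k]
        if pre is None:
            return np.nan
        rx, ssx = pre
        ry = _ranks(yseg)
        ry = ry - ry.mean()
        ssy = float(ry @ ry)
        if ssy == 0:
            return np.nan
        return float((rx @ ry) / np.sqrt(ssx * ssy))

    def scan(self, y: np.ndarray, with_table: bool = False) -> PeakScan:
        ys = y[self.order]
        rows = []
        best = (0.0, np.nan, np.nan, np.nan)
        for k, c in enumerate(self.cand):
            i, j = self.bounds[k]
            rho_l = self._flank_rho(self.left_rx, k, ys[:i])
            rho_r = self._flank_rho(self.right_rx, k, ys[j:])
            valid = (
                np.isfinite(rho_l) and np.isfinite(rho_r)
                and rho_l > 0 and rho_r < 0
            )
            p = min(rho_l, -rho_r) if valid else np.nan
            if with_table:
                rows.append((c, rho_l, rho_r, p))
            if valid and p > best[0]:
                best = (p, c, rho_l, rho_r)
        table = pd.DataFrame(
            rows, columns=["x", "rho_left", "rho_right", "peakiness"]
        )
        return PeakScan(best[1], best[0], best[2], best[3], table)


@dataclass
class PeakScan:
    """Result of one peakiness candidate scan."""

    x_star: float  # NaN when no valid candidate
    peakiness: float
    rho_left: float
    rho_right: float
    candidates: pd.DataFrame  # x, rho_left, rho_right, peakiness (NaN = invalid)


@dataclass
class PeakTestResult:
    x_star: float
    peakiness: float
    rho_left: float
    rho_right: float
    p_value: float
    n_shuffles: int
    candidates: pd.DataFrame


@dataclass
class SessionFitResult:
    coefficients: tuple[float, float, float]  # (a2, a1, a0)
    fit_max_x: float  # NaN when a2 >= 0
    consistent: bool
    criterion: str  # curvature+location | slope-left | slope-right | none


@dataclass
class ConsistencyCountResult:
    observed_count: int
    n_sessions: int
    p_value: float
    n_randomizations: int
    pooled_x_star: float
    session_fits: list[SessionFitResult] = field(default_factory=list)


def peakiness(x: np.ndarray, y: np.ndarray) -> PeakScan:
    """Scan candidate peak locations and return the maximizing one.

    Points exactly tied with a candidate x* belong to neither flank.
    Raises on fewer than 21 points (no admissible candidate remains after
    excluding the 10 extreme points at each end).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    return _PeakScanner(x).scan(y, with_table=True)


def peak_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> PeakTestResult:
    """Peakiness with a shuffle null: y randomly permuted against x.

    p = (1 + #{P_shuffle >= P_observed}) / (1 + n_shuffles).  The add-one
    form keeps p away from exactly zero, and counting ties (which occur as
    an atom at P = 0 when no candidate peak is valid) is what makes the
    estimator exactly super-uniform under the null; for continuous P the
    tie rule is immaterial.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    scanner = _PeakScanner(x)
    obs = scanner.scan(y, with_table=True)
    exceed = 0
    for _ in range(n_shuffles):
        if scanner.scan(rng.permutation(y)).peakiness >= obs.peakiness:
            exceed += 1
    p = (1 + exceed) / (1 + n_shuffles)
    return PeakTestResult(
        x_star=obs.x_star,
        peakiness=obs.peakiness,
        rho_left=obs.rho_left,
        rho_right=obs.rho_right,
        p_value=p,
        n_shuffles=n_shuffles,
        candidates=obs.candidates,
    )


def _quadratic_mean_slope(a2: float, a1: float, lo: float, hi: float) -> float:
    # mean of d/dx (a2 x^2 + a1 x + a0) over [lo, hi]
    return a2 * (lo + hi) + a1


def session_consistency(
    x: np.ndarray,
    y: np.ndarray,
    pooled_x_star: float,
    pooled_x_range: float,
    location_tol: float = 0.10,
    min_points: int = 5,
) -> SessionFitResult:
    """Quadratic-fit consistency of one session with the pooled peak."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {x.size}")
    a2, a1, a0 = np.polyfit(x, y, 2)
    fit_max_x = -a1 / (2 * a2) if a2 < 0 else np.nan

    if a2 < 0 and abs(fit_max_x - pooled_x_star) <= location_tol * pooled_x_range:
        return SessionFitResult((a2, a1, a0), fit_max_x, True, "curvature+location")

    xmin, xmax = float(x.min()), float(x.max())
    span = xmax - xmin
    if span > 0 and np.isfinite(pooled_x_star):
        split = np.clip(pooled_x_star, xmin, xmax)
        left_span = split - xmin
        right_span = xmax - split
        if left_span > span / 2:
            slope = _quadratic_mean_slope(a2, a1, xmin, split)
            if slope > 0:
                return SessionFitResult((a2, a1, a0), fit_max_x, True, "slope-left")
        elif right_span > span / 2:
            slope = _quadratic_mean_slope(a2, a1, split, xmax)
            if slope < 0:
                return SessionFitResult((a2, a1, a0), fit_max_x, True, "slope-right")
    return SessionFitResult((a2, a1, a0), fit_max_x, False, "none")


def _count_consistent(
    sessions: list[tuple[np.ndarray, np.ndarray]],
    pooled_x_star: float,
    pooled_x_range: float,
) -> tuple[int, list[SessionFitResult]]:
    fits = []
    count = 0
    for sx, sy in sessions:
        if not np.isfinite(pooled_x_star):
            fits.append(SessionFitResult((np.nan,) * 3, np.nan, False, "none"))
            continue
        fit = session_consistency(sx, sy, pooled_x_star, pooled_x_range)
        fits.append(fit)
        count += fit.consistent
    return count, fits


def consistency_count_test(
    sessions: list[tuple[np.ndarray, np.ndarray]],
    n_randomizations: int = 1000,
    rng: np.random.Generator | None = None,
    min_points: int = 5,
) -> ConsistencyCountResult:
    """Count consistent sessions and test the count against a shuffle null.

    The null shuffles y across all units and sessions, recomputes the pooled
    peak location, refits every session, and recounts; p = (1 + #{null count
    >= observed}) / (1 + n_randomizations).
    """
    if rng is None:
        rng = np.random.default_rng()
    kept = [
        (np.asarray(sx, float), np.asarray(sy, float))
        for sx, sy in sessions
        if np.asarray(sx).size >= min_points
    ]
    if len(kept) < 2:
        raise ValueError("need at least 2 sessions with enough units")
    pooled_x = np.concatenate([sx for sx, _ in kept])
    pooled_y = np.concatenate([sy for _, sy in kept])
    pooled_range = float(pooled_x.max() - pooled_x.min())
    sizes = np.cumsum([sx.size for sx, _ in kept])[:-1]

    scanner = _PeakScanner(pooled_x)
    obs_scan = scanner.scan(pooled_y)
    observed, fits = _count_consistent(kept, obs_scan.x_star, pooled_range)

    exceed = 0
    for _ in range(n_randomizations):
        perm_y = rng.permutation(pooled_y)
        scan = scanner.scan(perm_y)
        null_sessions = [
            (sx, py) for (sx, _), py in zip(kept, np.split(perm_y, sizes))
        ]
        null_count, _ = _count_consistent(null_sessions, scan.x_star, pooled_range)
        if null_count >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_randomizations)
    return ConsistencyCountResult(
        observed_count=observed,
        n_sessions=len(kept),
        p_value=p,
        n_randomizations=n_randomizations,
        pooled_x_star=obs_scan.x_star,
        session_fits=fits,
    )


def median_normalize(
    sessions: dict[str, tuple[np.ndarray, np.ndarray]],
    eps: float = 1e-9,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], list[str]]:
    """Divide each session's x and y by their session medians.

    Sessions whose |median| falls below ``eps`` on either axis are dropped
    and logged.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    log: list[str] = []
    for sid, (sx, sy) in sessions.items():
        sx = np.asarray(sx, float)
        sy = np.asarray(sy, float)
        mx, my = np.median(sx), np.median(sy)
        if abs(mx) < eps or abs(my) < eps:
            log.append(f"session {sid}: near-zero median, excluded from normalization")
            continue
        out[sid] = (sx / mx, sy / my)
    return out, log


def moving_quartile_summary(
    x: np.ndarray, y: np.ndarray, window: int
) -> pd.DataFrame:
    """Sliding-window median/quartile summary of y along sorted x.

    Fixed point-count windows slide one point at a time; each row reports
    the window's median x and the median, Q1, and Q3 of y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if window < 5 or window > x.size:
        raise ValueError("window must be in [5, n_points]")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    rows = []
    for i in range(x.size - window + 1):
        w = ys[i : i + window]
        rows.append(
            (
                np.median(xs[i : i + window]),
                np.median(w),
                np.percentile(w, 25),
                np.percentile(w, 75),
            )
        )
    return pd.DataFrame(rows, columns=["x", "median", "q1", "q3"])
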