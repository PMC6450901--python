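"""Population coupling of spike trains.

For unit *i* with spike counts ``f_i(t)`` in bins of width Delta, total spike
count ``N_i``, and the mean-subtracted summed counts of every *other* unit

    P_i(t) = sum_{j != i} (f_j(t) - mu_j),

population coupling is

    C_pop_i = (1/N_i) * sum_t f_i(t) * P_i(t).

It is dimensionless, positive for units that co-fluctuate with the rest of
the population, negative for anticorrelated units, and ~0 for independent
ones.  The default bin width is 0.25 s; 0.1/0.05/0.01 s are the standard
robustness variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import SpikeTrainSet

__all__ = [
    "BIN_WIDTHS_S",
    "BinnedCounts",
    "PopulationCouplingResult",
    "bin_spikes",
    "population_coupling",
    "split_population_coupling",
    "half_session_coupling",
    "motion_mask",
]

#: Default bin width plus robustness set (seconds).
BIN_WIDTHS_S = (0.25, 0.1, 0.05, 0.01)


@dataclass
class BinnedCounts:
    """Unit x time-bin spike-count matrix at a fixed bin width."""

    counts: np.ndarray  # (n_units, n_bins) non-negative ints
    bin_width_s: float
    unit_ids: list[str]

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class PopulationCouplingResult:
    c_pop: np.ndarray  # per unit; NaN where undefined
    bin_width_s: float
    n_units: int
    total_spikes: np.ndarray  # N_i within the analysed bins
    mean_counts: np.ndarray  # mu_i within the analysed bins
    unit_ids: list[str]
    log: list[str]


def bin_spikes(spikes: SpikeTrainSet, bin_width_s: float = 0.25) -> BinnedCounts:
    """Bin spike times into half-open bins [t, t + Delta).

    The trailing partial bin is discarded; a spike exactly at a bin edge
    belongs to the bin it opens.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    n_bins = int(np.floor(spikes.duration_s / bin_width_s + 1e-9))
    if n_bins < 1:
        raise ValueError("bin width larger than session duration")
    counts = np.zeros((spikes.n_units, n_bins), dtype=np.int64)
    for i, t in enumerate(spikes.spike_times):
        idx = np.floor(t / bin_width_s).astype(np.int64)
        idx = idx[idx < n_bins]
        counts[i] = np.bincount(idx, minlength=n_bins)
    return BinnedCounts(counts, bin_width_s, list(spikes.unit_ids))


def _c_pop(counts: np.ndarray) -> np.ndarray:
    """Vectorised C_pop; NaN for units with zero spikes."""
    counts = counts.astype(float)
    mu = counts.mean(axis=1)
    dev = counts - mu[:, None]
    total_dev = dev.sum(axis=0)
    pop = total_dev[None, :] - dev  # P_i(t) for every i at once
    num = np.einsum("it,it->i", counts, pop)
    n_spikes = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = num / n_spikes
    c[n_spikes == 0] = np.nan
    return c


def population_coupling(binned: BinnedCounts) -> PopulationCouplingResult:
    """C_pop for every unit; requires >= 2 units, each with >= 1 spike."""
    if binned.n_units < 2:
        raise ValueError("population coupling needs at least 2 units")
    n_spikes = binned.counts.sum(axis=1)
    if np.any(n_spikes == 0):
        silent = [u for u, n in zip(binned.unit_ids, n_spikes) if n == 0]
        raise ValueError(f"units with zero spikes in binned window: {silent}")
    return PopulationCouplingResult(
        c_pop=_c_pop(binned.counts),
        bin_width_s=binned.bin_width_s,
        n_units=binned.n_units,
        total_spikes=n_spikes,
        mean_counts=binned.counts.mean(axis=1),
        unit_ids=list(binned.unit_ids),
        log=[],
    )


def _partition_result(binned: BinnedCounts, sel: np.ndarray, label: str) -> PopulationCouplingResult:
    counts = binned.counts[:, sel]
    log: list[str] = []
    if counts.shape[1] == 0:
        log.append(f"{label}: empty partition, all C_pop undefined")
        c = np.full(binned.n_units, np.nan)
        return PopulationCouplingResult(
            c, binned.bin_width_s, binned.n_units,
            np.zeros(binned.n_units, dtype=int), np.full(binned.n_units, np.nan),
            list(binned.unit_ids), log,
        )
    n_spikes = counts.sum(axis=1)
    c = _c_pop(counts)
    for uid, n in zip(binned.unit_ids, n_spikes):
        if n == 0:
            log.append(f"{label}: unit {uid} silent, C_pop undefined")
    return PopulationCouplingResult(
        c, binned.bin_width_s, binned.n_units, n_spikes,
        counts.mean(axis=1) if counts.size else np.full(binned.n_units, np.nan),
        list(binned.unit_ids), log,
    )


def split_population_coupling(
    binned: BinnedCounts, mask: np.ndarray
) -> tuple[PopulationCouplingResult, PopulationCouplingResult]:
    """C_pop recomputed independently on the True-bins and the False-bins.

    N_i and mu_j are recomputed per partition.  Units silent in a partition
    (or an empty partition) get NaN and a log entry rather than an error.
    Returns ``(result_true, result_false)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != binned.n_bins:
        raise ValueError("mask length must equal n_bins")
    return (
        _partition_result(binned, mask, "partition_true"),
        _partition_result(binned, ~mask, "partition_false"),
    )


def half_session_coupling(
    binned: BinnedCounts,
) -> tuple[PopulationCouplingResult, PopulationCouplingResult]:
    """C_pop on the first floor(T/2) bins vs. the remaining bins."""
    mask = np.zeros(binned.n_bins, dtype=bool)
    mask[: binned.n_bins // 2] = True
    first, second = split_population_coupling(binned, mask)
    return first, second


def motion_mask(
    binned: BinnedCounts, mean_speed: np.ndarray, sample_rate_hz: float
) -> np.ndarray:
    """Per-bin motion label: mean speed within the bin > whole-session mean.

    True marks motion bins, False rest bins.
    """
    per_bin = int(round(binned.bin_width_s * sample_rate_hz))
    if per_bin < 1:
        raise ValueError("bin width below one motion sample")
    n = binned.n_bins * per_bin
    if mean_speed.size < n:
        raise ValueError("speed series shorter than the binned window")
    bin_speed = mean_speed[:n].reshape(binned.n_bins, per_bin).mean(axis=1)
    return bin_speed > mean_speed.mean()
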