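"""Binary probabilistic network model of a cortical population.

N binary neurons update synchronously.  Neuron *i* spikes at step *t* with
probability

    p_i(t) = sigma( [eta + sum_j W_ij s_j(t-1)] * r_i(t) ),

where sigma clips to [0, 1], ``eta`` is a constant external input, and the
activity-dependent adaptation factor

    r_i(t) = ( 1 + chi + alpha * sum_{tau=t-T_r}^{t-1} s_i(tau) )^-1

suppresses recently active neurons; ``chi`` shifts the adaptation offset and
models altered local inhibition (chi > 0: enhanced, chi < 0: reduced).

The signed connectivity ``W`` (input to *i* from *j*) is built in four
steps: (1) i.i.d. lognormal weights with variate mean 0.5 and variance 1;
(2) a random 20% of columns negated (inhibitory neurons); (3) per-row
pruning to lognormally distributed in-degrees (mean 20, variance 500);
(4) global division by the spectral radius so the leading eigenvalue has
modulus 1 (marginal stability).  The diagonal is zero (no self-coupling).

Population coupling of model neurons mimics the experimental measurement:
spike counts in 50-step bins, neurons partitioned into 50 disjoint subsets
of 20, and each neuron's coupling computed within its own subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coupling import _c_pop

__all__ = [
    "ModelParams",
    "WeightMatrix",
    "SimResult",
    "lognormal_underlying",
    "build_weight_matrix",
    "simulate",
    "model_population_coupling",
    "sweep",
    "SWEEP_PRESETS",
    "raster_frame",
]


@dataclass
class ModelParams:
    """Model and measurement parameters (defaults are the standard run)."""

    n_neurons: int = 1000
    frac_inhibitory: float = 0.2
    eta: float = 8e-4
    chi: float = 0.0
    alpha: float = 0.1
    t_r: int = 100
    n_steps: int = 50_000
    weight_mean: float = 0.5
    weight_var: float = 1.0
    indegree_mean: float = 20.0
    indegree_var: float = 500.0
    model_bin: int = 50
    subset_size: int = 20
    n_subsets: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.frac_inhibitory < 1:
            raise ValueError("frac_inhibitory must be in (0, 1)")
        if self.t_r < 1:
            raise ValueError("t_r must be >= 1")
        if self.subset_size * self.n_subsets > self.n_neurons:
            raise ValueError("subsets must fit inside the population")
        if 1 + self.chi <= 0:
            raise ValueError(
                f"chi={self.chi} invalid: 1 + chi must stay positive so the "
                "adaptation denominator cannot vanish"
            )


@dataclass
class WeightMatrix:
    W: sp.csr_matrix  # signed, spectral radius 1
    is_inhibitory: np.ndarray  # per-column flag
    raw_weight_mean: float  # mean of the step-1 lognormal draws
    in_degrees: np.ndarray  # per-row nonzero input counts
    spectral_radius_raw: float  # scale divided out in step 4


@dataclass
class SimResult:
    counts: np.ndarray  # (n_neurons, n_bins) spike counts in model_bin bins
    total_spikes: np.ndarray  # per neuron over all steps
    n_steps: int
    model_bin: int
    raster: list[np.ndarray] | None = None  # per-step active indices

    @property
    def rates(self) -> np.ndarray:
        """Per-neuron firing probability per step."""
        return self.total_spikes / self.n_steps


def lognormal_underlying(mean: float, var: float) -> tuple[float, float]:
    """Underlying-normal (mu, sigma) for a lognormal with given variate moments."""
    sigma2 = np.log(1 + var / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def build_weight_matrix(
    params: ModelParams, rng: np.random.Generator | int | None = None
) -> WeightMatrix:
    """Construct the signed, pruned, spectrally normalized connectivity."""
    rng = np.random.default_rng(rng)
    n = params.n_neurons
    mu_w, sig_w = lognormal_underlying(params.weight_mean, params.weight_var)
    raw = rng.lognormal(mu_w, sig_w, size=(n, n))
    raw_mean = float(raw.mean())

    n_inhib = int(round(params.frac_inhibitory * n))
    inhib_cols = rng.choice(n, size=n_inhib, replace=False)
    is_inhib = np.zeros(n, dtype=bool)
    is_inhib[inhib_cols] = True
    W = raw.copy()
    W[:, is_inhib] *= -1.0

    mu_k, sig_k = lognormal_underlying(params.indegree_mean, params.indegree_var)
    k = np.clip(np.rint(rng.lognormal(mu_k, sig_k, size=n)), 1, n - 1).astype(int)
    keep = np.zeros((n, n), dtype=bool)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        keep[i, rng.choice(others, size=k[i], replace=False)] = True
    W[~keep] = 0.0
    np.fill_diagonal(W, 0.0)

    Ws = sp.csr_matrix(W)
    try:
        vals = spla.eigs(Ws, k=1, which="LM", return_eigenvectors=False)
        radius = float(np.abs(vals[0]))
    except (spla.ArpackNoConvergence, RuntimeError):
        radius = float(np.max(np.abs(np.linalg.eigvals(W))))
    if radius <= 0:
        raise RuntimeError("degenerate connectivity: zero spectral radius")
    Ws = Ws / radius
    return WeightMatrix(
        W=sp.csr_matrix(Ws),
        is_inhibitory=is_inhib,
        raw_weight_mean=raw_mean,
        in_degrees=k,
        spectral_radius_raw=radius,
    )


def simulate(
    weights: WeightMatrix,
    params: ModelParams,
    rng: np.random.Generator | int | None = None,
    keep_raster: bool = False,
) -> SimResult:
    """Run the synchronous update from the all-silent initial state.

    The adaptation sum runs over however much history exists during the
    first ``t_r`` steps.
    """
    rng = np.random.default_rng(rng)
    n = params.n_neurons
    W = weights.W
    eta, chi, alpha = params.eta, params.chi, params.alpha
    if 1 + chi <= 0:
        raise ValueError(f"chi={chi} makes the adaptation denominator non-positive")

    s = np.zeros(n)
    ring = np.zeros((params.t_r, n), dtype=np.int8)
    hist_sum = np.zeros(n)
    n_bins = params.n_steps // params.model_bin
    counts = np.zeros((n, n_bins), dtype=np.int32)
    totals = np.zeros(n, dtype=np.int64)
    raster: list[np.ndarray] | None = [] if keep_raster else None

    for t in range(params.n_steps):
        r = 1.0 / (1.0 + chi + alpha * hist_sum)
        p = np.clip((eta + W @ s) * r, 0.0, 1.0)
        spikes = rng.random(n) < p
        slot = t % params.t_r
        hist_sum += spikes - ring[slot]
        ring[slot] = spikes
        s = spikes.astype(float)
        totals += spikes
        b = t // params.model_bin
        if b < n_bins:
            counts[spikes, b] += 1
        if raster is not None:
            raster.append(np.flatnonzero(spikes))

    return SimResult(counts, totals, params.n_steps, params.model_bin, raster)


def model_population_coupling(
    sim: SimResult,
    params: ModelParams,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[list[int]]]:
    """Per-neuron C_pop from disjoint random subsets of the population.

    Returns ``(c_pop, subsets)``; silent neurons get NaN.
    """
    rng = np.random.default_rng(rng)
    order = rng.permutation(params.n_neurons)
    c = np.full(params.n_neurons, np.nan)
    subsets = []
    for g in range(params.n_subsets):
        members = order[g * params.subset_size : (g + 1) * params.subset_size]
        subsets.append(sorted(int(m) for m in members))
        sub = sim.counts[members]
        vals = _c_pop(sub)  # NaN where a member never spiked
        c[members] = vals
    return c, subsets


SWEEP_PRESETS: dict[str, list[tuple[float, float]]] = {
    # (eta, chi) grids used for the input/inhibition sweeps
    "fig3c": [(8e-4, 0.2), (8e-4, 0.1), (8e-4, 0.0), (8e-4, -0.1), (8e-4, -0.2)],
    "fig3d": [(2e-4, 0.0), (4e-4, 0.0), (8e-4, 0.0), (1.6e-3, 0.0), (3.2e-3, 0.0)],
    "fig3e": [(4e-4, 0.1), (2e-3, 0.0), (5e-3, -0.1)],
}


def sweep(
    grid: list[tuple[float, float]] | str,
    params: ModelParams | None = None,
    seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Simulate every (eta, chi) grid point and summarize over seeds.

    Each seed builds its own connectivity and runs its own simulation;
    summaries (mean/variance of C_pop over neurons, mean rate) are averaged
    across seeds.
    """
    if isinstance(grid, str):
        grid = SWEEP_PRESETS[grid]
    if params is None:
        params = ModelParams()
    if seeds is None:
        seeds = [0, 1, 2]
    if len(seeds) < 1:
        raise ValueError("at least one seed required")
    rows = []
    for eta, chi in grid:
        p = replace(params, eta=eta, chi=chi)
        means, varis, rates = [], [], []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            wm = build_weight_matrix(p, rng)
            sim = simulate(wm, p, rng)
            c, _ = model_population_coupling(sim, p, rng)
            means.append(np.nanmean(c))
            varis.append(np.nanvar(c))
            rates.append(sim.rates.mean())
        rows.append(
            {
                "eta": eta,
                "chi": chi,
                "mean_c_pop": float(np.mean(means)),
                "var_c_pop": float(np.mean(varis)),
                "mean_rate": float(np.mean(rates)),
                "n_seeds": len(seeds),
            }
        )
    return pd.DataFrame(rows)


def raster_frame(sim: SimResult) -> pd.DataFrame:
    """Flatten a kept raster into a ``neuron_id,step`` table for CSV export."""
    if sim.raster is None:
        raise ValueError("simulation was run without keep_raster=True")
    rows = [
        (int(n), step)
        for step, active in enumerate(sim.raster)
        for n in active
    ]
    return pd.DataFrame(rows, columns=["neuron_id", "step"])
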