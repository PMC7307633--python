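"""Two-layer dendritic integration model: clustered vs distributed input.

A layer-2 neuron is modeled as a two-layer unit: it fires when the total
number of active input synapses reaches the distributed threshold
``n_dist`` (linear somatic integration), or when any single dendritic
branch receives at least ``n_clus`` active synapses, triggering a local
NMDA-spike that propagates to the soma.  Synapse counts are Poisson;
assuming constant synaptic density, a branch of length BL on a dendrite of
total length TDBL receives a Poisson(S * BL / TDBL) share of S active
synapses, and the branches are independent (Poisson splitting).  The
clustered response probability is then

    P = 1 - (1 - P[Pois(S*BL/TDBL) >= n_clus])**(TDBL/BL),

so the dendritic-spike probability grows with mean branch length — long
branches concentrate input and favour clustered suprathreshold events.

Two tail variants are provided.  ``standard_tail`` is the usual Poisson
survival function P(X >= n) = 1 - sum_{k=0}^{n-1} pmf(k).  ``printed_eq``
starts the sum at k = 1, omitting the k = 0 mass; it is kept for exact
replication of the source formula but is not a valid tail probability
(``printed_eq >= standard_tail`` pointwise, and equals 1 at n = 1).

The census defaults describe mouse aPCx: 3700 bulbar glomeruli, 9.7e7
glomerulus-to-layer-2 synapses, 41,000 layer-2 neurons, at most 70
synapses activated on one neuron per odor; branch lengths 40-110 µm
(mean 72) and TDBL ~1800 µm at the start of the critical period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VARIANTS = ("standard_tail", "printed_eq")
MODES = ("clustered", "distributed", "combined")


@dataclass(frozen=True)
class IntegrationModelParams:
    n_glomeruli: int = 3700
    total_synapses: float = 9.7e7
    n_neurons: int = 41_000
    s_max: int = 70                  # max active synapses per neuron per odor
    n_dist: int = 40                 # somatic threshold, distributed input
    n_clus: int = 10                 # same-branch threshold for a dendritic spike
    tdbl: float = 1800.0             # µm
    bl_min: float = 40.0             # µm
    bl_max: float = 110.0            # µm
    bl_mean: float = 72.0            # µm

    def __post_init__(self) -> None:
        if min(self.n_glomeruli, self.total_synapses, self.n_neurons,
               self.s_max, self.n_dist, self.n_clus, self.tdbl,
               self.bl_min, self.bl_max) <= 0:
            raise ValueError("all census parameters must be positive")
        if self.n_clus > self.n_dist:
            raise ValueError("n_clus must not exceed n_dist")
        if self.bl_max > self.tdbl:
            raise ValueError("branch length cannot exceed TDBL")


def poisson_exceedance(lam: float, n: int, variant: str = "standard_tail") -> float:
    """P(X >= n) for X ~ Poisson(lam), or the printed k=1-start variant.

    standard_tail uses the survival function (numerically stable for large
    lam); printed_eq adds back the omitted k = 0 mass, 1 - sum_{k=1}^{n-1}.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    tail = float(stats.poisson.sf(n - 1, lam))
    if variant == "printed_eq":
        tail = min(1.0, tail + float(np.exp(-lam)))
    return tail


def response_probability(params: IntegrationModelParams, s: float, bl: float,
                         mode: str = "clustered",
                         variant: str = "standard_tail",
                         integer_branches: bool = False,
                         n_trials: int = 100_000, seed: int = 0) -> float:
    """Firing probability for S active synapses on a neuron of mean BL.

    clustered: probability that at least one branch collects >= n_clus
    synapses.  With ``integer_branches`` the dendrite has floor(TDBL/BL)
    branches of equal load S/NB (the discrete model the Monte-Carlo oracle
    samples exactly); otherwise the branch count enters as the real-valued
    exponent TDBL/BL with per-branch mean S*BL/TDBL.  distributed: total
    count reaches n_dist.  combined (fires via either route) has no closed
    form here and is estimated by Monte Carlo.
    """
    if s < 0:
        raise ValueError("S must be non-negative")
    if not 0 < bl <= params.tdbl:
        raise ValueError("BL must lie in (0, TDBL]")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "distributed":
        return 0.0 if s == 0 else poisson_exceedance(s, params.n_dist, variant)
    if mode == "combined":
        est, _ = monte_carlo_response(params, s, bl, "combined", n_trials, seed)
        return est
    if s == 0:
        return 0.0
    if integer_branches:
        nb = float(np.floor(params.tdbl / bl))
        lam_b = s / nb
    else:
        nb = params.tdbl / bl
        lam_b = s * bl / params.tdbl
    p_branch = poisson_exceedance(lam_b, params.n_clus, variant)
    return float(1.0 - (1.0 - p_branch) ** nb)


def monte_carlo_response(params: IntegrationModelParams, s: float, bl: float,
                         mode: str = "clustered", n_trials: int = 100_000,
                         seed: int = 0, batch: int = 50_000
                         ) -> tuple[float, float]:
    """Multinomial-placement Monte-Carlo estimate of the firing probability.

    Per trial, draw a Poisson(S) total synapse count and place each synapse
    uniformly on floor(TDBL/BL) branches; the neuron fires per the mode's
    threshold rule.  Returns (estimate, binomial SE); seeded and
    reproducible.
    """
    if n_trials < 1000:
        raise ValueError("n_trials must be >= 1000")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not 0 < bl <= params.tdbl:
        raise ValueError("BL must lie in (0, TDBL]")
    if s == 0:
        return 0.0, 0.0
    nb = max(1, int(params.tdbl // bl))
    rng = np.random.default_rng(seed)
    fires = 0
    done = 0
    pvals = np.full(nb, 1.0 / nb)
    while done < n_trials:
        m = min(batch, n_trials - done)
        totals = rng.poisson(s, size=m)
        counts = rng.multinomial(totals, pvals)   # (m, nb)
        clustered = (counts >= params.n_clus).any(axis=1)
        distributed = totals >= params.n_dist
        if mode == "clustered":
            fire = clustered
        elif mode == "distributed":
            fire = distributed
        else:
            fire = clustered | distributed
        fires += int(fire.sum())
        done += m
    p = fires / n_trials
    se = float(np.sqrt(p * (1 - p) / n_trials))
    return float(p), se


@dataclass
class CircuitCensus:
    synapses_per_neuron: int
    glomeruli_per_odor: int
    max_branches: int
    min_branches: int


def derive_census(params: IntegrationModelParams = IntegrationModelParams()
                  ) -> CircuitCensus:
    """Derived circuit constants from the census parameters.

    synapses/neuron = round(total synapses / neurons); glomeruli activated
    per odor = floor(glomeruli * S_max / synapses-per-neuron); branch-count
    extremes = floor(TDBL / BL) at the shortest and longest mean BL.
    """
    if params.n_neurons == 0 or params.bl_min == 0 or params.bl_max == 0:
        raise ValueError("zero denominator in census derivation")
    spn = int(round(params.total_synapses / params.n_neurons))
    return CircuitCensus(
        synapses_per_neuron=spn,
        glomeruli_per_odor=int(params.n_glomeruli * params.s_max // spn),
        max_branches=int(params.tdbl // params.bl_min),
        min_branches=int(params.tdbl // params.bl_max),
    )


@dataclass
class ResponseCurve:
    bl_grid: np.ndarray
    s_values: np.ndarray
    probabilities: np.ndarray        # shape (len(s_values), len(bl_grid))
    mode: str
    variant: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.s_values):
            for j, bl in enumerate(self.bl_grid):
                rows.append({"S": s, "BL": bl,
                             "probability": self.probabilities[i, j],
                             "mode": self.mode, "variant": self.variant})
        return pd.DataFrame(rows)


def response_curve(params: IntegrationModelParams, bl_grid, s_values,
                   mode: str = "clustered", variant: str = "standard_tail",
                   **kwargs) -> ResponseCurve:
    """Response probability over a BL grid for several synapse counts S.

    For the clustered mode (continuous branch count) the probability is
    non-decreasing along BL and along S; this analytic property is asserted
    post hoc.
    """
    bl_grid = np.asarray(bl_grid, dtype=float)
    s_values = np.asarray(s_values, dtype=float)
    if bl_grid.size == 0 or s_values.size == 0:
        raise ValueError("empty BL grid or S list")
    probs = np.empty((s_values.size, bl_grid.size))
    for i, s in enumerate(s_values):
        for j, bl in enumerate(bl_grid):
            probs[i, j] = response_probability(params, float(s), float(bl),
                                               mode, variant, **kwargs)
    if mode == "clustered" and not kwargs.get("integer_branches", False):
        assert (np.diff(probs, axis=1) >= -1e-12).all(), \
            "clustered response must be non-decreasing in BL"
        if (np.diff(s_values) > 0).all():
            assert (np.diff(probs, axis=0) >= -1e-12).all(), \
                "clustered response must be non-decreasing in S"
    return ResponseCurve(bl_grid, s_values, probs, mode, variant)


def plot_response_curve(curve: ResponseCurve, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, s in enumerate(curve.s_values):
        ax.plot(curve.bl_grid, curve.probabilities[i], label=f"S = {s:g}")
    ax.set_xlabel("mean branch length BL (µm)")
    ax.set_ylabel("response probability")
    ax.set_title(f"{curve.mode} ({curve.variant})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
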