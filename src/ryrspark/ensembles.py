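"""Ensemble waiting-time estimation and parameter sweeps.

The mean spark waiting time T under a given condition is estimated by
averaging independent first-passage runs (default 50).  The error bar
follows the set-splitting protocol: the runs are divided into 5 independent
sets and the reported spread is the sample standard deviation of the 5
set means.  Sweeps cover the four axes that control spark timing: bulk Ca
``c0``, inter-channel coupling ``sigma``, bond-survival probability ``p``
(cluster fragmentation), and clustering parameter ``alpha`` (morphology
compactness).  For the p and alpha axes a fresh random graph is generated
for every run, with graph and gating randomness drawn from independent,
recorded seed streams so either can be reproduced separately.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import CouplingGraph, dilute_bonds, full_lattice, grow_preferential, lattice_to_graph
from .gillespie import DEFAULT_MAX_EVENTS, DEFAULT_T_MAX, first_passage_time
from .model import RateParams

__all__ = ["GraphSpec", "SweepResult", "mean_waiting_time", "sweep", "spark_frequency",
           "results_to_dataframe", "results_to_json", "SWEEP_AXES"]

SWEEP_AXES = ("c0", "sigma", "p", "alpha")

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class GraphSpec:
    """Recipe for a cluster coupling graph, possibly random.

    Either a full ``rows x cols`` lattice, or (when ``n_channels`` and
    ``alpha`` are set) a preferential-attachment morphology of
    ``n_channels`` channels grown on the ``rows x cols`` grid.  ``p`` < 1
    additionally dilutes inter-channel bonds.  A spec is *random* when it
    involves morphology growth or nontrivial dilution; random specs are
    rebuilt freshly for every simulation run.
    """

    topology: str = "oblique"
    rows: int = 10
    cols: int = 10
    n_channels: int | None = None
    alpha: float | None = None
    p: float | None = None
    weight: float = 1.0
    growth_mode: str = "power"

    def __post_init__(self):
        if self.topology not in ("adjoining", "oblique"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if (self.n_channels is None) != (self.alpha is None):
            raise ValueError("n_channels and alpha must be given together")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    @property
    def is_random(self) -> bool:
        return self.alpha is not None or (self.p is not None and self.p < 1.0)

    def build(self, seed: int | np.random.Generator | None = None) -> CouplingGraph:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if self.alpha is not None:
            lattice = grow_preferential(
                self.n_channels, self.rows, self.cols, self.alpha, rng, mode=self.growth_mode
            )
        else:
            lattice = full_lattice(self.rows, self.cols)
        graph = lattice_to_graph(lattice, self.topology, self.weight,
                                 seed=seed if isinstance(seed, (int, np.integer)) else None)
        if self.p is not None and self.p < 1.0:
            graph = dilute_bonds(graph, self.p, rng)
        return graph


@dataclass(frozen=True)
class SweepResult:
    """Ensemble waiting-time estimate under one condition.

    ``mean_T`` is the ensemble mean of the per-run waiting times (ms) and
    ``se_T`` its standard error estimated from the set-splitting protocol:
    the sample standard deviation of the set means divided by the square
    root of the number of sets (ms).  When any run
    was censored, ``lower_bound`` is set and ``mean_T`` underestimates the
    true mean.
    """

    topology: str
    rows: int
    cols: int
    n_channels: int
    c0: float
    sigma: float
    p: float | None
    alpha: float | None
    mean_T: float
    se_T: float
    n_runs: int
    n_censored: int
    master_seed: int
    run_seeds: tuple[int, ...] = field(repr=False, default=())
    times: tuple[float, ...] = field(repr=False, default=())
    lower_bound: bool = False

    def __post_init__(self):
        if self.mean_T <= 0:
            raise ValueError("mean_T must be > 0")
        if self.se_T < 0:
            raise ValueError("se_T must be >= 0")
        if self.n_censored > self.n_runs:
            raise ValueError("n_censored cannot exceed n_runs")


def _derive_seeds(master_seed: int | None, n_runs: int) -> tuple[int, np.ndarray, np.ndarray]:
    """Independent recorded integer seed streams for gating and graphs."""
    if master_seed is None:
        master_seed = int(np.random.SeedSequence().generate_state(1)[0] % _SEED_MOD)
    gate_seq, graph_seq = np.random.SeedSequence(int(master_seed)).spawn(2)
    gate = gate_seq.generate_state(n_runs, dtype=np.uint64) % _SEED_MOD
    graph = graph_seq.generate_state(n_runs, dtype=np.uint64) % _SEED_MOD
    return int(master_seed), gate.astype(np.int64), graph.astype(np.int64)


def mean_waiting_time(
    spec: GraphSpec | CouplingGraph,
    params: RateParams,
    n_runs: int = 50,
    master_seed: int | None = None,
    t_max: float = DEFAULT_T_MAX,
    n_sets: int = 5,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> SweepResult:
    """Ensemble mean spark waiting time under one condition.

    For a random :class:`GraphSpec` a fresh graph is built per run.  The
    error estimate splits the runs into ``n_sets`` consecutive sets and
    scales the sample standard deviation of the set means by 1/sqrt(n_sets),
    so ``n_runs`` must be divisible by ``n_sets``.  Censored runs enter the mean at their
    horizon value (making the estimate a flagged lower bound); an ensemble
    in which every run censored raises, reporting the lower bound.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_runs % n_sets != 0:
        raise ValueError(f"n_runs={n_runs} not divisible into {n_sets} sets")
    master_seed, gate_seeds, graph_seeds = _derive_seeds(master_seed, n_runs)

    fixed_graph = spec if isinstance(spec, CouplingGraph) else None
    times = np.empty(n_runs)
    n_censored = 0
    for r in range(n_runs):
        if fixed_graph is not None:
            graph = fixed_graph
        elif spec.is_random:
            graph = spec.build(int(graph_seeds[r]))
        else:
            graph = spec.build()
        res = first_passage_time(graph, params, t_max=t_max,
                                 seed=int(gate_seeds[r]), max_events=max_events)
        times[r] = res.T
        n_censored += res.censored
    if n_censored == n_runs:
        raise RuntimeError(
            f"all {n_runs} runs censored at t_max={t_max}; mean T > {times.mean():.6g} ms"
        )
    set_means = times.reshape(n_sets, -1).mean(axis=1)
    se = float(np.std(set_means, ddof=1) / np.sqrt(n_sets)) if n_sets > 1 else 0.0

    if fixed_graph is not None:
        topology = fixed_graph.topology
        rows, cols = fixed_graph.lattice.rows, fixed_graph.lattice.cols
        n_channels = fixed_graph.n_channels
        p = alpha = None
    else:
        topology, rows, cols = spec.topology, spec.rows, spec.cols
        n_channels = spec.n_channels if spec.n_channels is not None else spec.rows * spec.cols
        p, alpha = spec.p, spec.alpha
    return SweepResult(
        topology=topology, rows=rows, cols=cols, n_channels=n_channels,
        c0=params.c0, sigma=params.sigma, p=p, alpha=alpha,
        mean_T=float(times.mean()), se_T=se, n_runs=n_runs, n_censored=n_censored,
        master_seed=master_seed, run_seeds=tuple(int(s) for s in gate_seeds),
        times=tuple(float(t) for t in times), lower_bound=n_censored > 0,
    )


def sweep(
    axis: str,
    grid: Sequence[float],
    spec: GraphSpec,
    params: RateParams,
    n_runs: int = 50,
    master_seed: int | None = None,
    t_max: float = DEFAULT_T_MAX,
    n_sets: int = 5,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> list[SweepResult]:
    """Ensemble waiting times along one parameter axis.

    ``axis`` is one of ``c0`` / ``sigma`` (kinetic conditions) or ``p`` /
    ``alpha`` (morphology conditions, fresh random graph per run).  Each
    grid point gets its own child seed of ``master_seed``.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    if len(grid) == 0:
        raise ValueError("empty sweep grid")
    if master_seed is None:
        master_seed = int(np.random.SeedSequence().generate_state(1)[0] % _SEED_MOD)
    child_seeds = np.random.SeedSequence(int(master_seed)).generate_state(
        len(grid), dtype=np.uint64) % _SEED_MOD

    results = []
    for value, child in zip(grid, child_seeds):
        value = float(value)
        cond_params, cond_spec = params, spec
        if axis == "c0":
            cond_params = params.with_(c0=value)
        elif axis == "sigma":
            cond_params = params.with_(sigma=value)
        elif axis == "p":
            cond_spec = replace(spec, p=value)
        else:
            n_ch = spec.n_channels if spec.n_channels is not None else spec.rows * spec.cols
            cond_spec = replace(spec, alpha=value, n_channels=n_ch)
        results.append(
            mean_waiting_time(cond_spec, cond_params, n_runs=n_runs,
                              master_seed=int(child), t_max=t_max, n_sets=n_sets,
                              max_events=max_events)
        )
    return results


def spark_frequency(result: SweepResult) -> float:
    """Average spontaneous spark frequency, per ms: 1 / mean_T.

    When the ensemble contains censored runs (``result.lower_bound``), the
    returned frequency is an upper bound on the true rate; an ensemble
    dominated by censoring gives only that bound.
    """
    return 1.0 / result.mean_T


_CSV_COLUMNS = ["topology", "rows", "cols", "n_channels", "c0_uM", "sigma", "p",
                "alpha", "n_runs", "n_censored", "mean_T_ms", "se_T_ms", "master_seed"]


def results_to_dataframe(results: Sequence[SweepResult]) -> pd.DataFrame:
    """One row per condition in the standard sweep-CSV column order."""
    rows = [
        {
            "topology": r.topology, "rows": r.rows, "cols": r.cols,
            "n_channels": r.n_channels, "c0_uM": r.c0, "sigma": r.sigma,
            "p": r.p, "alpha": r.alpha, "n_runs": r.n_runs,
            "n_censored": r.n_censored, "mean_T_ms": r.mean_T,
            "se_T_ms": r.se_T, "master_seed": r.master_seed,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def results_to_json(results: Sequence[SweepResult], **kwargs) -> str:
    """Full JSON mirror including per-run times and seeds."""
    return json.dumps([asdict(r) for r in results], **kwargs)
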