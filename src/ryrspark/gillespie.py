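"""Exact stochastic simulation of cluster gating and spark first passage.

The direct-method Gillespie algorithm over all subunit flips: the time to
the next event is exponential with the total rate as parameter, and the
event is drawn with probability proportional to the individual subunit
rates.  :func:`first_passage_time` measures the spark waiting time T — from
the all-closed configuration to the first moment the conducting-channel
count reaches the threshold nc — and :func:`simulate_trajectory` records
the full (t, n_open) history of a run.  Spark termination (inactivation,
SR depletion, Ca clearance) is outside the model: runs end at the
threshold crossing or at the censoring horizon ``t_max``.

The production path is a compiled kernel (:mod:`ryrspark._kernels`);
:func:`step` and :func:`subunit_rates` provide a transparent pure-Python
reference used for fine-grained checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import CouplingGraph
from .model import ClusterState, RateParams, channel_open_flags, local_calcium, transition_rate

__all__ = [
    "AbsorbingStateError",
    "FirstPassageResult",
    "Trajectory",
    "first_passage_time",
    "simulate_trajectory",
    "step",
    "subunit_rates",
]

_STATUS_NAMES = {
    _kernels.THRESHOLD: "threshold",
    _kernels.TIME_CENSORED: "time_censored",
    _kernels.ABSORBING: "absorbing",
    _kernels.EVENT_CAP: "event_cap",
    _kernels.RECORD_FULL: "record_full",
}

DEFAULT_T_MAX = 1e8       # ms
DEFAULT_MAX_EVENTS = 10**9


class AbsorbingStateError(RuntimeError):
    """No transition has positive rate from the current state."""


@dataclass(frozen=True)
class FirstPassageResult:
    """Outcome of one spark-waiting-time run.

    ``T`` is the waiting time in ms; when ``censored`` it equals the
    censoring horizon and is a lower bound on the true waiting time.
    ``status`` distinguishes threshold crossing from time censoring, an
    absorbing start (e.g. kfo=0) and the event-count safety stop.
    """

    T: float
    censored: bool
    status: str
    n_events: int
    seed: int | None
    final_n_open: int
    t_max: float

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("waiting time must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """(time, conducting-channel count) recorded at every change of the count."""

    times: np.ndarray
    n_open: np.ndarray
    seed: int | None
    truncated: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.times) < 0):
            raise ValueError("trajectory times must be nondecreasing")


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seed_label(seed) -> int | None:
    return int(seed) if isinstance(seed, (int, np.integer)) else None


def compile_graph(graph: CouplingGraph, params: RateParams):
    """Neighbor/coefficient arrays consumed by the compiled kernel."""
    return graph.neighbor_arrays(params.sigma, params.delta)


_EMPTY_T = np.empty(0, dtype=np.float64)
_EMPTY_N = np.empty(0, dtype=np.int64)


def first_passage_time(
    graph: CouplingGraph,
    params: RateParams,
    t_max: float = DEFAULT_T_MAX,
    seed: int | np.random.Generator | None = None,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> FirstPassageResult:
    """Waiting time from all-closed to ``n_open >= params.nc``.

    Runs one exact SSA realization; returns a censored result (T = t_max,
    a lower bound) if the threshold is not reached by ``t_max`` or if no
    transition is possible.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    nbr, coeff, deg = compile_graph(graph, params)
    gen = _as_generator(seed)
    t, n_events, status, n_open, _ = _kernels.run_ssa(
        nbr, coeff, deg, params.open_subunit_min, params.nc,
        params.kfo, params.kb, params.c0, params.g,
        float(t_max), int(max_events), gen, False, _EMPTY_T, _EMPTY_N,
    )
    censored = status != _kernels.THRESHOLD
    T = float(t_max) if status == _kernels.ABSORBING else float(t)
    return FirstPassageResult(
        T=T, censored=censored, status=_STATUS_NAMES[status],
        n_events=int(n_events), seed=_seed_label(seed),
        final_n_open=int(n_open), t_max=float(t_max),
    )


def simulate_trajectory(
    graph: CouplingGraph,
    params: RateParams,
    t_end: float,
    seed: int | np.random.Generator | None = None,
    max_events: int = DEFAULT_MAX_EVENTS,
    record_max: int = 1 << 20,
) -> Trajectory:
    """Record (t, n_open) from all-closed until ``t_end``.

    The spark threshold does not stop the run; identical seeds reproduce
    identical trajectories.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    nbr, coeff, deg = compile_graph(graph, params)
    gen = _as_generator(seed)
    rec_t = np.empty(record_max, dtype=np.float64)
    rec_n = np.empty(record_max, dtype=np.int64)
    no_threshold = graph.n_channels + 1   # unreachable: never stops the run
    t_end = float(t_end)
    if t_end == 0.0:
        return Trajectory(np.zeros(1), np.zeros(1, dtype=np.int64), _seed_label(seed))
    t, n_events, status, n_open, n_rec = _kernels.run_ssa(
        nbr, coeff, deg, params.open_subunit_min, no_threshold,
        params.kfo, params.kb, params.c0, params.g,
        t_end, int(max_events), gen, True, rec_t, rec_n,
    )
    return Trajectory(
        times=rec_t[:n_rec].copy(),
        n_open=rec_n[:n_rec].copy(),
        seed=_seed_label(seed),
        truncated=status == _kernels.RECORD_FULL,
    )


# -- pure-Python reference path ------------------------------------------


def subunit_rates(state: ClusterState, graph: CouplingGraph, params: RateParams) -> np.ndarray:
    """Flip rate of every subunit in the current state (reference path).

    Computed independently of the incremental kernel bookkeeping, one call
    to :func:`~ryrspark.model.transition_rate` per subunit.
    """
    return np.array(
        [transition_rate((c, s), state, graph, params)
         for c in range(graph.n_channels) for s in range(4)]
    )


def step(
    state: ClusterState,
    graph: CouplingGraph,
    params: RateParams,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], float]:
    """One direct-method SSA event, mutating ``state`` in place.

    Draws the waiting increment dt ~ Exponential(total rate) and the flipped
    subunit with probability rate/total; returns ((channel, subunit), dt).
    Raises :class:`AbsorbingStateError` when no transition has positive rate.
    """
    rates = subunit_rates(state, graph, params)
    total = rates.sum()
    if total <= 0:
        raise AbsorbingStateError("total transition rate is zero")
    dt = rng.exponential(1.0 / total)
    idx = rng.choice(rates.size, p=rates / total)
    c, s = divmod(int(idx), 4)
    state.values[idx] *= -1
    return (c, s), float(dt)
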