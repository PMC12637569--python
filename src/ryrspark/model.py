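"""Kinetic model of coupled two-state RyR2 subunits.

Each RyR2 channel is a tetramer of identical two-state subunits
(closed ``s = -1`` / open ``s = +1``) arranged on a periodic ring.
Conformational mismatch between neighboring subunits carries an energetic
penalty, implemented as a multiplicative bias on the transition rates:

    k(-1 -> +1) = kfo * [Ca] * gamma_i        (opening, first order in Ca)
    k(+1 -> -1) = kb / gamma_i                (closing, Ca independent)

with the coupling factor

    gamma_i = exp( delta * (s_{i-1} + s_{i+1}) + sigma * sum_b w_b s_b )

where the ring sum runs over the two intra-tetramer neighbors and the second
sum over the subunit's surviving inter-channel contacts ``b`` (0, 1 or 2 of
them, relative weight ``w_b``; a broken contact contributes nothing).
``delta`` and ``sigma`` are both dimensionless interaction energies in
units of kT — ``delta`` the intra-tetramer mismatch penalty, ``sigma`` the
inter-channel contact strength.

The dyadic cleft is treated as well mixed (rapid-diffusion approximation):
with ``n`` channels conducting, the local Ca seen by every subunit is

    [Ca] = c0 + g * n

which closes the calcium-induced-calcium-release feedback loop.  A channel
conducts when at least ``open_subunit_min`` (default 3) of its four subunits
are open; a spark is declared when the conducting-channel count first
reaches the threshold ``nc``.

At fixed Ca (``g = 0``) the dynamics satisfy detailed balance with respect
to the Ising-like energy

    E(s) = -delta * sum_ring s s' - sigma * sum_inter w s s' - h * sum_i s_i,
    h = (1/2) * ln(kfo * c0 / kb),

which makes the model thermodynamically consistent; the Ca feedback (g > 0)
breaks reversibility but not the validity of the master equation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .geometry import RING_NEIGHBORS, CouplingGraph

__all__ = [
    "RateParams",
    "ClusterState",
    "local_calcium",
    "coupling_factor",
    "transition_rate",
    "channel_open_flags",
]


@dataclass(frozen=True)
class RateParams:
    """Kinetic and coupling constants.

    Parameters
    ----------
    kfo : float
        Ca-binding rate constant, per uM per ms. Opening rate is kfo*[Ca].
    kb : float
        Subunit closing rate, per ms (mean open dwell ~ 1/kb).
    delta : float
        Dimensionless mismatch penalty for intra-tetramer neighbor disagreement.
    sigma : float
        Dimensionless inter-channel contact energy (applied to both
        contacts of the adjoining geometry).
    g : float
        Dyadic Ca increment per conducting channel, uM.
    c0 : float
        Bulk (diastolic) Ca concentration, uM.
    open_subunit_min : int
        Open subunits required for a channel to conduct (majority rule).
    nc : int
        Conducting-channel count defining spark initiation.
    """

    kfo: float = 0.005
    kb: float = 0.3
    delta: float = 0.5
    sigma: float = 0.5
    g: float = 25.0
    c0: float = 0.1
    open_subunit_min: int = 3
    nc: int = 5

    def __post_init__(self) -> None:
        if self.kfo < 0:
            raise ValueError("kfo must be >= 0")
        if self.kb <= 0:
            raise ValueError("kb must be > 0")
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")
        if not 1 <= self.open_subunit_min <= 4:
            raise ValueError("open_subunit_min must be in 1..4")
        if self.nc < 1:
            raise ValueError("nc must be >= 1")

    def with_(self, **kwargs) -> "RateParams":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)


class ClusterState:
    """The ±1 conformation of every subunit in a cluster.

    Stored as an int8 array of length ``4 * n_channels``; subunit ``s`` of
    channel ``c`` lives at flat index ``4*c + s`` with ``s`` in ring order
    0..3.
    """

    __slots__ = ("values",)

    def __init__(self, values: Iterable[int] | np.ndarray):
        arr = np.asarray(values, dtype=np.int8).copy()
        if arr.ndim != 1 or arr.size % 4 != 0:
            raise ValueError("state length must be a multiple of 4")
        if not np.all(np.abs(arr) == 1):
            raise ValueError("subunit states must be -1 or +1")
        self.values = arr

    @classmethod
    def all_closed(cls, n_channels: int) -> "ClusterState":
        return cls(np.full(4 * n_channels, -1, dtype=np.int8))

    @property
    def n_channels(self) -> int:
        return self.values.size // 4

    def __getitem__(self, address: tuple[int, int]) -> int:
        c, s = address
        return int(self.values[4 * c + s])

    def flipped(self, channel: int, subunit: int) -> "ClusterState":
        out = ClusterState(self.values)
        out.values[4 * channel + subunit] *= -1
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, ClusterState) and np.array_equal(self.values, other.values)

    def __repr__(self) -> str:
        return f"ClusterState({self.values.tolist()})"


def local_calcium(n_open: int, params: RateParams) -> float:
    """Dyadic Ca concentration (uM) with ``n_open`` conducting channels.

    Rapid-diffusion approximation: Ca released by open channels equilibrates
    across the dyad instantly on the gating timescale, so the concentration
    seen by every subunit is ``c0 + g * n_open``.
    """
    if n_open < 0:
        raise ValueError("n_open must be >= 0")
    return params.c0 + params.g * n_open


def coupling_factor(
    address: tuple[int, int],
    state: ClusterState,
    graph: CouplingGraph,
    params: RateParams,
) -> float:
    """Neighbor-coupling bias gamma for one subunit.

    gamma = exp(delta * (s_{i-1} + s_{i+1}) + sigma * sum_b w_b s_b) over the
    two ring neighbors and any surviving inter-channel contacts b.
    """
    c, s = address
    if not (0 <= c < graph.n_channels and 0 <= s < 4):
        raise KeyError(f"no subunit {address}")
    ring = sum(state[c, s2] for s2 in RING_NEIGHBORS[s])
    inter = sum(w * state[c2, s2] for c2, s2, w in graph.inter_contacts(c, s))
    return float(np.exp(params.delta * ring + params.sigma * inter))


def channel_open_flags(state: ClusterState, params: RateParams) -> tuple[np.ndarray, int]:
    """Conducting flag per channel and the conducting-channel count.

    A channel conducts when at least ``open_subunit_min`` of its four
    subunits are open; the rule counts subunits only, so it is invariant
    under rotation of the ring labels.
    """
    per_channel = (state.values.reshape(-1, 4) == 1).sum(axis=1)
    flags = per_channel >= params.open_subunit_min
    return flags, int(flags.sum())


def transition_rate(
    address: tuple[int, int],
    state: ClusterState,
    graph: CouplingGraph,
    params: RateParams,
) -> float:
    """Flip rate (per ms) of one subunit in the current cluster state.

    Closed subunits open at ``kfo * [Ca] * gamma``; open subunits close at
    ``kb / gamma``.  [Ca] is the dyadic concentration implied by the current
    global count of conducting channels (the transitioning subunit's own
    channel included — Ca is uniform within the dyad).
    """
    gamma = coupling_factor(address, state, graph, params)
    if state[address[0], address[1]] == -1:
        _, n_open = channel_open_flags(state, params)
        return params.kfo * local_calcium(n_open, params) * gamma
    return params.kb / gamma
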