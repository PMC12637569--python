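"""Exact master-equation machinery for small clusters.

Brute-force enumeration of the full state space (``2**(4M)`` configurations
for ``M`` channels, capped at ``M <= 4``), the exact generator of the
continuous-time Markov chain including the dyadic Ca feedback, its
stationary distribution, and linear-solve mean first-passage times.  These
serve as ground truth for the Gillespie engine: the simulated waiting-time
mean must converge to :func:`mfpt_exact` as the number of runs grows.

With the Ca feedback switched off (``g = 0``) the chain is reversible and
the stationary law is the Boltzmann distribution of the Ising-like energy
stated in :mod:`ryrspark.model`; :func:`boltzmann_distribution` provides
that closed form for detailed-balance checks.  With ``g > 0`` the chain is
irreversible, but the generator-based routines make no reversibility
assumption and remain exact.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CouplingGraph
from .model import RateParams

__all__ = [
    "MAX_CHANNELS",
    "StateSpace",
    "generator_matrix",
    "stationary_distribution",
    "boltzmann_distribution",
    "mfpt_exact",
]

MAX_CHANNELS = 4   # 2**16 states; sparse solves stay immediate


class StateSpace:
    """Bijective enumeration of all subunit configurations of a small cluster.

    State ``k`` (``0 <= k < 2**n_subunits``) has subunit ``i`` open iff bit
    ``i`` of ``k`` is set; index 0 is the all-closed configuration.
    """

    def __init__(self, graph: CouplingGraph):
        if graph.n_channels > MAX_CHANNELS:
            raise ValueError(
                f"state space of {graph.n_channels} channels "
                f"(2**{graph.n_subunits} states) exceeds the M<={MAX_CHANNELS} oracle cap"
            )
        self.graph = graph
        self.n_subunits = graph.n_subunits
        self.n_states = 1 << self.n_subunits

    def spins(self) -> np.ndarray:
        """All states as a (n_states, n_subunits) array of ±1."""
        k = np.arange(self.n_states, dtype=np.int64)
        bits = (k[:, None] >> np.arange(self.n_subunits)) & 1
        return (2 * bits - 1).astype(np.int8)

    def index_of(self, spins: np.ndarray) -> int:
        """Flat index of a single ±1 configuration."""
        bits = (np.asarray(spins) == 1).astype(np.int64)
        return int(bits @ (1 << np.arange(self.n_subunits, dtype=np.int64)))

    def n_open(self, params: RateParams) -> np.ndarray:
        """Conducting-channel count of every state."""
        open_bits = (self.spins() == 1).reshape(self.n_states, -1, 4).sum(axis=2)
        return (open_bits >= params.open_subunit_min).sum(axis=1)


def _coefficient_matrix(graph: CouplingGraph, params: RateParams) -> np.ndarray:
    """Symmetric exponent coefficients C with gamma_i = exp(sum_j C_ij s_j)."""
    n = graph.n_subunits
    nbr, coeff, deg = graph.neighbor_arrays(params.sigma, params.delta)
    C = np.zeros((n, n))
    for i in range(n):
        for k in range(deg[i]):
            C[i, nbr[i, k]] += coeff[i, k]
    return C


def generator_matrix(graph: CouplingGraph, params: RateParams) -> sp.csr_matrix:
    """Exact transition-rate matrix Q over the full state space.

    Off-diagonal ``Q[k, k']`` is the single-subunit flip rate from state
    ``k`` to ``k'`` (Ca evaluated from the conducting-channel count of the
    source state ``k``); diagonal entries make rows sum to zero.
    """
    space = StateSpace(graph)
    S = space.spins().astype(np.float64)                 # (n_states, n_sub)
    C = _coefficient_matrix(graph, params)
    gamma = np.exp(S @ C)                                # gamma_i per state
    ca = params.c0 + params.g * space.n_open(params)     # source-state Ca
    closed = S < 0
    rates = np.where(closed, params.kfo * ca[:, None] * gamma, params.kb / gamma)

    k = np.arange(space.n_states, dtype=np.int64)
    rows = np.repeat(k, space.n_subunits)
    cols = (k[:, None] ^ (1 << np.arange(space.n_subunits, dtype=np.int64))).ravel()
    Q = sp.coo_matrix(
        (rates.ravel(), (rows, cols)), shape=(space.n_states, space.n_states)
    ).tocsr()
    Q.setdiag(-np.asarray(Q.sum(axis=1)).ravel())
    return Q


def stationary_distribution(graph: CouplingGraph, params: RateParams) -> np.ndarray:
    """Stationary probability vector of the exact chain.

    Solves ``pi Q = 0`` with normalization by replacing one balance equation;
    requires an irreducible chain (``kfo * c0 > 0``).
    """
    if params.kfo * params.c0 <= 0:
        raise ValueError("chain is reducible: kfo*c0 must be > 0")
    if graph.n_channels > 3:
        raise ValueError(
            "stationary_distribution supports up to 3 channels; "
            "for g=0 use boltzmann_distribution"
        )
    Q = generator_matrix(graph, params)
    n = Q.shape[0]
    A = Q.T.toarray()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def boltzmann_distribution(graph: CouplingGraph, params: RateParams) -> np.ndarray:
    """Closed-form stationary law in the fixed-Ca (g = 0) limit.

    Weights ``exp(delta * sum_ring s s' + sigma * sum_inter w s s' + h * sum s)``
    with field ``h = 0.5 * ln(kfo * c0 / kb)``; normalized over the state
    space.
    """
    if params.kfo * params.c0 <= 0:
        raise ValueError("field h undefined: kfo*c0 must be > 0")
    space = StateSpace(graph)
    S = space.spins().astype(np.float64)
    C = _coefficient_matrix(graph, params)
    h = 0.5 * np.log(params.kfo * params.c0 / params.kb)
    # sum over edges = 1/2 sum_ij C_ij s_i s_j
    energy = 0.5 * np.einsum("ki,ij,kj->k", S, C, S) + h * S.sum(axis=1)
    w = np.exp(energy - energy.max())
    return w / w.sum()


def mfpt_exact(graph: CouplingGraph, params: RateParams, nc: int | None = None) -> float:
    """Exact mean first-passage time (ms) from all-closed to a spark.

    The absorbing set is every state with at least ``nc`` conducting
    channels (default ``params.nc``); the expected hitting times of the
    transient states solve ``Q_tt tau = -1``.
    """
    nc = params.nc if nc is None else nc
    space = StateSpace(graph)
    absorbing = space.n_open(params) >= nc
    if absorbing[0]:
        return 0.0
    if not absorbing.any():
        raise ValueError(f"no state reaches nc={nc} conducting channels")
    Q = generator_matrix(graph, params)
    transient = ~absorbing
    Qtt = Q[transient][:, transient]
    b = -np.ones(int(transient.sum()))
    if Qtt.shape[0] <= 4096:
        tau = np.linalg.solve(Qtt.toarray(), b)
    else:
        # direct LU fills in badly on the hypercube state graph; the
        # Jacobi-preconditioned Krylov solve is immediate and checked
        Qtt = Qtt.tocsr()
        precond = sp.diags(1.0 / Qtt.diagonal())
        tau, info = spla.bicgstab(Qtt, b, M=precond, rtol=1e-12, atol=0.0, maxiter=50_000)
        resid = np.linalg.norm(Qtt @ tau - b) / np.linalg.norm(b)
        if info != 0 or resid > 1e-6:
            raise RuntimeError(f"hitting-time solve did not converge (info={info}, resid={resid:.2e})")
    # all-closed is state 0, first among transient states
    return float(tau[0])
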