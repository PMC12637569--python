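"""Cluster geometry: channel lattices and subunit-level coupling graphs.

RyR2 channels occupy sites of a 2-D square lattice (one channel per ~30 nm
square footprint). Each channel is a tetramer whose four subunits sit at the
corners of its footprint, indexed in ring order::

    0 (NW) -- 1 (NE)
      |          |
    3 (SW) -- 2 (SE)

Within a channel the four subunits form a fixed periodic ring (0-1-2-3-0);
between laterally adjacent channels, corner subunits form physical contacts
whose pattern depends on the cluster architecture:

* ``adjoining`` — side-by-side contact: every pair of adjacent channels is
  joined by the two facing corner subunits on the shared edge, so an interior
  subunit carries two inter-channel contacts (one horizontal, one vertical).
* ``oblique`` — staggered contact: each adjacent channel pair is joined by a
  single diagonally facing corner pair, assigned so that no subunit carries
  more than one inter-channel contact (the 0-2 / 1-3 checkerboard pattern).

Inter-channel edges carry a relative weight (default 1.0) multiplied by the
global coupling strength ``sigma`` of :class:`~ryrspark.model.RateParams`
when rates are evaluated, so per-edge heterogeneity remains expressible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChannelLattice",
    "CouplingGraph",
    "InterEdge",
    "build_adjoining",
    "build_oblique",
    "dilute_bonds",
    "grow_preferential",
    "lattice_to_graph",
    "full_lattice",
]

#: subunit ring order and corner placement: 0=NW, 1=NE, 2=SE, 3=SW
RING_NEIGHBORS = ((3, 1), (0, 2), (1, 3), (2, 0))

# For a channel and its neighbor one step in direction d, the pairs of corner
# subunits that touch across the interface.  Directions as (dx, dy) with x the
# column (nx) and y the row (ny), y increasing southward.
_ADJOIN_CONTACTS = {
    (1, 0): ((1, 0), (2, 3)),   # east: my NE-its NW, my SE-its SW
    (0, 1): ((3, 0), (2, 1)),   # south: my SW-its NW, my SE-its NE
}
# Oblique: one diagonal contact per interface, chosen so each of the four
# subunits serves exactly one of the four directions (inter-degree <= 1).
_OBLIQUE_CONTACTS = {
    (1, 0): ((1, 3),),          # east: my NE-its SW
    (0, 1): ((2, 0),),          # south: my SE-its NW
}

_TOPOLOGIES = {"adjoining": _ADJOIN_CONTACTS, "oblique": _OBLIQUE_CONTACTS}


@dataclass(frozen=True)
class ChannelLattice:
    """Occupied channel positions on a ``rows`` x ``cols`` grid.

    Sites are ``(nx, ny)`` with ``nx`` the 0-based column and ``ny`` the
    0-based row; two channels are adjacent when their sites differ by one
    step in exactly one coordinate (von Neumann 4-neighborhood).
    """

    rows: int
    cols: int
    sites: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("lattice dimensions must be positive")
        seen = set()
        for nx, ny in self.sites:
            if not (0 <= nx < self.cols and 0 <= ny < self.rows):
                raise ValueError(f"site ({nx}, {ny}) outside {self.rows}x{self.cols} grid")
            if (nx, ny) in seen:
                raise ValueError(f"duplicate site ({nx}, {ny})")
            seen.add((nx, ny))

    @property
    def n_channels(self) -> int:
        return len(self.sites)

    def adjacent_pairs(self) -> list[tuple[int, int, tuple[int, int]]]:
        """Occupied adjacent site pairs as (channel_index, channel_index, direction).

        Direction is the (dx, dy) step from the first channel to the second;
        only east and south steps are enumerated so each unordered pair
        appears once.
        """
        index = {site: c for c, site in enumerate(self.sites)}
        pairs = []
        for c, (nx, ny) in enumerate(self.sites):
            for dx, dy in ((1, 0), (0, 1)):
                other = index.get((nx + dx, ny + dy))
                if other is not None:
                    pairs.append((c, other, (dx, dy)))
        return pairs


InterEdge = tuple[tuple[int, int], tuple[int, int], float]
"""One inter-channel contact: ((channel, subunit), (channel, subunit), weight)."""


@dataclass(frozen=True)
class CouplingGraph:
    """Subunit-level interaction structure of a cluster.

    The intra-tetramer ring (subunit i with i±1 mod 4) is implicit and
    structural — it exists for every channel and is never modified.
    ``inter_edges`` lists inter-channel contacts once per unordered pair.
    """

    lattice: ChannelLattice
    topology: str
    inter_edges: tuple[InterEdge, ...] = ()
    sigma: float | None = None   # metadata: sigma recorded at generation time
    seed: int | None = None      # metadata: seed used to generate, if random

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        n = self.lattice.n_channels
        seen = set()
        for (c1, s1), (c2, s2), w in self.inter_edges:
            for c, s in ((c1, s1), (c2, s2)):
                if not (0 <= c < n and 0 <= s < 4):
                    raise ValueError(f"edge endpoint ({c}, {s}) out of range")
            if (c1, s1) == (c2, s2):
                raise ValueError("self-edge not allowed")
            key = frozenset({(c1, s1), (c2, s2)})
            if key in seen:
                raise ValueError(f"duplicate inter edge {key}")
            seen.add(key)
            if w <= 0:
                raise ValueError("edge weight must be positive")

    @property
    def n_channels(self) -> int:
        return self.lattice.n_channels

    @property
    def n_subunits(self) -> int:
        return 4 * self.lattice.n_channels

    def inter_contacts(self, channel: int, subunit: int) -> list[tuple[int, int, float]]:
        """Surviving inter-channel contacts of one subunit as (channel, subunit, weight)."""
        if not (0 <= channel < self.n_channels and 0 <= subunit < 4):
            raise KeyError(f"no subunit ({channel}, {subunit})")
        out = []
        for (c1, s1), (c2, s2), w in self.inter_edges:
            if (c1, s1) == (channel, subunit):
                out.append((c2, s2, w))
            elif (c2, s2) == (channel, subunit):
                out.append((c1, s1, w))
        return out

    def inter_degrees(self) -> np.ndarray:
        """Inter-channel contact count per subunit, shape (n_subunits,)."""
        deg = np.zeros(self.n_subunits, dtype=np.int64)
        for (c1, s1), (c2, s2), _ in self.inter_edges:
            deg[4 * c1 + s1] += 1
            deg[4 * c2 + s2] += 1
        return deg

    def neighbor_arrays(self, sigma: float, delta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened adjacency for the simulation kernel.

        Returns ``(nbr, coeff, deg)`` where for subunit ``i`` the neighbors
        are ``nbr[i, :deg[i]]`` (global subunit indices, ring first) and
        ``coeff[i, k]`` is the full exponent coefficient: ``delta`` for ring
        edges and ``sigma * w`` for inter edges (each coupling parameter is
        its own dimensionless energy).  The coefficient matrix is symmetric
        by construction.
        """
        n = self.n_subunits
        nbr = np.full((n, 6), -1, dtype=np.int64)
        coeff = np.zeros((n, 6), dtype=np.float64)
        deg = np.zeros(n, dtype=np.int64)
        for c in range(self.n_channels):
            for s in range(4):
                i = 4 * c + s
                for s2 in RING_NEIGHBORS[s]:
                    nbr[i, deg[i]] = 4 * c + s2
                    coeff[i, deg[i]] = delta
                    deg[i] += 1
        for (c1, s1), (c2, s2), w in self.inter_edges:
            i, j = 4 * c1 + s1, 4 * c2 + s2
            for a, b in ((i, j), (j, i)):
                nbr[a, deg[a]] = b
                coeff[a, deg[a]] = sigma * w
                deg[a] += 1
        return nbr, coeff, deg

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rows": self.lattice.rows,
            "cols": self.lattice.cols,
            "topology": self.topology,
            "sigma": self.sigma,
            "channels": [list(site) for site in self.lattice.sites],
            "inter_edges": [[[c1, s1], [c2, s2], w] for (c1, s1), (c2, s2), w in self.inter_edges],
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, doc: dict) -> "CouplingGraph":
        lattice = ChannelLattice(doc["rows"], doc["cols"], tuple(tuple(s) for s in doc["channels"]))
        edges = tuple(
            ((int(e[0][0]), int(e[0][1])), (int(e[1][0]), int(e[1][1])), float(e[2]))
            for e in doc["inter_edges"]
        )
        return cls(lattice, doc["topology"], edges, sigma=doc.get("sigma"), seed=doc.get("seed"))

    @classmethod
    def from_json(cls, text: str) -> "CouplingGraph":
        return cls.from_dict(json.loads(text))


def full_lattice(rows: int, cols: int) -> ChannelLattice:
    """Fully occupied rows x cols lattice, row-major site order."""
    sites = tuple((nx, ny) for ny in range(rows) for nx in range(cols))
    return ChannelLattice(rows, cols, sites)


def lattice_to_graph(
    lattice: ChannelLattice,
    topology: str,
    weight: float = 1.0,
    sigma: float | None = None,
    seed: int | None = None,
) -> CouplingGraph:
    """Couple every pair of occupied, laterally adjacent channels.

    ``topology`` selects the contact rule (``"adjoining"``: two facing corner
    subunits per interface; ``"oblique"``: one diagonal corner pair).
    Isolated channels receive no inter edges.  ``weight`` is the relative
    per-edge weight multiplied by the global sigma at rate evaluation.
    """
    try:
        contacts = _TOPOLOGIES[topology]
    except KeyError:
        raise ValueError(f"unknown topology {topology!r}") from None
    edges: list[InterEdge] = []
    for c1, c2, direction in lattice.adjacent_pairs():
        for s1, s2 in contacts[direction]:
            edges.append(((c1, s1), (c2, s2), weight))
    return CouplingGraph(lattice, topology, tuple(edges), sigma=sigma, seed=seed)


def build_adjoining(rows: int, cols: int, weight: float = 1.0) -> CouplingGraph:
    """Full rows x cols cluster in the adjoining (side-by-side) architecture."""
    return lattice_to_graph(full_lattice(rows, cols), "adjoining", weight)


def build_oblique(rows: int, cols: int, weight: float = 1.0) -> CouplingGraph:
    """Full rows x cols cluster in the oblique (checkerboard) architecture."""
    return lattice_to_graph(full_lattice(rows, cols), "oblique", weight)


def dilute_bonds(
    graph: CouplingGraph,
    p: float,
    seed: int | np.random.Generator | None = None,
) -> CouplingGraph:
    """Retain each inter-channel bond independently with probability ``p``.

    Models cluster fragmentation / fraying: ``p=1`` keeps the cluster fully
    connected, ``p=0`` dissociates all inter-channel contacts.  Intra-tetramer
    rings are structural and never broken.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"connection probability p={p} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = rng.random(len(graph.inter_edges)) < p
    edges = tuple(e for e, k in zip(graph.inter_edges, keep) if k)
    recorded = seed if isinstance(seed, (int, np.integer)) else None
    return replace(graph, inter_edges=edges, seed=recorded)


def grow_preferential(
    n_channels: int,
    rows: int,
    cols: int,
    alpha: float,
    seed: int | np.random.Generator | None = None,
    mode: str = "power",
) -> ChannelLattice:
    """Place channels sequentially with neighbor-count-biased site selection.

    At each step an empty site is drawn with probability proportional to
    ``1 + ne**alpha`` (``mode="power"``, with the convention ``0**0 := 1``) or
    ``1 + ne*alpha`` (``mode="product"``), where ``ne`` is the number of
    occupied von Neumann neighbors.  ``alpha=0`` gives uniform random
    placement in either mode; large ``alpha`` grows compact clusters.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_channels > rows * cols:
        raise ValueError(f"cannot place {n_channels} channels on a {rows}x{cols} lattice")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if mode not in ("power", "product"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    occupied = np.zeros((rows, cols), dtype=bool)
    ne = np.zeros((rows, cols), dtype=np.int64)   # occupied 4-neighbor counts
    sites: list[tuple[int, int]] = []
    for _ in range(n_channels):
        if mode == "power":
            # 0**0 := 1 so alpha=0 is exactly uniform
            w = 1.0 + np.where(ne == 0, float(alpha == 0.0), ne.astype(float) ** alpha)
        else:
            w = 1.0 + ne * alpha
        w[occupied] = 0.0
        flat = w.ravel()
        choice = rng.choice(flat.size, p=flat / flat.sum())
        ny, nx = divmod(int(choice), cols)
        occupied[ny, nx] = True
        sites.append((nx, ny))
        if ny > 0:
            ne[ny - 1, nx] += 1
        if ny < rows - 1:
            ne[ny + 1, nx] += 1
        if nx > 0:
            ne[ny, nx - 1] += 1
        if nx < cols - 1:
            ne[ny, nx + 1] += 1
    return ChannelLattice(rows, cols, tuple(sites))
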