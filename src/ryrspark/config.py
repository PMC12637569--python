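"""Flat key=value run configuration with validated defaults.

A run is fully specified by the kinetic parameters, a cluster geometry
(either an explicit ``rows`` x ``cols`` lattice, or ``n_channels`` grown
with clustering parameter ``alpha`` on a square ``grid``), the optional
bond-survival probability ``p``, and the simulation controls (t_max,
n_runs, master_seed, max_events).  Unknown keys are rejected; all value
constraints of the underlying types are re-checked at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .ensembles import GraphSpec
from .model import RateParams

__all__ = ["RunConfig", "parse_config", "format_config"]

_INT = ("open_subunit_min", "nc", "rows", "cols", "n_channels", "grid",
        "n_runs", "n_sets", "master_seed", "max_events")
_FLOAT = ("kfo", "kb", "delta", "sigma", "g", "c0", "p", "alpha", "weight", "t_max")
_STR = ("topology", "growth_mode")
_OPTIONAL = ("n_channels", "grid", "alpha", "p", "master_seed")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration (defaults are the standard kinetics)."""

    kfo: float = 0.005
    kb: float = 0.3
    delta: float = 0.5
    sigma: float = 0.5
    g: float = 25.0
    c0: float = 0.1
    open_subunit_min: int = 3
    nc: int = 5
    topology: str = "oblique"
    rows: int | None = None
    cols: int | None = None
    n_channels: int | None = None
    grid: int | None = None
    alpha: float | None = None
    p: float | None = None
    weight: float = 1.0
    growth_mode: str = "power"
    t_max: float = 1e8
    max_events: int = 10**9
    n_runs: int = 50
    n_sets: int = 5
    master_seed: int | None = None

    def __post_init__(self):
        explicit = self.rows is not None or self.cols is not None
        grown = self.n_channels is not None or self.alpha is not None or self.grid is not None
        if explicit and grown:
            raise ValueError(
                "ambiguous geometry: give rows/cols OR n_channels+grid+alpha, not both"
            )
        if grown and (self.n_channels is None or self.grid is None or self.alpha is None):
            raise ValueError("grown geometry requires n_channels, grid and alpha together")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.n_runs < 1 or self.n_sets < 1:
            raise ValueError("n_runs and n_sets must be >= 1")
        self.rate_params()   # re-validate kinetic constraints
        self.graph_spec()    # re-validate geometry constraints

    def rate_params(self) -> RateParams:
        return RateParams(kfo=self.kfo, kb=self.kb, delta=self.delta, sigma=self.sigma,
                          g=self.g, c0=self.c0, open_subunit_min=self.open_subunit_min,
                          nc=self.nc)

    def graph_spec(self) -> GraphSpec:
        if self.n_channels is not None:
            return GraphSpec(topology=self.topology, rows=self.grid, cols=self.grid,
                             n_channels=self.n_channels, alpha=self.alpha, p=self.p,
                             weight=self.weight, growth_mode=self.growth_mode)
        rows = 10 if self.rows is None else self.rows
        cols = 10 if self.cols is None else self.cols
        return GraphSpec(topology=self.topology, rows=rows, cols=cols, p=self.p,
                         weight=self.weight, growth_mode=self.growth_mode)


def _coerce(key: str, raw: str):
    if raw.lower() in ("none", "null") and key in _OPTIONAL:
        return None
    if key in _INT:
        return int(raw)
    if key in _FLOAT:
        return float(raw)
    return raw


def parse_config(text: str, overrides: dict | None = None) -> RunConfig:
    """Parse a flat ``key = value`` document into a validated RunConfig.

    Blank lines and ``#`` comments are ignored.  ``overrides`` (e.g. from
    command-line flags) take precedence over the file, which takes
    precedence over defaults.  Unknown keys raise.
    """
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
        if key in values:
            raise ValueError(f"line {lineno}: duplicate key {key!r}")
        values[key] = _coerce(key, raw)
    for key, val in (overrides or {}).items():
        if key not in known:
            raise ValueError(f"unknown override {key!r}")
        if val is not None:
            values[key] = val
    return RunConfig(**values)


def format_config(cfg: RunConfig) -> str:
    """Render the fully resolved configuration as a key = value document."""
    return "\n".join(f"{f.name} = {getattr(cfg, f.name)}" for f in fields(RunConfig))
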