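"""Propagule-size simulation of whole-community vertical transmission.

A dispersing alate carries N protist cells sampled (with replacement) from
the source community of its nymph or worker stage.  Transmission of the
whole community succeeds when every species group is represented at least
once among the N cells.  This module implements

* the Monte-Carlo experiment: N i.i.d. categorical draws from the source
  proportions p (one multinomial draw), repeated for I hypothetical alates,
  with transmission efficiency E(N) the fraction of alates holding every
  group;
* an exact analytic counterpart by inclusion–exclusion,

      P(all present) = sum over subsets S of groups of
                       (-1)^|S| (1 - sum_{i in S} p_i)^N,

  used both as a deterministic twin of the simulation and as its oracle;
* the minimum-propagule search: the smallest N on the grid whose
  efficiency reaches a threshold (1.0 by default, i.e. every simulated
  alate received the full community).

The Monte-Carlo minimum at threshold 1.0 is a property of the grid, the
iteration count I and the seed; the analytic minimum at threshold
1 - 1/(2I) is reported alongside as a seed-free reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityComposition

__all__ = [
    "SimulationConfig",
    "EfficiencyCurve",
    "MinCellsResult",
    "DEFAULT_GRID",
    "sample_transmission",
    "transmission_efficiency",
    "analytic_full_transmission_prob",
    "efficiency_curve",
    "minimum_cells_for_full_transmission",
    "analytic_reference_threshold",
    "refine_minimum_cells",
]

#: propagule sizes examined by default: 500..10000 cells in steps of 500
DEFAULT_GRID: tuple[int, ...] = tuple(range(500, 10001, 500))

MAX_ANALYTIC_GROUPS = 25


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one transmission-efficiency experiment."""

    n_grid: tuple[int, ...] = DEFAULT_GRID
    iterations: int = 5000
    seed: int = 0
    efficiency_threshold: float = 1.0
    mode: str = "monte_carlo"
    require_all_panel: bool = True

    def __post_init__(self) -> None:
        grid = tuple(int(n) for n in self.n_grid)
        if not grid or any(n <= 0 for n in grid):
            raise ValueError("n_grid must contain positive integers")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("n_grid must be strictly increasing")
        object.__setattr__(self, "n_grid", grid)
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.efficiency_threshold <= 1:
            raise ValueError("efficiency_threshold must be in (0, 1]")
        if self.mode not in ("monte_carlo", "analytic"):
            raise ValueError(f"mode must be 'monte_carlo' or 'analytic', got {self.mode!r}")


@dataclass
class EfficiencyCurve:
    """Transmission efficiency E(N) over a propagule-size grid."""

    composition_source: str
    n_values: tuple[int, ...]
    efficiency: np.ndarray
    iterations: int
    seed: int | None
    mode: str

    def __post_init__(self) -> None:
        self.n_values = tuple(int(n) for n in self.n_values)
        e = np.asarray(self.efficiency, dtype=float)
        if len(e) != len(self.n_values):
            raise ValueError("efficiency and n_values lengths differ")
        if np.any((e < -1e-12) | (e > 1 + 1e-12)):
            raise ValueError("efficiencies must lie in [0, 1]")
        self.efficiency = np.clip(e, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_cells": self.n_values, "efficiency": self.efficiency})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, mode: str = "unknown") -> "EfficiencyCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(
            composition_source=str(path),
            n_values=tuple(int(n) for n in df["n_cells"]),
            efficiency=df["efficiency"].to_numpy(dtype=float),
            iterations=0,
            seed=None,
            mode=mode,
        )


@dataclass(frozen=True)
class MinCellsResult:
    """Smallest grid propagule size reaching the efficiency threshold."""

    min_cells: int | None
    threshold: float
    mode: str
    composition_source: str = ""


def _positive_mask(comp: CommunityComposition) -> np.ndarray:
    return comp.proportions > 0


def sample_transmission(
    comp: CommunityComposition,
    n_cells: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one hypothetical alate: which groups are present among n_cells?

    n_cells cells are sampled i.i.d. from the categorical distribution p
    (implemented as a single multinomial draw — the two are the same
    distribution).  Returns a boolean presence vector in panel order;
    groups with p_i = 0 are never present.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    counts = rng.multinomial(int(n_cells), comp.proportions)
    return counts > 0


def transmission_efficiency(
    comp: CommunityComposition,
    n_cells: int,
    iterations: int = 5000,
    seed: int | np.random.Generator = 0,
    require_all_panel: bool = True,
) -> float:
    """Monte-Carlo transmission efficiency at one propagule size.

    The fraction of ``iterations`` hypothetical alates whose n_cells
    sampled cells include every species group.  With the strict default,
    "every group" means the whole panel, so a composition containing a
    zero-proportion group yields 0.0 — surfacing a data problem rather
    than silently shrinking the success criterion.  Pass
    ``require_all_panel=False`` to restrict the criterion to groups with
    p_i > 0.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = comp.proportions
    if require_all_panel and np.any(p == 0):
        return 0.0
    counts = rng.multinomial(int(n_cells), p, size=int(iterations))
    present = counts[:, p > 0] > 0
    return float(present.all(axis=1).mean())


def _inclusion_exclusion_terms(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subset sums and signs for inclusion–exclusion over the groups of p."""
    sums = np.zeros(1)
    signs = np.ones(1)
    for pi in p:
        sums = np.concatenate([sums, sums + pi])
        signs = np.concatenate([signs, -signs])
    return sums, signs


def analytic_full_transmission_prob(
    comp: CommunityComposition,
    n_cells: int | Sequence[int],
    require_all_panel: bool = True,
) -> float | np.ndarray:
    """Exact probability that N i.i.d. draws from p contain every group.

    Computed by inclusion–exclusion over the 2^k subsets of the k groups
    with positive proportion; k is capped at 25 (use the Monte-Carlo mode
    beyond that).  Accepts a scalar or a sequence of N values; returns the
    matching scalar or array.
    """
    n_arr = np.atleast_1d(np.asarray(n_cells, dtype=np.int64))
    if np.any(n_arr < 0):
        raise ValueError("n_cells must be >= 0")
    p = comp.proportions
    has_zero = bool(np.any(p == 0))
    p_pos = p[p > 0]
    if len(p_pos) > MAX_ANALYTIC_GROUPS:
        raise ValueError(
            f"{len(p_pos)} groups exceed the {MAX_ANALYTIC_GROUPS}-group limit of "
            "the 2^k inclusion-exclusion enumeration; use mode='monte_carlo'"
        )
    if require_all_panel and has_zero:
        out = np.zeros(len(n_arr))
    else:
        sums, signs = _inclusion_exclusion_terms(p_pos)
        base = np.clip(1.0 - sums, 0.0, 1.0)
        # P(n) = sum_S (-1)^|S| (1 - p_S)^n ; rows = n values
        out = np.clip((signs * base[None, :] ** n_arr[:, None]).sum(axis=1), 0.0, 1.0)
        # n draws cannot cover more than n groups: exact zero, not float residue
        out[n_arr < len(p_pos)] = 0.0
    return float(out[0]) if np.isscalar(n_cells) or np.ndim(n_cells) == 0 else out


def efficiency_curve(comp: CommunityComposition, config: SimulationConfig) -> EfficiencyCurve:
    """Compute E(N) for every N on the grid in the configured mode.

    Monte-Carlo runs derive one independent substream per grid point from
    the master seed, so the curve does not depend on evaluation order or
    batching; analytic mode is deterministic.
    """
    if config.mode == "analytic":
        eff = analytic_full_transmission_prob(
            comp, list(config.n_grid), require_all_panel=config.require_all_panel
        )
        seed: int | None = None
    else:
        children = np.random.SeedSequence(config.seed).spawn(len(config.n_grid))
        eff = np.array(
            [
                transmission_efficiency(
                    comp,
                    n,
                    iterations=config.iterations,
                    seed=np.random.default_rng(ss),
                    require_all_panel=config.require_all_panel,
                )
                for n, ss in zip(config.n_grid, children)
            ]
        )
        seed = config.seed
    return EfficiencyCurve(
        composition_source=comp.source,
        n_values=config.n_grid,
        efficiency=np.asarray(eff, dtype=float),
        iterations=config.iterations if config.mode == "monte_carlo" else 0,
        seed=seed,
        mode=config.mode,
    )


def minimum_cells_for_full_transmission(
    curve: EfficiencyCurve,
    threshold: float = 1.0,
) -> MinCellsResult:
    """Smallest grid N with E(N) >= threshold, or None if never reached.

    With the default threshold 1.0 on a Monte-Carlo curve this is the
    smallest propagule size at which *all* simulated alates received the
    complete community — the quantity is therefore resolved only to grid
    resolution and depends on the iteration count and seed.
    """
    if len(curve.n_values) == 0:
        raise ValueError("curve is empty")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    hit = np.nonzero(curve.efficiency >= threshold - 1e-12)[0]
    min_cells = int(curve.n_values[hit[0]]) if len(hit) else None
    return MinCellsResult(
        min_cells=min_cells,
        threshold=threshold,
        mode=curve.mode,
        composition_source=curve.composition_source,
    )


def analytic_reference_threshold(iterations: int) -> float:
    """Seed-free stand-in for 'all I iterations succeed': 1 - 1/(2I)."""
    return 1.0 - 1.0 / (2 * iterations)


def refine_minimum_cells(
    comp: CommunityComposition,
    result: MinCellsResult,
    grid: Sequence[int],
    require_all_panel: bool = True,
) -> int | None:
    """Bisect below a grid-resolved analytic minimum to single-cell resolution.

    Only meaningful for analytic curves (P is exactly non-decreasing in N).
    Returns the smallest integer N with P(N) >= threshold, or None when
    the grid search itself found nothing.
    """
    if result.min_cells is None:
        return None
    grid = sorted(int(n) for n in grid)
    idx = grid.index(result.min_cells)
    lo = grid[idx - 1] + 1 if idx > 0 else 1
    hi = result.min_cells
    while lo < hi:
        mid = (lo + hi) // 2
        p = analytic_full_transmission_prob(comp, mid, require_all_panel=require_all_panel)
        if p >= result.threshold - 1e-12:
            hi = mid
        else:
            lo = mid + 1
    return lo
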