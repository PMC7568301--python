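"""Minimum free-energy path (MFEP) extraction on a gridded surface.

The path between two basins is built in two stages:

1. **Bottleneck-optimal search** — a Dijkstra-style scan over the
   8-connected sampled bins that minimizes the *maximum* free energy
   encountered en route (the bottleneck).  Among paths with equal
   bottleneck, ties break toward the lower running sum of free energy
   along the path, then toward lexicographic bin order.  The highest
   bin of the winning path is the saddle.
2. **Steepest-descent refinement** — from the bins flanking the saddle,
   the path is relaxed by repeatedly stepping to the lowest sampled
   8-neighbour until a local minimum is reached.  If a descent ends in
   a basin other than the requested one, the bottleneck path segment is
   kept for that side instead.

The barrier is ∆G‡ = G(saddle) − G(reactant) and the step free energy
is ∆G_reaction = G(product) − G(reactant).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wham import NEIGHBOR_OFFSETS, Basin, FreeEnergySurface

__all__ = ["ReactionPath", "extract_mfep", "PathError"]


class PathError(RuntimeError):
    """The two basins are not connected through sampled bins."""


@dataclass
class ReactionPath:
    """Ordered grid path from reactant to product through the saddle."""

    bins: list[tuple[int, int]]
    coordinates: np.ndarray  # (n, 2) bin-center coordinates, Å
    free_energy: np.ndarray  # (n,) kcal/mol
    reactant_index: int
    saddle_index: int
    product_index: int
    barrier: float  # ∆G‡, kcal/mol
    reaction_free_energy: float  # ∆G_reaction, kcal/mol
    barrier_err: float = float("nan")
    reaction_free_energy_err: float = float("nan")

    @classmethod
    def from_values(
        cls,
        barrier: float,
        reaction_free_energy: float,
        barrier_err: float = float("nan"),
        reaction_free_energy_err: float = float("nan"),
    ) -> "ReactionPath":
        """A degenerate three-point path carrying stated energetics.

        Used when a step's ∆G‡ and ∆G_reaction come from a table rather
        than from a reconstructed surface (e.g. literature values fed
        into rate and mechanism summaries).
        """
        g = np.array([0.0, barrier, reaction_free_energy])
        coords = np.zeros((3, 2))
        return cls(
            bins=[(0, 0), (1, 0), (2, 0)], coordinates=coords, free_energy=g,
            reactant_index=0, saddle_index=1, product_index=2,
            barrier=barrier, reaction_free_energy=reaction_free_energy,
            barrier_err=barrier_err, reaction_free_energy_err=reaction_free_energy_err,
        )

    @property
    def saddle_coordinates(self) -> tuple[float, float]:
        return tuple(self.coordinates[self.saddle_index])

    def to_frame(self) -> pd.DataFrame:
        tags = [""] * len(self.bins)
        tags[self.reactant_index] = "reactant"
        tags[self.saddle_index] = "saddle"
        tags[self.product_index] = "product"
        return pd.DataFrame(
            {
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "G": self.free_energy,
                "role": tags,
            }
        )


@dataclass(order=True)
class _QueueItem:
    bottleneck: float
    path_sum: float
    tiebreak: tuple[int, int]
    node: tuple[int, int] = field(compare=False)


def _neighbors(node, sampled):
    nx, ny = sampled.shape
    i, j = node
    for di, dj in NEIGHBOR_OFFSETS:
        a, b = i + di, j + dj
        if 0 <= a < nx and 0 <= b < ny and sampled[a, b]:
            yield (a, b)


def bottleneck_path(
    g: np.ndarray,
    sampled: np.ndarray,
    start: tuple[int, int],
    goal: tuple[int, int],
) -> tuple[list[tuple[int, int]], float]:
    """Bottleneck-shortest path on the sampled 8-connected grid.

    Returns the path (list of bins, start → goal) and its bottleneck
    value max G.  Lexicographically documented tie-breaking: minimal
    bottleneck, then minimal path sum of G, then lowest bin order.
    """
    if not sampled[start] or not sampled[goal]:
        raise PathError(f"endpoint {start if not sampled[start] else goal} is not a sampled bin")
    best: dict[tuple[int, int], tuple[float, float]] = {
        start: (g[start], g[start])
    }
    parent: dict[tuple[int, int], tuple[int, int] | None] = {start: None}
    heap = [_QueueItem(g[start], g[start], start, start)]
    done: set[tuple[int, int]] = set()
    while heap:
        item = heapq.heappop(heap)
        node = item.node
        if node in done:
            continue
        done.add(node)
        if node == goal:
            break
        bneck, psum = best[node]
        for nb in _neighbors(node, sampled):
            if nb in done:
                continue
            cand = (max(bneck, g[nb]), psum + g[nb])
            if nb not in best or cand < best[nb]:
                best[nb] = cand
                parent[nb] = node
                heapq.heappush(heap, _QueueItem(cand[0], cand[1], nb, nb))
    if goal not in done:
        raise PathError(
            f"basins {start} and {goal} are not connected through sampled bins"
        )
    path = [goal]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()
    return path, best[goal][0]


def _steepest_descent(g, sampled, start):
    """Greedy descent to the nearest local minimum (lowest 8-neighbour)."""
    path = [start]
    node = start
    while True:
        nbs = list(_neighbors(node, sampled))
        if not nbs:
            return path
        down = min(nbs, key=lambda n: (g[n], n))
        if g[down] >= g[node]:
            return path
        path.append(down)
        node = down


def extract_mfep(
    fes: FreeEnergySurface,
    reactant: Basin | tuple[int, int],
    product: Basin | tuple[int, int],
) -> ReactionPath:
    """Extract the MFEP between two basins of a reconstructed surface."""
    r = (reactant.ix, reactant.iy) if isinstance(reactant, Basin) else tuple(reactant)
    p = (product.ix, product.iy) if isinstance(product, Basin) else tuple(product)
    g = fes.free_energy
    sampled = fes.sampled

    if r == p:
        coords = np.array([[fes.x_centers[r[0]], fes.y_centers[r[1]]]])
        val = float(g[r])
        return ReactionPath(
            bins=[r], coordinates=coords, free_energy=np.array([val]),
            reactant_index=0, saddle_index=0, product_index=0,
            barrier=0.0, reaction_free_energy=0.0,
        )

    bpath, _ = bottleneck_path(g, sampled, r, p)
    saddle_pos = int(np.argmax([g[b] for b in bpath]))
    saddle = bpath[saddle_pos]

    if saddle_pos == 0:
        left: list[tuple[int, int]] = []
    else:
        left = _steepest_descent(g, sampled, bpath[saddle_pos - 1])
        if left[-1] != r:
            left = bpath[:saddle_pos]  # descent strayed; keep bottleneck segment
        else:
            left = left[::-1]
    if saddle_pos == len(bpath) - 1:
        right: list[tuple[int, int]] = []
    else:
        right = _steepest_descent(g, sampled, bpath[saddle_pos + 1])
        if right[-1] != p:
            right = bpath[saddle_pos + 1:]

    bins = left + [saddle] + right
    energies = np.array([g[b] for b in bins])
    coords = np.array([[fes.x_centers[i], fes.y_centers[j]] for i, j in bins])
    saddle_index = len(left)
    barrier = float(g[saddle] - g[r])
    dg = float(g[p] - g[r])
    return ReactionPath(
        bins=bins,
        coordinates=coords,
        free_energy=energies,
        reactant_index=0,
        saddle_index=saddle_index,
        product_index=len(bins) - 1,
        barrier=barrier,
        reaction_free_energy=dg,
    )
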