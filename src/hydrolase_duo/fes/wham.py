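"""2D weighted-histogram analysis (WHAM) of umbrella-sampling windows.

Window samples are binned on a common 2D grid and the standard WHAM
self-consistent equations are iterated:

    P(b) ∝ Σ_i n_i(b)  /  Σ_i N_i · exp[(f_i − c_i(b)) / k_BT]
    f_i  = −k_BT · ln Σ_b P(b) · exp[−c_i(b) / k_BT]

where n_i(b) is window i's count in bin b, c_i(b) its bias energy at
the bin center, and f_i its free-energy shift.  Iteration stops when
the sup-norm change of the shifts drops below ``tol``.  The surface is
G(b) = −k_BT·ln P(b), shifted so the minimum over sampled bins is 0.

Bins with fewer than ``min_count`` total samples are masked and never
silently interpolated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..constants import kt
from .windows import UmbrellaWindow

__all__ = [
    "GridSpec",
    "FreeEnergySurface",
    "Basin",
    "estimate_fes",
    "locate_basins",
    "select_reaction_basins",
    "WhamConvergenceError",
]

#: Offsets of the 8-connected neighbourhood on the bin grid.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
)


def integrated_autocorr_time(series: np.ndarray, max_lag_fraction: float = 0.1) -> float:
    """Integrated autocorrelation time τ of a 1D series, in sample units.

    τ = ½ + Σ_k ρ_k, summed while the autocorrelation stays positive
    (initial-positive-sequence estimator), capped at a tenth of the
    series length.  For independent samples τ = ½, giving a
    statistical inefficiency g = 2τ = 1.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        return 0.5
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return 0.5
    tau = 0.5
    max_lag = max(1, int(max_lag_fraction * n))
    for lag in range(1, max_lag + 1):
        rho = float(np.dot(x[:-lag], x[lag:])) / (n * var)
        if rho <= 0:
            break
        tau += rho
    return tau


class WhamConvergenceError(RuntimeError):
    """WHAM iteration hit max_iter; carries the last sup-norm residual."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"WHAM did not converge in {max_iter} iterations (last |Δf|∞ = {residual:.3e} kcal/mol)"
        )


@dataclass(frozen=True)
class GridSpec:
    """Histogram grid: bin counts plus optional explicit ranges (Å)."""

    nx: int = 50
    ny: int = 50
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.nx}x{self.ny}")

    @classmethod
    def parse(cls, text: str) -> "GridSpec":
        """Parse a '50x50' style grid string."""
        nx, ny = (int(t) for t in text.lower().split("x"))
        return cls(nx=nx, ny=ny)

    def edges(self, windows: list[UmbrellaWindow]) -> tuple[np.ndarray, np.ndarray]:
        if self.x_range is not None:
            xr = self.x_range
        else:
            xr = (
                min(w.samples[:, 0].min() for w in windows),
                max(w.samples[:, 0].max() for w in windows),
            )
        if self.y_range is not None:
            yr = self.y_range
        else:
            yr = (
                min(w.samples[:, 1].min() for w in windows),
                max(w.samples[:, 1].max() for w in windows),
            )
        return np.linspace(xr[0], xr[1], self.nx + 1), np.linspace(yr[0], yr[1], self.ny + 1)


@dataclass
class FreeEnergySurface:
    """Gridded 2D free energy with sampled-bin mask and per-bin error."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny), kcal/mol; NaN where unsampled
    sampled: np.ndarray  # (nx, ny) bool
    stderr: np.ndarray  # (nx, ny), kcal/mol; NaN where unsampled
    temperature: float
    n_iterations: int = 0
    residual: float = 0.0
    connected: bool = True
    window_shifts: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: x_center, y_center, G, stderr, sampled."""
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame(
            {
                "x_center": xc.ravel(),
                "y_center": yc.ravel(),
                "G": self.free_energy.ravel(),
                "stderr": self.stderr.ravel(),
                "sampled": self.sampled.ravel().astype(int),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="nan")

    @classmethod
    def read(cls, path: str | Path, temperature: float = 303.15) -> "FreeEnergySurface":
        df = pd.read_csv(path, sep="\t")
        xc = np.unique(df["x_center"].to_numpy())
        yc = np.unique(df["y_center"].to_numpy())
        nx, ny = len(xc), len(yc)
        shape = (nx, ny)
        g = df["G"].to_numpy().reshape(shape)
        err = df["stderr"].to_numpy().reshape(shape)
        sampled = df["sampled"].to_numpy().astype(bool).reshape(shape)
        dx = xc[1] - xc[0] if nx > 1 else 1.0
        dy = yc[1] - yc[0] if ny > 1 else 1.0
        x_edges = np.concatenate([xc - dx / 2, [xc[-1] + dx / 2]])
        y_edges = np.concatenate([yc - dy / 2, [yc[-1] + dy / 2]])
        return cls(x_edges, y_edges, g, sampled, err, temperature)


@dataclass(frozen=True)
class Basin:
    """A local minimum of the surface over sampled bins."""

    ix: int
    iy: int
    x: float
    y: float
    free_energy: float


def _sampled_region_connected(sampled: np.ndarray) -> bool:
    """True if the sampled bins form one 8-connected component."""
    idx = np.argwhere(sampled)
    if len(idx) == 0:
        return True
    seen = np.zeros_like(sampled, dtype=bool)
    stack = [tuple(idx[0])]
    seen[tuple(idx[0])] = True
    nx, ny = sampled.shape
    while stack:
        i, j = stack.pop()
        for di, dj in NEIGHBOR_OFFSETS:
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and sampled[a, b] and not seen[a, b]:
                seen[a, b] = True
                stack.append((a, b))
    return bool(seen.sum() == len(idx))


def estimate_fes(
    windows: list[UmbrellaWindow],
    grid: GridSpec | str = GridSpec(),
    tol: float = 1e-7,
    max_iter: int = 100_000,
    min_count: int = 5,
) -> FreeEnergySurface:
    """Reconstruct the 2D free-energy surface from umbrella windows.

    Parameters
    ----------
    windows : list of UmbrellaWindow
        All windows must share one temperature.
    grid : GridSpec or '50x50' string
        Histogram grid; ranges default to the sampled extent.
    tol : float
        Convergence threshold on the sup-norm change of the window
        shifts, kcal/mol.
    max_iter : int
        Iteration cap; exceeding it raises :class:`WhamConvergenceError`.
    min_count : int
        Bins with fewer total samples are masked out.
    """
    if not windows:
        raise ValueError("need at least one window")
    temps = {w.temperature for w in windows}
    if len({round(t, 6) for t in temps}) > 1:
        raise ValueError(f"windows must share one temperature, got {sorted(temps)}")
    temperature = windows[0].temperature
    kbt = kt(temperature)
    if isinstance(grid, str):
        grid = GridSpec.parse(grid)

    x_edges, y_edges = grid.edges(windows)
    nbins = grid.nx * grid.ny

    counts = np.empty((len(windows), nbins))
    tau = np.empty(len(windows))
    for i, w in enumerate(windows):
        h, _, _ = np.histogram2d(w.samples[:, 0], w.samples[:, 1], bins=(x_edges, y_edges))
        counts[i] = h.ravel()
        tau[i] = max(
            integrated_autocorr_time(w.samples[:, 0]),
            integrated_autocorr_time(w.samples[:, 1]),
        )
    n_w = counts.sum(axis=1)  # samples landing on the grid, per window
    total = counts.sum(axis=0)
    # statistical inefficiency g = 2τ discounts autocorrelated samples
    total_eff = (counts / (2.0 * tau)[:, None]).sum(axis=0)

    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    # Boltzmann factor of each window's bias at each bin center.
    bias = np.stack([w.bias_energy(gx, gy).ravel() for w in windows])
    bfac = np.exp(-bias / kbt)  # (n_windows, nbins)

    f = np.zeros(len(windows))  # shifts in kcal/mol
    numer = total  # fixed numerator of the P update
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        ef = np.exp(f / kbt)
        denom = (n_w * ef) @ bfac  # Σ_i N_i exp((f_i − c_ib)/kBT), per bin
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, numer / denom, 0.0)
        z = bfac @ p  # window partition functions (unnormalized)
        f_new = -kbt * np.log(z)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise WhamConvergenceError(residual, max_iter)

    sampled = (total >= min_count) & (p > 0)
    with np.errstate(divide="ignore"):
        g = -kbt * np.log(np.where(p > 0, p, np.nan))
    g[~sampled] = np.nan
    g -= np.nanmin(g[sampled]) if sampled.any() else 0.0
    # Quick per-bin error: counting noise propagated through the log, with
    # each window's samples discounted by its integrated autocorrelation
    # time; serious error bars come from the block bootstrap.
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.where(sampled, kbt / np.sqrt(np.maximum(total_eff, 1e-300)), np.nan)

    shape = (grid.nx, grid.ny)
    sampled2 = sampled.reshape(shape)
    connected = _sampled_region_connected(sampled2)
    if not connected:
        warnings.warn(
            "sampled bins do not form one connected region; the surface is "
            "disconnected and window overlap is insufficient",
            stacklevel=2,
        )
    return FreeEnergySurface(
        x_edges=x_edges,
        y_edges=y_edges,
        free_energy=g.reshape(shape),
        sampled=sampled2,
        stderr=err.reshape(shape),
        temperature=temperature,
        n_iterations=iteration,
        residual=residual,
        connected=connected,
        window_shifts=f,
    )


def select_reaction_basins(
    fes: FreeEnergySurface, min_separation: float = 0.25
) -> tuple[Basin, Basin]:
    """Pick the reactant/product pair among a surface's basins.

    Sampling noise can split one physical well into several nearby
    local minima, so the pair is chosen as the lowest basin plus the
    lowest basin at least ``min_separation`` (as a fraction of the grid
    diagonal) away from it.  Raises if no sufficiently separated
    partner exists.
    """
    basins = locate_basins(fes)
    if len(basins) < 2:
        raise ValueError("surface has fewer than 2 basins")
    span = math.hypot(
        fes.x_edges[-1] - fes.x_edges[0], fes.y_edges[-1] - fes.y_edges[0]
    )
    first = basins[0]
    for cand in basins[1:]:
        if math.hypot(cand.x - first.x, cand.y - first.y) >= min_separation * span:
            return first, cand
    raise ValueError(
        f"no second basin at least {min_separation:.0%} of the grid diagonal "
        "away from the global minimum; the surface may have a single well"
    )


def locate_basins(fes: FreeEnergySurface) -> list[Basin]:
    """Local minima of the surface over its sampled bins.

    A sampled bin is a basin if no sampled 8-neighbour is strictly
    lower.  Plateau ties are broken toward the lowest flattened bin
    index (row-major), so an all-equal surface yields one basin at the
    first sampled bin.  Results are sorted by free energy, then bin
    index.
    """
    if not fes.sampled.any():
        raise ValueError("surface has no sampled bins")
    g = fes.free_energy
    nx, ny = g.shape
    basins: list[Basin] = []
    claimed_plateau: set[tuple[int, int]] = set()
    for i in range(nx):
        for j in range(ny):
            if not fes.sampled[i, j]:
                continue
            val = g[i, j]
            is_min = True
            ties: list[tuple[int, int]] = []
            for di, dj in NEIGHBOR_OFFSETS:
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and fes.sampled[a, b]:
                    if g[a, b] < val:
                        is_min = False
                        break
                    if g[a, b] == val:
                        ties.append((a, b))
            if not is_min:
                continue
            # plateau rule: only the lowest-index member of an equal-value
            # neighbourhood is reported
            if any((a, b) in claimed_plateau for a, b in ties if (a * ny + b) < (i * ny + j)):
                continue
            if any((a * ny + b) < (i * ny + j) and g[a, b] == val for a, b in ties):
                continue
            claimed_plateau.add((i, j))
            basins.append(
                Basin(ix=i, iy=j, x=float(fes.x_centers[i]), y=float(fes.y_centers[j]),
                      free_energy=float(val))
            )
    basins.sort(key=lambda b: (b.free_energy, b.ix, b.iy))
    return basins
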