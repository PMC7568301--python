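"""Moving-block bootstrap errors for the WHAM → MFEP chain.

Umbrella-window time series are autocorrelated, so plain resampling of
individual frames underestimates errors.  Each bootstrap replicate
rebuilds every window from contiguous blocks (moving-block bootstrap,
default block length = series length / 20), re-runs the WHAM estimate
and path extraction on the same grid, and records the barrier, the
reaction free energy and the per-bin surface.  Reported errors are the
standard deviations over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mfep import PathError, extract_mfep
from .wham import FreeEnergySurface, GridSpec, estimate_fes, locate_basins
from .windows import UmbrellaWindow

__all__ = ["BootstrapErrors", "bootstrap_errors", "block_resample"]


@dataclass
class BootstrapErrors:
    """Standard errors from the block bootstrap of the full chain."""

    barrier_err: float  # kcal/mol
    reaction_free_energy_err: float  # kcal/mol
    bin_stderr: np.ndarray  # (nx, ny) spread of G per bin, NaN if never sampled
    n_replicates: int
    n_failed: int  # replicates where path extraction failed


def block_resample(series: np.ndarray, block_len: int, rng: np.random.Generator) -> np.ndarray:
    """Moving-block bootstrap of a (n, d) time series, length preserved."""
    n = len(series)
    if block_len >= n:
        raise ValueError(f"block length {block_len} must be shorter than the series ({n})")
    if block_len < 1:
        raise ValueError("block length must be >= 1")
    n_blocks = -(-n // block_len)
    starts = rng.integers(0, n - block_len + 1, size=n_blocks)
    parts = [series[s:s + block_len] for s in starts]
    return np.concatenate(parts)[:n]


def bootstrap_errors(
    windows: list[UmbrellaWindow],
    grid: GridSpec | str = GridSpec(),
    n_boot: int = 50,
    block_len: int | None = None,
    seed: int = 0,
    reference: FreeEnergySurface | None = None,
    reactant: tuple[int, int] | None = None,
    product: tuple[int, int] | None = None,
) -> BootstrapErrors:
    """Bootstrap standard errors for ∆G‡, ∆G_reaction and the per-bin surface.

    The reference surface (computed here unless supplied) fixes the
    histogram grid; every replicate is analyzed on that same grid so
    bins align across replicates.  Reactant and product default to the
    two lowest basins of the reference surface but can be pinned
    explicitly (bin indices).  Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise ValueError(f"need at least 2 bootstrap replicates, got {n_boot}")
    if isinstance(grid, str):
        grid = GridSpec.parse(grid)
    if reference is None:
        reference = estimate_fes(windows, grid)
    # pin the grid to the reference edges so replicate bins align
    fixed = GridSpec(
        nx=len(reference.x_centers),
        ny=len(reference.y_centers),
        x_range=(reference.x_edges[0], reference.x_edges[-1]),
        y_range=(reference.y_edges[0], reference.y_edges[-1]),
    )
    if reactant is not None and product is not None:
        r_bin, p_bin = tuple(reactant), tuple(product)
    else:
        ref_basins = locate_basins(reference)
        if len(ref_basins) < 2:
            r_bin = p_bin = (ref_basins[0].ix, ref_basins[0].iy)
        else:
            r_bin = (ref_basins[0].ix, ref_basins[0].iy)
            p_bin = (ref_basins[1].ix, ref_basins[1].iy)

    rng = np.random.default_rng(seed)
    barriers, dgs = [], []
    g_stack = np.full((n_boot,) + reference.free_energy.shape, np.nan)
    n_failed = 0
    for rep in range(n_boot):
        rewindows = []
        for w in windows:
            bl = block_len if block_len is not None else max(1, w.n_samples // 20)
            rewindows.append(
                UmbrellaWindow(
                    center=w.center,
                    force_constants=w.force_constants,
                    temperature=w.temperature,
                    samples=block_resample(w.samples, bl, rng),
                )
            )
        fes = estimate_fes(rewindows, fixed)
        g_stack[rep] = fes.free_energy
        try:
            rr = _nearest_sampled(fes, r_bin)
            pp = _nearest_sampled(fes, p_bin)
            path = extract_mfep(fes, rr, pp)
        except (PathError, ValueError):
            n_failed += 1
            continue
        barriers.append(path.barrier)
        dgs.append(path.reaction_free_energy)

    with np.errstate(invalid="ignore"):
        bin_err = np.nanstd(g_stack, axis=0, ddof=1)
    return BootstrapErrors(
        barrier_err=float(np.std(barriers, ddof=1)) if len(barriers) > 1 else float("nan"),
        reaction_free_energy_err=float(np.std(dgs, ddof=1)) if len(dgs) > 1 else float("nan"),
        bin_stderr=bin_err,
        n_replicates=n_boot,
        n_failed=n_failed,
    )


def _nearest_sampled(fes: FreeEnergySurface, target: tuple[int, int]) -> tuple[int, int]:
    """The sampled bin nearest to ``target`` (Euclidean on bin indices)."""
    if fes.sampled[target]:
        return target
    idx = np.argwhere(fes.sampled)
    if len(idx) == 0:
        raise ValueError("surface has no sampled bins")
    d = ((idx - np.array(target)) ** 2).sum(axis=1)
    return tuple(idx[np.argmin(d)])
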