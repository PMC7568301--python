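"""MFEP extraction checked against independent path oracles.

Two oracles verify the bottleneck stage: exhaustive enumeration of all
simple paths (tiny grids), and a threshold/flood-fill search — the
smallest level L such that start and goal are connected through bins
with G ≤ L — which is a different algorithm from the Dijkstra-style
scan under test.
"""

import numpy as np
import pytest

from hydrolase_duo.fes import FreeEnergySurface, PathError, extract_mfep, locate_basins
from hydrolase_duo.fes.mfep import bottleneck_path

OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def make_surface(g, sampled=None):
    g = np.asarray(g, dtype=float)
    nx, ny = g.shape
    sampled = np.ones_like(g, dtype=bool) if sampled is None else sampled
    return FreeEnergySurface(
        x_edges=np.arange(nx + 1, dtype=float),
        y_edges=np.arange(ny + 1, dtype=float),
        free_energy=g,
        sampled=sampled,
        stderr=np.zeros_like(g),
        temperature=303.15,
    )


def oracle_enumerate(g, start, goal):
    """Min over all simple paths of the max value en route (exponential)."""
    nx, ny = g.shape
    best = [np.inf]

    def dfs(node, seen, peak):
        peak = max(peak, g[node])
        if peak >= best[0]:
            return
        if node == goal:
            best[0] = peak
            return
        for di, dj in OFFSETS:
            nb = (node[0] + di, node[1] + dj)
            if 0 <= nb[0] < nx and 0 <= nb[1] < ny and nb not in seen:
                dfs(nb, seen | {nb}, peak)

    dfs(start, {start}, -np.inf)
    return best[0]


def oracle_threshold(g, sampled, start, goal):
    """Smallest level whose sublevel set connects start to goal (flood fill)."""
    values = sorted({g[i, j] for i in range(g.shape[0]) for j in range(g.shape[1])
                     if sampled[i, j]})
    for level in values:
        ok = sampled & (g <= level)
        if not (ok[start] and ok[goal]):
            continue
        stack, seen = [start], {start}
        while stack:
            node = stack.pop()
            if node == goal:
                return level
            for di, dj in OFFSETS:
                nb = (node[0] + di, node[1] + dj)
                if (0 <= nb[0] < g.shape[0] and 0 <= nb[1] < g.shape[1]
                        and ok[nb] and nb not in seen):
                    seen.add(nb)
                    stack.append(nb)
    return np.inf


class TestBottleneckOracles:
    @pytest.mark.parametrize("shape", [(3, 3), (3, 4)])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, shape, seed):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0, 10, size=shape)
        start, goal = (0, 0), (shape[0] - 1, shape[1] - 1)
        sampled = np.ones(shape, dtype=bool)
        _, value = bottleneck_path(g, sampled, start, goal)
        assert value == pytest.approx(oracle_enumerate(g, start, goal))

    @pytest.mark.parametrize("shape", [(5, 5), (6, 6)])
    @pytest.mark.parametrize("seed", [10, 11, 12, 13, 14])
    def test_matches_threshold_flood_fill(self, shape, seed):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0, 10, size=shape)
        sampled = rng.random(shape) > 0.15
        start = goal = None
        idx = np.argwhere(sampled)
        start, goal = tuple(idx[0]), tuple(idx[-1])
        expected = oracle_threshold(g, sampled, start, goal)
        if np.isinf(expected):
            with pytest.raises(PathError):
                bottleneck_path(g, sampled, start, goal)
        else:
            _, value = bottleneck_path(g, sampled, start, goal)
            assert value == pytest.approx(expected)

    def test_hand_written_ridge_grid(self):
        """A 5×5 grid with a ridge: the path must cross at the lowest pass (4)."""
        g = np.array(
            [
                [0.0, 1.0, 9.0, 1.0, 0.5],
                [1.0, 2.0, 8.0, 2.0, 1.0],
                [1.5, 3.0, 4.0, 3.0, 1.5],
                [1.0, 2.0, 7.0, 2.0, 1.0],
                [0.5, 1.0, 9.0, 1.0, 0.2],
            ]
        )
        sampled = np.ones_like(g, dtype=bool)
        path, value = bottleneck_path(g, sampled, (0, 0), (0, 4))
        assert value == pytest.approx(4.0)
        assert (2, 2) in path
        assert value == pytest.approx(oracle_enumerate(g, (0, 0), (0, 4)))


class TestExtractMfep:
    def test_planted_barrier_on_reconstructed_surface(self, double_well_fes):
        basins = locate_basins(double_well_fes)
        path = extract_mfep(double_well_fes, basins[0], basins[1])
        assert path.barrier == pytest.approx(10.0, abs=0.3)
        assert path.saddle_coordinates[0] == pytest.approx(0.0, abs=0.15)
        assert path.free_energy[path.saddle_index] == max(path.free_energy)

    def test_path_is_grid_connected(self, double_well_fes):
        basins = locate_basins(double_well_fes)
        path = extract_mfep(double_well_fes, basins[0], basins[1])
        for a, b in zip(path.bins, path.bins[1:]):
            assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1

    def test_same_basin_gives_zero_length_path(self):
        fes = make_surface(np.zeros((4, 4)))
        path = extract_mfep(fes, (1, 1), (1, 1))
        assert path.barrier == 0.0
        assert path.reaction_free_energy == 0.0
        assert len(path.bins) == 1

    def test_barrier_never_negative(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            g = rng.uniform(0, 5, size=(6, 6))
            fes = make_surface(g)
            basins = locate_basins(fes)
            if len(basins) < 2:
                continue
            path = extract_mfep(fes, basins[0], basins[1])
            assert path.barrier >= 0.0

    def test_disconnected_basins_raise_path_error(self):
        g = np.zeros((5, 5))
        sampled = np.ones((5, 5), dtype=bool)
        sampled[:, 2] = False  # unsampled wall
        fes = make_surface(g, sampled)
        with pytest.raises(PathError, match="not connected"):
            extract_mfep(fes, (0, 0), (0, 4))


class TestLocateBasins:
    def test_monotone_plane_has_single_corner_basin(self):
        g = np.add.outer(np.arange(5.0), np.arange(5.0))
        basins = locate_basins(make_surface(g))
        assert len(basins) == 1
        assert (basins[0].ix, basins[0].iy) == (0, 0)

    def test_all_equal_surface_ties_break_to_lowest_bin_index(self):
        basins = locate_basins(make_surface(np.zeros((3, 3))))
        assert len(basins) == 1
        assert (basins[0].ix, basins[0].iy) == (0, 0)

    def test_analytic_double_well_grid_has_exactly_two_basins(self, double_well):
        xs = np.linspace(-1.5, 1.5, 31)
        ys = np.linspace(-1.0, 1.0, 21)
        g = double_well.energy(*np.meshgrid(xs, ys, indexing="ij"))
        fes = FreeEnergySurface(
            x_edges=np.linspace(-1.55, 1.55, 32),
            y_edges=np.linspace(-1.05, 1.05, 22),
            free_energy=g,
            sampled=np.ones_like(g, dtype=bool),
            stderr=np.zeros_like(g),
            temperature=303.15,
        )
        basins = locate_basins(fes)
        assert len(basins) == 2
        coords = sorted((round(b.x, 1), round(b.y, 1)) for b in basins)
        assert coords == [(-1.0, -0.5), (1.0, 0.5)]

    def test_empty_surface_rejected(self):
        fes = make_surface(np.zeros((3, 3)), sampled=np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError, match="no sampled bins"):
            locate_basins(fes)
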