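"""Shared fixtures: sampled umbrella windows, synthetic families, toy structures.

The expensive fixtures (Langevin window sets) are session-scoped so the
surface-reconstruction tests share one sampling run.
"""

from __future__ import annotations

import numpy as np
import pytest

from hydrolase_duo.fes import GridSpec, estimate_fes
from hydrolase_duo.synth import (
    FamilySpec,
    ToyStructureSpec,
    default_window_grid,
    gen_family_msa,
    gen_toy_structure,
    make_potential,
    sample_windows,
)


@pytest.fixture(scope="session")
def double_well():
    """The default landscape: barrier 10 kcal/mol, minima (±1, ±0.5)."""
    return make_potential()


@pytest.fixture(scope="session")
def double_well_windows(double_well):
    """Umbrella windows tiling the double well (shared sampling run)."""
    specs = default_window_grid(double_well, n_samples=4000)
    return sample_windows(double_well, specs, seed=20260928)


@pytest.fixture(scope="session")
def double_well_fes(double_well_windows):
    return estimate_fes(double_well_windows, GridSpec(nx=50, ny=50))


@pytest.fixture(scope="session")
def two_subfamily_data():
    """A strongly diverged two-subfamily alignment with planted Cys columns."""
    spec = FamilySpec(
        n_sequences=40,
        length=60,
        conservation=0.85,
        divergence=0.5,
        planted={5: ("C", 1.0), 25: ("C", 1.0)},
    )
    return gen_family_msa(spec, seed=97)


@pytest.fixture()
def toy_structure():
    return gen_toy_structure(ToyStructureSpec())


@pytest.fixture()
def rigid_transform():
    """A fixed non-trivial rotation + translation for invariance tests."""
    rng = np.random.default_rng(12)
    m = rng.standard_normal((3, 3))
    q, _ = np.linalg.qr(m)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-30, 30, size=3)
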