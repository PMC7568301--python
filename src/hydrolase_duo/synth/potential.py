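"""Analytic two-basin model potentials for collective-variable sampling.

The default landscape is a quartic double well coupled to a transverse
harmonic coordinate,

    V(x, y) = A·(x² − 1)² + B·(y − s·x)²,

a minimal stand-in for the two-basin (reactant/product) free-energy
landscape of a chemical step described by two distance-like collective
variables.  It has exactly two minima, at (±1, ±s) with V = 0, and a
single saddle at the origin with V = A, so the barrier height is known
in closed form and can be used as ground truth for surface
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnalyticPotential", "make_potential"]


@dataclass(frozen=True)
class AnalyticPotential:
    """An analytic model landscape on a rectangular domain.

    Two functional forms are supported:

    ``"double-well"`` (default)
        V(x, y) = A·(x²−1)² + B·(y−s·x)², two minima and one saddle.
    ``"harmonic"``
        V(x, y) = ½·B·(x² + y²), a single isotropic well of curvature B
        (A and s are ignored); its reconstructed surface is quadratic
        with known curvature, a useful oracle.

    Parameters
    ----------
    barrier : float
        A, the saddle height above the minima, kcal/mol.
    stiffness : float
        B, harmonic stiffness, kcal/mol/Å².
    coupling : float
        s, dimensionless tilt of the transverse valley.
    bounds : tuple
        ((xmin, xmax), (ymin, ymax)) domain in Å.
    form : str
        Functional form id.
    """

    barrier: float
    stiffness: float
    coupling: float = 0.0
    bounds: tuple[tuple[float, float], tuple[float, float]] = field(
        default=((-2.0, 2.0), (-2.0, 2.0))
    )
    form: str = "double-well"

    def __post_init__(self) -> None:
        if self.form not in ("double-well", "harmonic"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if self.barrier <= 0:
            raise ValueError(f"barrier height A must be positive, got {self.barrier}")
        if self.stiffness <= 0:
            raise ValueError(f"stiffness B must be positive, got {self.stiffness}")
        (x0, x1), (y0, y1) = self.bounds
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate domain bounds {self.bounds}")

    def energy(self, x, y):
        """V(x, y) in kcal/mol; broadcasts over array input."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        a, b, s = self.barrier, self.stiffness, self.coupling
        if self.form == "harmonic":
            return 0.5 * b * (x * x + y * y)
        return a * (x * x - 1.0) ** 2 + b * (y - s * x) ** 2

    def gradient(self, x: float, y: float) -> tuple[float, float]:
        """(∂V/∂x, ∂V/∂y) at a point, kcal/mol/Å."""
        a, b, s = self.barrier, self.stiffness, self.coupling
        if self.form == "harmonic":
            return b * x, b * y
        t = y - s * x
        gx = 4.0 * a * x * (x * x - 1.0) - 2.0 * b * s * t
        gy = 2.0 * b * t
        return gx, gy

    @property
    def minima(self) -> list[tuple[float, float]]:
        """Locations of the exact minima (V = 0 at each)."""
        if self.form == "harmonic":
            return [(0.0, 0.0)]
        s = self.coupling
        return [(-1.0, -s), (1.0, s)]

    @property
    def saddle(self) -> tuple[float, float]:
        """The saddle point (0, 0) of the double well, V = barrier."""
        if self.form == "harmonic":
            raise ValueError("a harmonic well has no saddle point")
        return (0.0, 0.0)

    @property
    def max_curvature(self) -> float:
        """Upper bound on |∂²V| over the domain, used to pick stable step sizes."""
        (x0, x1), _ = self.bounds
        xm = max(abs(x0), abs(x1))
        return self.curvature_bound(xm, 0.0)

    def curvature_bound(self, x: float, y: float) -> float:
        """Gershgorin bound on the largest |Hessian eigenvalue| at a point."""
        a, b, s = self.barrier, self.stiffness, self.coupling
        if self.form == "harmonic":
            return b
        vxx = 4.0 * a * (3.0 * x * x - 1.0) + 2.0 * b * s * s
        vyy = 2.0 * b
        vxy = -2.0 * b * s
        return max(abs(vxx) + abs(vxy), vyy + abs(vxy), 4.0 * a)

    def contains(self, x: float, y: float) -> bool:
        (x0, x1), (y0, y1) = self.bounds
        return x0 <= x <= x1 and y0 <= y <= y1


def make_potential(
    barrier: float = 10.0,
    stiffness: float = 5.0,
    coupling: float = 0.5,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((-2.0, 2.0), (-2.0, 2.0)),
    form: str = "double-well",
) -> AnalyticPotential:
    """Construct the default double-well landscape.

    Defaults plant a 10 kcal/mol barrier with a mildly tilted transverse
    valley (s = 0.5), which is the ground truth used throughout the
    surface-reconstruction tests.
    """
    return AnalyticPotential(
        barrier=barrier, stiffness=stiffness, coupling=coupling, bounds=bounds, form=form
    )
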