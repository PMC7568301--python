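"""Synthetic initial-velocity and timecourse data with known kinetics.

Velocities follow the Haldane substrate-inhibition form
v(S) = kcat·S/(Km + S + S²/Kk) per enzyme (Kk = ∞ recovers plain
Michaelis–Menten), with multiplicative Gaussian noise at a stated
coefficient of variation — the error structure typical of HPLC-derived
rates, where uncertainty scales with the measured value.  Additive
Gaussian noise is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..kinetics import KineticsDataset, Timecourse, si_velocity

__all__ = ["KineticTruth", "gen_velocity_table", "gen_timecourse", "MHETASE_TRUTH",
           "C_THIOOXYDANS_TRUTH", "HYDROGENOPHAGA_TRUTH"]

#: Default substrate grid, µM: log-spaced through and past the velocity optimum.
_DEFAULT_GRID = tuple(float(x) for x in np.geomspace(5.0, 1000.0, 12))


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth kinetic parameters for data generation."""

    kcat: float  # s⁻¹
    km: float  # µM
    kk: float = math.inf  # µM; inf = no substrate inhibition
    e0_nM: float = 5.0
    substrate_uM: tuple[float, ...] = field(default=_DEFAULT_GRID)
    cv: float = 0.05  # coefficient of variation of multiplicative noise

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km <= 0 or self.kk <= 0 or self.e0_nM <= 0:
            raise ValueError("kcat, Km, Kk and E0 must all be positive")
        if self.cv < 0:
            raise ValueError(f"noise CV must be >= 0, got {self.cv}")
        if len(self.substrate_uM) == 0 or any(s <= 0 for s in self.substrate_uM):
            raise ValueError("substrate grid must be non-empty and strictly positive")

    @property
    def velocity_optimum_uM(self) -> float:
        """S* = √(Km·Kk), the substrate level of maximal velocity (inf if MM)."""
        return math.sqrt(self.km * self.kk) if math.isfinite(self.kk) else math.inf

    def velocity(self, s) -> np.ndarray:
        """Noise-free per-enzyme velocity at substrate level(s) s, s⁻¹."""
        return si_velocity(s, self.kcat, self.km, self.kk if math.isfinite(self.kk) else 1e300)


#: Wild-type MHETase kinetic constants (kcat s⁻¹, Km µM, Kk µM).
MHETASE_TRUTH = KineticTruth(kcat=27.6, km=23.17, kk=307.30)
#: C. thiooxydans homolog: only Km is an established constant; kcat is set for a
#: comparable maximal rate and Kk for visibly weaker inhibition.
C_THIOOXYDANS_TRUTH = KineticTruth(kcat=27.2, km=174.70, kk=1468.0)
#: Hydrogenophaga sp. PML113 homolog (slower enzyme, Km as established).
HYDROGENOPHAGA_TRUTH = KineticTruth(kcat=7.7, km=41.09, kk=575.0)


def gen_velocity_table(
    truth: KineticTruth,
    seed: int,
    replicates: int = 1,
    noise: str = "multiplicative",
) -> KineticsDataset:
    """Generate a noisy initial-velocity table from a kinetic truth.

    Multiplicative noise scales each velocity by N(1, cv); additive
    noise adds N(0, cv·v̄) with v̄ the mean noise-free velocity.
    ``cv = 0`` returns exact model values.  Deterministic given seed.
    """
    if noise not in ("multiplicative", "additive"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    s = np.tile(np.asarray(truth.substrate_uM, dtype=float), replicates)
    rep = np.repeat(np.arange(replicates), len(truth.substrate_uM))
    v = truth.velocity(s)
    if truth.cv > 0:
        if noise == "multiplicative":
            v = v * (1.0 + truth.cv * rng.standard_normal(len(v)))
        else:
            v = v + truth.cv * float(np.mean(v)) * rng.standard_normal(len(v))
    return KineticsDataset(
        substrate_uM=s, velocity=v, velocity_units="per_enzyme",
        e0_nM=truth.e0_nM, replicate=rep,
    )


def gen_timecourse(
    truth: KineticTruth,
    substrate_uM: float = 250.0,
    duration_s: float = 60.0,
    n_points: int = 31,
    seed: int = 0,
) -> Timecourse:
    """Product-accumulation timecourse at one substrate level.

    Product grows linearly at the initial rate v(S)·E₀ (µM/s); noise is
    multiplicative at the truth's CV.  Substrate depletion is not
    modelled, so only the early window is kinetically meaningful —
    which is exactly what initial-rate estimation assumes.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    rate_uM_s = truth.velocity(substrate_uM) * truth.e0_nM * 1e-3
    p = rate_uM_s * t
    if truth.cv > 0:
        p = p * (1.0 + truth.cv * rng.standard_normal(len(p)))
        p[0] = 0.0
    return Timecourse(time_s=t, product_uM=p, e0_nM=truth.e0_nM, substrate_uM=substrate_uM)
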