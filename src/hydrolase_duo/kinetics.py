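"""Steady-state enzyme kinetics: Michaelis–Menten and substrate inhibition.

Initial-velocity data v(S) are fit by nonlinear least squares to the
Michaelis–Menten model

    v = kcat·E₀·S / (Km + S)                      (MM)

or the Haldane single-site substrate-inhibition model

    v = kcat·E₀·S / (Km + S + S²/Kk)              (MM_SI)

with all parameters constrained positive.  MM is nested in MM_SI
(Kk → ∞), so the models are compared with an extra-sum-of-squares
F-test (α = 0.05), with small-sample AICc reported alongside.
Confidence intervals come from a case-resampling percentile bootstrap.

Velocities may be supplied per enzyme (s⁻¹) or as µM/s together with
the enzyme concentration E₀ (nM); all fitted parameters are reported
per enzyme (kcat in s⁻¹, Km and Kk in µM, efficiency in µM⁻¹·s⁻¹).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticsDataset",
    "KineticsFit",
    "Timecourse",
    "mm_velocity",
    "si_velocity",
    "fit_mm",
    "fit_substrate_inhibition",
    "select_model",
    "initial_rate",
    "confidence_intervals",
]

#: Kk at or above this bound (µM) is treated as "no inhibition detectable".
KK_UPPER_BOUND = 1e9


def mm_velocity(s, kcat: float, km: float):
    """Per-enzyme Michaelis–Menten velocity, s⁻¹."""
    s = np.asarray(s, dtype=float)
    return kcat * s / (km + s)


def si_velocity(s, kcat: float, km: float, kk: float):
    """Per-enzyme substrate-inhibition velocity, s⁻¹ (Kk may be inf)."""
    s = np.asarray(s, dtype=float)
    return kcat * s / (km + s + s * s / kk)


@dataclass(frozen=True)
class KineticsDataset:
    """Initial velocities over a substrate grid.

    ``velocity_units`` is either ``"per_enzyme"`` (s⁻¹) or ``"uM_per_s"``;
    the latter requires ``e0_nM`` and is converted on access.
    """

    substrate_uM: np.ndarray
    velocity: np.ndarray
    velocity_units: str = "per_enzyme"
    e0_nM: float | None = None
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_uM, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        if s.shape != v.shape:
            raise ValueError("substrate and velocity arrays must align")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be strictly positive")
        if self.velocity_units not in ("per_enzyme", "uM_per_s"):
            raise ValueError(f"unknown velocity units {self.velocity_units!r}")
        if self.velocity_units == "uM_per_s" and not self.e0_nM:
            raise ValueError("uM_per_s velocities require e0_nM")
        object.__setattr__(self, "substrate_uM", s)
        object.__setattr__(self, "velocity", v)

    @property
    def turnover(self) -> np.ndarray:
        """Velocities per enzyme, s⁻¹ (E₀ in nM → µM conversion by 1e-3)."""
        if self.velocity_units == "per_enzyme":
            return self.velocity
        return self.velocity / (self.e0_nM * 1e-3)

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.substrate_uM))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"substrate_uM": self.substrate_uM, "velocity": self.velocity})
        if self.replicate is not None:
            df["replicate"] = self.replicate
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(
        cls, path: str | Path, velocity_units: str = "per_enzyme", e0_nM: float | None = None
    ) -> "KineticsDataset":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(
            substrate_uM=df["substrate_uM"].to_numpy(),
            velocity=df["velocity"].to_numpy(),
            velocity_units=velocity_units,
            e0_nM=e0_nM,
            replicate=df["replicate"].to_numpy() if "replicate" in df else None,
        )


@dataclass(frozen=True)
class Timecourse:
    """Product accumulation over time at one substrate concentration."""

    time_s: np.ndarray
    product_uM: np.ndarray
    e0_nM: float
    substrate_uM: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.product_uM, dtype=float)
        if t.shape != p.shape:
            raise ValueError("time and product arrays must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "product_uM", p)


@dataclass
class KineticsFit:
    """Result of an MM or MM_SI nonlinear least-squares fit."""

    model: str  # "MM" or "MM_SI"
    kcat: float  # s⁻¹
    km: float  # µM
    kk: float = math.inf  # µM; inf = no substrate inhibition
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    rss: float = float("nan")
    aicc: float = float("nan")
    n_obs: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km, µM⁻¹·s⁻¹."""
        return self.kcat / self.km

    def predict(self, s) -> np.ndarray:
        if math.isinf(self.kk):
            return mm_velocity(s, self.kcat, self.km)
        return si_velocity(s, self.kcat, self.km, self.kk)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return float("inf")
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _initial_guesses(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    vmax = float(np.max(v))
    if vmax <= 0:
        return 1e-6, float(np.median(s))
    half = 0.5 * vmax
    above = s[v >= half]
    km0 = float(np.min(above)) if len(above) else float(np.median(s))
    return vmax, max(km0, 1e-6)


def fit_mm(ds: KineticsDataset) -> KineticsFit:
    """Fit the Michaelis–Menten model; needs ≥ 3 distinct substrate levels."""
    if ds.n_levels < 3:
        raise ValueError(f"MM fit needs >= 3 distinct substrate levels, got {ds.n_levels}")
    s, v = ds.substrate_uM, ds.turnover
    kcat0, km0 = _initial_guesses(s, v)
    try:
        popt, _ = optimize.curve_fit(
            mm_velocity, s, v, p0=[kcat0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"MM fit failed to converge (p0=kcat {kcat0:.3g}, Km {km0:.3g}): {exc}")
    kcat, km = (float(p) for p in popt)
    rss = float(np.sum((v - mm_velocity(s, kcat, km)) ** 2))
    flags = []
    if km < 1e-3 * float(np.min(s)):
        flags.append("degenerate_km")  # saturated data: Km indistinct from 0
    return KineticsFit(
        model="MM", kcat=kcat, km=km, rss=rss,
        aicc=_aicc(rss, len(s), 2), n_obs=len(s), flags=flags,
    )


def fit_substrate_inhibition(ds: KineticsDataset) -> KineticsFit:
    """Fit the substrate-inhibition model; needs ≥ 4 distinct substrate levels.

    If the best-fit Kk reaches the numerical upper bound, inhibition is
    not detectable and the fit is flagged ``effectively_mm``.  If the
    largest observed velocity sits at the largest substrate level, no
    decline was observed and Kk carries an ``kk_unidentifiable`` flag.
    """
    if ds.n_levels < 4:
        raise ValueError(
            f"substrate-inhibition fit needs >= 4 distinct substrate levels, got {ds.n_levels}"
        )
    s, v = ds.substrate_uM, ds.turnover
    kcat0, km0 = _initial_guesses(s, v)
    try:
        popt, _ = optimize.curve_fit(
            si_velocity, s, v, p0=[kcat0, km0, 10.0 * float(np.max(s))],
            bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, KK_UPPER_BOUND]),
            maxfev=50_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"substrate-inhibition fit failed to converge: {exc}")
    kcat, km, kk = (float(p) for p in popt)
    flags = []
    if kk >= 0.99 * KK_UPPER_BOUND:
        flags.append("effectively_mm")
        kk = math.inf
    smax_level = s[int(np.argmax(v))]
    if smax_level >= float(np.max(s)):
        flags.append("kk_unidentifiable")
    rss = float(np.sum((v - si_velocity(s, kcat, km, kk if kk != math.inf else 1e300)) ** 2))
    return KineticsFit(
        model="MM_SI", kcat=kcat, km=km, kk=kk, rss=rss,
        aicc=_aicc(rss, len(s), 3), n_obs=len(s), flags=flags,
    )


@dataclass(frozen=True)
class ModelSelection:
    """Extra-sum-of-squares comparison between nested MM and MM_SI fits."""

    chosen: str
    f_statistic: float
    p_value: float
    alpha: float
    mm: KineticsFit
    mm_si: KineticsFit

    @property
    def delta_aicc(self) -> float:
        return self.mm_si.aicc - self.mm.aicc


def select_model(ds: KineticsDataset, alpha: float = 0.05) -> ModelSelection:
    """Choose MM vs MM_SI by the extra-sum-of-squares F-test at ``alpha``."""
    mm = fit_mm(ds)
    mm_si = fit_substrate_inhibition(ds)
    n = len(ds.substrate_uM)
    df_full = n - 3
    if df_full <= 0:
        raise ValueError("too few observations for the F-test")
    # an essentially perfect MM fit (RSS at floating-point noise) cannot
    # justify the extra parameter, whatever the RSS ratio says
    perfect = mm.rss <= 1e-12 * float(np.sum(ds.turnover**2))
    if perfect or mm_si.rss >= mm.rss or mm_si.rss <= 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat = (mm.rss - mm_si.rss) / (mm_si.rss / df_full)
        p = float(stats.f.sf(f_stat, 1, df_full))
    chosen = "MM_SI" if p < alpha else "MM"
    return ModelSelection(chosen=chosen, f_statistic=float(f_stat), p_value=p,
                          alpha=alpha, mm=mm, mm_si=mm_si)


def initial_rate(tc: Timecourse, linear_fraction: float = 0.10) -> float:
    """Per-enzyme turnover (s⁻¹) from the initial linear window.

    Uses the least-squares slope over points where product is below
    ``linear_fraction`` of the substrate concentration, divided by E₀
    (nM → µM).  Needs at least 3 such points.
    """
    mask = tc.product_uM < linear_fraction * tc.substrate_uM
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} points below {linear_fraction:.0%} conversion; "
            "need >= 3 in the linear window"
        )
    slope = float(np.polyfit(tc.time_s[mask], tc.product_uM[mask], 1)[0])
    return slope / (tc.e0_nM * 1e-3)


def confidence_intervals(
    fit: KineticsFit,
    ds: KineticsDataset,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> KineticsFit:
    """Attach case-resampling percentile bootstrap CIs to a fit.

    Resamples (S, v) pairs with replacement, refits the same model per
    replicate, and reports percentile intervals for kcat, Km, Kk (when
    applicable) and kcat/Km.  Deterministic given ``seed``.
    """
    if n_boot < 50:
        warnings.warn(f"{n_boot} bootstrap replicates is too few for stable CIs", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(ds.substrate_uM)
    refit = fit_substrate_inhibition if fit.model == "MM_SI" else fit_mm
    draws: dict[str, list[float]] = {"kcat": [], "km": [], "kk": [], "efficiency": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = KineticsDataset(
            substrate_uM=ds.substrate_uM[idx],
            velocity=ds.velocity[idx],
            velocity_units=ds.velocity_units,
            e0_nM=ds.e0_nM,
        )
        try:
            b = refit(sub)
        except (RuntimeError, ValueError):
            continue
        draws["kcat"].append(b.kcat)
        draws["km"].append(b.km)
        draws["kk"].append(b.kk)
        draws["efficiency"].append(b.efficiency)
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ci = {}
    for name, vals in draws.items():
        if name == "kk" and fit.model != "MM_SI":
            continue
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2:
            ci[name] = (float("nan"), float("nan"))
            continue
        finite = arr[np.isfinite(arr)]
        if name == "kk" and len(finite) < len(arr):
            # Kk escaped to infinity in some replicates: upper limit unbounded
            ci[name] = (float(np.percentile(finite, lo)) if len(finite) else float("nan"),
                        math.inf)
        else:
            ci[name] = (float(np.percentile(arr, lo)), float(np.percentile(arr, hi)))
    fit.ci = ci
    return fit
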