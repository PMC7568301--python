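"""Transition-state-theory rates and the two-step mechanism summary.

The Eyring expression converts an activation free energy into a rate:

    k = κ · (k_B·T / h) · exp(−∆G‡ / R·T)

with transmission coefficient κ = 1 by default.  For a two-step serine
hydrolase mechanism (acylation then deacylation), the net reaction free
energy is the sum of the per-step values and the rate-limiting step is
the one with the larger barrier; the speed difference is summarized as
log10(k_fast/k_slow) = (∆G‡_slow − ∆G‡_fast)/(R·T·ln 10).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from ..constants import DEFAULT_TEMPERATURE, R_KCAL, eyring_prefactor, kt
from .mfep import ReactionPath

__all__ = ["RateEstimate", "MechanismSummary", "tst_rate", "two_step_summary"]


@dataclass(frozen=True)
class RateEstimate:
    """Eyring rate for one activation free energy."""

    barrier: float  # ∆G‡, kcal/mol
    temperature: float  # K
    transmission: float  # κ
    rate: float  # s⁻¹
    rate_err: float = float("nan")  # s⁻¹


@dataclass(frozen=True)
class MechanismSummary:
    """Comparison of the two catalytic steps of a serine hydrolase."""

    step_names: tuple[str, str]
    barriers: tuple[float, float]  # kcal/mol
    reaction_free_energies: tuple[float, float]  # kcal/mol
    rates: tuple[float, float]  # s⁻¹
    net_reaction_free_energy: float  # kcal/mol
    net_err: float
    rate_limiting: str
    log10_rate_ratio: float  # ≥ 0; fast over slow


def tst_rate(
    barrier: float,
    temperature: float = DEFAULT_TEMPERATURE,
    transmission: float = 1.0,
    barrier_err: float | None = None,
) -> RateEstimate:
    """Transition-state-theory rate from an activation free energy.

    A negative barrier triggers a warning and the rate is capped at the
    κ·k_BT/h prefactor (the zero-barrier limit).  If ``barrier_err`` is
    given, the rate error is propagated to first order,
    σ_k = k·σ_∆G‡/(R·T).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if not (0 < transmission <= 1):
        raise ValueError(f"transmission coefficient must be in (0, 1], got {transmission}")
    if barrier < 0:
        warnings.warn(
            f"negative barrier {barrier:.3g} kcal/mol; rate capped at the prefactor",
            stacklevel=2,
        )
        barrier = 0.0
    k = transmission * eyring_prefactor(temperature) * math.exp(-barrier / kt(temperature))
    err = float("nan") if barrier_err is None else k * barrier_err / kt(temperature)
    return RateEstimate(
        barrier=barrier, temperature=temperature, transmission=transmission,
        rate=k, rate_err=err,
    )


def two_step_summary(
    acylation: ReactionPath,
    deacylation: ReactionPath,
    temperature: float = DEFAULT_TEMPERATURE,
    transmission: float = 1.0,
    step_names: tuple[str, str] = ("acylation", "deacylation"),
) -> MechanismSummary:
    """Combine the two catalytic steps into a mechanism-level summary.

    Net free energy is the sum of the step ∆G_reaction values with
    errors combined in quadrature; the rate-limiting step is the larger
    barrier (an exact tie is labelled 'tie').
    """
    barriers = (acylation.barrier, deacylation.barrier)
    dgs = (acylation.reaction_free_energy, deacylation.reaction_free_energy)
    errs = (acylation.reaction_free_energy_err, deacylation.reaction_free_energy_err)
    net = dgs[0] + dgs[1]
    net_err = math.sqrt(sum(e * e for e in errs if not math.isnan(e))) if any(
        not math.isnan(e) for e in errs
    ) else float("nan")
    rates = tuple(
        tst_rate(b, temperature, transmission,
                 barrier_err=None if math.isnan(err) else err).rate
        for b, err in zip(barriers, (acylation.barrier_err, deacylation.barrier_err))
    )
    if barriers[0] == barriers[1]:
        limiting = "tie"
    else:
        limiting = step_names[0] if barriers[0] > barriers[1] else step_names[1]
    ratio = abs(barriers[1] - barriers[0]) / (R_KCAL * temperature * math.log(10.0))
    return MechanismSummary(
        step_names=step_names,
        barriers=barriers,
        reaction_free_energies=dgs,
        rates=rates,
        net_reaction_free_energy=net,
        net_err=net_err,
        rate_limiting=limiting,
        log10_rate_ratio=ratio,
    )
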