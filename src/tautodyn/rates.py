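"""Transition-state-theory rate constants with tunnelling corrections.

Forward and reverse rate constants follow the Eyring form

    k = κ · (1/βh) · exp(−βG),    β = 1/(k_B T),

where G is the Gibbs free-energy barrier in eV and κ the tunnelling factor
(quantum-to-classical rate ratio from the phase-space dynamics).  The same
κ multiplies both directions, which preserves detailed balance
k_f/k_r = exp(−β(G_f − G_r)).  A two-branch competition with nucleotide
unbinding converts rates into the fraction of wobble encounters that
tautomerize before the mismatched base escapes the active site.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import ParameterError, RangeError, UndefinedCompetitionError
from .pes import BarrierFreeEnergy
from .units import H_PLANCK_EV_S, KB

__all__ = [
    "ThermoContext",
    "RateResult",
    "eyring_rate",
    "rate_pair",
    "kie_from_rates",
    "unbinding_competition",
]

# exp argument bounds keeping the Eyring product inside double range
_EXP_MIN = -700.0


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and derived inverse temperature β = 1/(k_B T) in 1/eV."""

    T: float

    def __post_init__(self):
        if self.T <= 0:
            raise ParameterError("temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.T)

    @property
    def kT(self) -> float:
        return KB * self.T


@dataclass(frozen=True)
class RateResult:
    """Forward/reverse rate constants (1/s) and derived quantities."""

    k_f: float
    k_r: float
    kappa: float
    G_f: float
    G_r: float
    K_eq: float
    KIE: float | None = None

    def __post_init__(self):
        if self.k_f <= 0 or self.k_r <= 0:
            raise ParameterError("rate constants must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def eyring_rate(G: float, ctx: ThermoContext, kappa: float = 1.0) -> float:
    """κ-corrected Eyring rate k = κ·(1/βh)·exp(−βG) in s⁻¹."""
    if G < 0:
        raise ParameterError("Gibbs barrier must be non-negative")
    if kappa <= 0:
        raise ParameterError("tunnelling factor must be positive")
    arg = -ctx.beta * G
    if arg < _EXP_MIN:
        raise RangeError(
            f"exp(-beta*G) underflows for G = {G:g} eV at T = {ctx.T:g} K"
        )
    prefactor = ctx.kT / H_PLANCK_EV_S  # 1/s
    k = kappa * prefactor * math.exp(arg)
    if not math.isfinite(k) or k == 0.0:
        raise RangeError("Eyring rate outside the representable double range")
    return k


def rate_pair(
    barriers: BarrierFreeEnergy, ctx: ThermoContext, kappa: float = 1.0
) -> RateResult:
    """Forward and reverse Eyring rates sharing one tunnelling factor.

    K_eq = k_f/k_r equals exp(−β(G_f − G_r)) identically because the κ and
    1/βh prefactors cancel in the ratio.
    """
    k_f = eyring_rate(barriers.G_f, ctx, kappa)
    k_r = eyring_rate(barriers.G_r, ctx, kappa)
    return RateResult(
        k_f=k_f,
        k_r=k_r,
        kappa=kappa,
        G_f=barriers.G_f,
        G_r=barriers.G_r,
        K_eq=k_f / k_r,
    )


def kie_from_rates(k_H: float, k_D: float) -> float:
    """Kinetic isotope effect k_H/k_D."""
    if k_H <= 0 or k_D <= 0:
        raise ParameterError("rates must be positive")
    return k_H / k_D


def unbinding_competition(k_pt: float, k_unbind: float) -> float:
    """Fraction of wobble encounters that tautomerize before unbinding.

    Two-branch competition: proton transfer at k_pt vs escape of the
    mismatched nucleotide from the active site at k_unbind, both in the
    same units; the branching fraction is k_pt/(k_pt + k_unbind).
    """
    if k_pt < 0 or k_unbind < 0:
        raise ParameterError("rates must be non-negative")
    if k_pt == 0 and k_unbind == 0:
        raise UndefinedCompetitionError(
            "branching fraction undefined when both rates vanish"
        )
    return k_pt / (k_pt + k_unbind)
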