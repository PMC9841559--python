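"""Internal unit system: energies in eV, lengths in Å, times in fs.

Masses are carried in amu at the user interface and converted to the
internal mass unit eV·fs²/Å² so that kinetic energy p²/2μ comes out in eV
when momentum is expressed in eV·fs/Å.  In this system

    ħ = 0.6582119569 eV·fs      k_B = 8.617333262e-5 eV/K

which are the natural scales for proton motion on chemical potentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.constants as _const

#: reduced Planck constant, eV·fs
HBAR: float = _const.hbar / _const.e * 1e15
#: Planck constant, eV·fs
H_PLANCK: float = _const.h / _const.e * 1e15
#: Planck constant, eV·s (for rates reported in 1/s)
H_PLANCK_EV_S: float = _const.h / _const.e
#: Boltzmann constant, eV/K
KB: float = _const.k / _const.e
#: speed of light, cm/fs (for cm⁻¹ → fs⁻¹ conversions)
C_CM_FS: float = _const.c * 1e2 * 1e-15
#: 1 amu in the internal mass unit eV·fs²/Å²
AMU_INTERNAL: float = _const.atomic_mass / (_const.e * 1e-10)

#: isotope masses, amu
MASS_H_AMU: float = 1.00783
MASS_D_AMU: float = 2.01410

FS_PER_S: float = 1e15


def gamma_cm_to_fs(gamma_cm: float) -> float:
    """Convert an ohmic coupling quoted as a wavenumber to fs⁻¹.

    The coupling is treated as an angular frequency, γ[fs⁻¹] = 2π c γ[cm⁻¹],
    matching the convention in which γ is compared with vibrational
    frequencies of the surrounding solvent.
    """
    import math

    return 2.0 * math.pi * C_CM_FS * gamma_cm


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of the physical constants used by the dynamics and rate code."""

    hbar: float = HBAR
    h: float = H_PLANCK
    k_B: float = KB
    c_cm_fs: float = C_CM_FS
    amu_internal: float = AMU_INTERNAL

    def __post_init__(self) -> None:
        import math

        if abs(self.h - 2.0 * math.pi * self.hbar) > 1e-9 * self.h:
            raise ValueError("inconsistent unit system: h != 2*pi*hbar")


DEFAULT_UNITS = UnitSystem()
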