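"""Dissipative phase-space dynamics of a transferring proton.

The proton's state is a Wigner quasi-probability density W(q, p) evolved
under the high-temperature Caldeira–Leggett master equation

    ∂W/∂t = −(p/μ) ∂q W + ∂qV ∂pW − (ħ²/24) ∂q³V ∂p³W + …
            + γ ∂p(p W) + γ μ k_B T̃ ∂p²W ,

i.e. quantum Liouville streaming (the Moyal series of the potential term),
ohmic friction γ, and momentum diffusion set by the effective bath
temperature T̃.  The propagator is an operator-split scheme in which every
sub-step is applied exactly:

* free streaming is a spectral shift in q (exact advection);
* the potential term is a phase in the Fourier conjugate of momentum —
  truncating the phase at first/third order gives the classical
  (Klein–Kramers) and leading-quantum propagators, while the
  ``spectral-kernel`` scheme applies the full nonlocal Wigner potential
  kernel (V(q + ħy/2) − V(q − ħy/2))/ħ;
* friction + diffusion form an Ornstein–Uhlenbeck step applied through its
  exact Green's function (contraction in p followed by a Gaussian
  convolution).

Rates are extracted by preparing a thermal state in the reactant well and
monitoring the flux of density through the transition state; the plateau
of flux over surviving reactant population is the raw rate, and the ratio
of quantum to classical plateau rates is the tunnelling factor κ.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy.linalg import eigh_tridiagonal
from scipy.optimize import minimize_scalar

from .errors import (
    DivergenceError,
    DomainError,
    InvalidWellError,
    NonConvergenceError,
    NumericalError,
    ParameterError,
    StabilityError,
    UnderflowError,
)
from .pes import PESProfile, barrier_summary
from .units import (
    AMU_INTERNAL,
    HBAR,
    KB,
    MASS_D_AMU,
    MASS_H_AMU,
    gamma_cm_to_fs,
)

__all__ = [
    "ParticleSpec",
    "BathSpec",
    "PhaseSpaceGrid",
    "WignerState",
    "PropagatorConfig",
    "Propagator",
    "thermal_initial_state",
    "propagate",
    "transition_state_flux",
    "compute_rate",
    "kappa",
    "kie",
    "RateEstimate",
    "KappaResult",
    "KIEResult",
    "tst_rate",
    "wigner_tunnelling_correction",
    "harmonic_thermal_variances",
    "save_state",
    "load_state",
]


@dataclass(frozen=True)
class ParticleSpec:
    """Effective particle moving along the reaction coordinate."""

    mass_amu: float
    isotope: str = "H"

    def __post_init__(self):
        if self.mass_amu <= 0:
            raise ParameterError("particle mass must be positive")

    @property
    def mass(self) -> float:
        """Mass in internal units (eV·fs²/Å²)."""
        return self.mass_amu * AMU_INTERNAL

    @classmethod
    def hydrogen(cls) -> "ParticleSpec":
        return cls(MASS_H_AMU, "H")

    @classmethod
    def deuterium(cls) -> "ParticleSpec":
        return cls(MASS_D_AMU, "D")

    @classmethod
    def from_isotope(cls, isotope: str) -> "ParticleSpec":
        try:
            return {"H": cls.hydrogen, "D": cls.deuterium}[isotope]()
        except KeyError:
            raise ParameterError(f"unknown isotope {isotope!r}; use 'H' or 'D'")


@dataclass(frozen=True)
class BathSpec:
    """Ohmic bath: coupling γ quoted in cm⁻¹, effective temperature T̃ in K."""

    gamma_cm: float
    T_tilde: float
    spectral_form: str = "ohmic"

    def __post_init__(self):
        if self.gamma_cm < 0:
            raise ParameterError("bath coupling must be non-negative")
        if self.T_tilde <= 0:
            raise ParameterError("effective bath temperature must be positive")
        if self.spectral_form != "ohmic":
            raise ParameterError("only the ohmic spectral form is supported")

    @property
    def gamma_fs(self) -> float:
        return gamma_cm_to_fs(self.gamma_cm)


@dataclass(frozen=True)
class PhaseSpaceGrid:
    """Uniform (q, p) grid; q in Å, p in eV·fs/Å."""

    q: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        p = np.asarray(self.p, dtype=float)
        for name, arr in (("q", q), ("p", p)):
            if arr.ndim != 1 or arr.size < 32:
                raise ParameterError(f"{name} grid needs at least 32 points")
            d = np.diff(arr)
            if not np.allclose(d, d[0], rtol=1e-9, atol=0):
                raise ParameterError(f"{name} grid must be uniform")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "p", p)

    @property
    def dq(self) -> float:
        return float(self.q[1] - self.q[0])

    @property
    def dp(self) -> float:
        return float(self.p[1] - self.p[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.q.size, self.p.size

    @classmethod
    def for_profile(
        cls,
        profile: PESProfile,
        particle: ParticleSpec,
        T: float,
        n_q: int = 256,
        n_p: int = 256,
        p_sigmas: float = 6.0,
        pad_q: float = 0.4,
    ) -> "PhaseSpaceGrid":
        """Grid covering the profile domain (padded) and the thermal momenta."""
        lo, hi = profile.domain
        q = np.linspace(lo - pad_q, hi + pad_q, n_q)
        sigma_p = math.sqrt(particle.mass * KB * T)
        p_max = p_sigmas * sigma_p
        dp = 2.0 * p_max / n_p
        p = (np.arange(n_p) - n_p // 2) * dp
        return cls(q=q, p=p)


@dataclass
class WignerState:
    """Quasi-probability density on a phase-space grid at a given time."""

    W: np.ndarray
    grid: PhaseSpaceGrid
    time: float = 0.0

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.shape != self.grid.shape:
            raise ParameterError("W shape does not match the grid")
        self.W = W

    @property
    def _dqdp(self) -> float:
        return self.grid.dq * self.grid.dp

    def norm(self) -> float:
        return float(self.W.sum() * self._dqdp)

    def marginal_q(self) -> np.ndarray:
        return self.W.sum(axis=1) * self.grid.dp

    def marginal_p(self) -> np.ndarray:
        return self.W.sum(axis=0) * self.grid.dq

    def mean_q(self) -> float:
        return float((self.marginal_q() * self.grid.q).sum() * self.grid.dq / self.norm())

    def mean_p(self) -> float:
        return float((self.marginal_p() * self.grid.p).sum() * self.grid.dp / self.norm())

    def var_p(self) -> float:
        mp = self.marginal_p()
        n = mp.sum() * self.grid.dp
        mean = (mp * self.grid.p).sum() * self.grid.dp / n
        return float((mp * (self.grid.p - mean) ** 2).sum() * self.grid.dp / n)

    def var_q(self) -> float:
        mq = self.marginal_q()
        n = mq.sum() * self.grid.dq
        mean = (mq * self.grid.q).sum() * self.grid.dq / n
        return float((mq * (self.grid.q - mean) ** 2).sum() * self.grid.dq / n)

    def normalized(self) -> "WignerState":
        return WignerState(self.W / self.norm(), self.grid, self.time)

    def copy(self) -> "WignerState":
        return WignerState(self.W.copy(), self.grid, self.time)


_SCHEMES = ("moyal-truncated", "spectral-kernel")
_BOUNDARIES = ("absorbing", "reflecting")
_MODES = ("quantum", "classical")


@dataclass(frozen=True)
class PropagatorConfig:
    """Discretization and protocol settings for the phase-space propagator.

    ``mode='classical'`` forces the potential phase to first (classical)
    order regardless of ``moyal_order`` or ``scheme``, turning the solver
    into a Klein–Kramers integrator on the identical grid.  The default
    boundary treatment absorbs density on the product side (a sponge over
    the last ``n_absorb`` columns) and confines the reactant side with a
    smooth wall in the grid padding, which suppresses re-crossing artifacts
    in the measured flux.
    """

    dt: float = 0.25
    scheme: str = "moyal-truncated"
    moyal_order: int = 3
    boundary: str = "absorbing"
    max_time: float = 2500.0
    mode: str = "quantum"
    n_q: int = 256
    n_p: int = 256
    p_sigmas: float = 6.0
    pad_q: float = 1.0
    n_absorb: int = 24
    absorb_rate: float = 1.0  # peak damping rate of the sponges, 1/fs
    wall_height: float = 1.2
    sample_every: int = 4
    init_method: str = "eigen"
    plateau_slope_tol: float = 1e-3  # relative flux/population slope per 100 fs
    plateau_hold: float = 500.0  # fs the plateau criterion must be sustained
    transient_skip: float = 100.0  # fs ignored before plateau detection

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.scheme not in _SCHEMES:
            raise ParameterError(f"scheme must be one of {_SCHEMES}")
        if self.boundary not in _BOUNDARIES:
            raise ParameterError(f"boundary must be one of {_BOUNDARIES}")
        if self.mode not in _MODES:
            raise ParameterError(f"mode must be one of {_MODES}")
        if self.moyal_order not in (1, 3):
            raise ParameterError("moyal_order must be 1 (classical) or 3")

    @property
    def effective_order(self) -> int:
        return 1 if self.mode == "classical" else self.moyal_order


def _extended_potential(profile: PESProfile, config: PropagatorConfig):
    """V, V', V''' callables valid on the whole real line.

    Inside the image domain the spline is used; outside, a quadratic
    continuation matched to value/slope/curvature at the ends.  Confining
    walls (quadratic, reaching ``wall_height`` eV across the padding) are
    added in the pad region: always on the reactant (left) side, and on the
    product side too when the boundary is fully reflecting.
    """
    lo, hi = profile.domain
    pad = config.pad_q
    v_lo, g_lo, c_lo = (float(profile(lo, nu=n)) for n in (0, 1, 2))
    v_hi, g_hi, c_hi = (float(profile(hi, nu=n)) for n in (0, 1, 2))
    wall_left = config.wall_height if pad > 0 else 0.0
    wall_right = (
        config.wall_height if (pad > 0 and config.boundary == "reflecting") else 0.0
    )

    def V(x):
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        mask_in = (x >= lo) & (x <= hi)
        out[mask_in] = profile.spline(x[mask_in])
        dl = x[x < lo] - lo
        out[x < lo] = v_lo + g_lo * dl + 0.5 * c_lo * dl**2
        dr = x[x > hi] - hi
        out[x > hi] = v_hi + g_hi * dr + 0.5 * c_hi * dr**2
        if wall_left:
            dl_all = np.minimum(x - lo, 0.0)
            out += wall_left * (dl_all / pad) ** 2
        if wall_right:
            dr_all = np.maximum(x - hi, 0.0)
            out += wall_right * (dr_all / pad) ** 2
        return out

    dspl = profile.spline.derivative(1)
    d3spl = profile.spline.derivative(3)

    def dV(x):
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        mask_in = (x >= lo) & (x <= hi)
        out[mask_in] = dspl(x[mask_in])
        out[x < lo] = g_lo + c_lo * (x[x < lo] - lo)
        out[x > hi] = g_hi + c_hi * (x[x > hi] - hi)
        if wall_left:
            out += 2.0 * wall_left * np.minimum(x - lo, 0.0) / pad**2
        if wall_right:
            out += 2.0 * wall_right * np.maximum(x - hi, 0.0) / pad**2
        return out

    def d3V(x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        mask_in = (x >= lo) & (x <= hi)
        out[mask_in] = d3spl(x[mask_in])
        return out

    return V, dV, d3V


class Propagator:
    """Split-operator integrator for one (profile, particle, bath, config)."""

    def __init__(
        self,
        profile: PESProfile,
        particle: ParticleSpec,
        bath: BathSpec,
        config: PropagatorConfig,
        grid: PhaseSpaceGrid | None = None,
        T: float | None = None,
    ):
        self.profile = profile
        self.particle = particle
        self.bath = bath
        self.config = config
        if grid is None:
            grid = PhaseSpaceGrid.for_profile(
                profile,
                particle,
                max(T if T is not None else bath.T_tilde, bath.T_tilde),
                n_q=config.n_q,
                n_p=config.n_p,
                p_sigmas=config.p_sigmas,
                pad_q=config.pad_q,
            )
        self.grid = grid
        self._build()

    def _build(self):
        cfg = self.config
        grid = self.grid
        mu = self.particle.mass
        dt = cfg.dt
        q, p = grid.q, grid.p
        Vf, dVf, d3Vf = _extended_potential(self.profile, cfg)
        self.extended_V = Vf
        self.V_grid = Vf(q)
        dV = dVf(q)
        d3V = d3Vf(q)

        # stability: per-substep characteristic shifts must stay well inside
        # the grid, otherwise the spectral advection aliases (CFL analogue)
        q_span = q[-1] - q[0]
        p_span = p[-1] - p[0]
        if dt * np.abs(p).max() / mu > q_span / 4.0:
            raise StabilityError(
                "dt too large: free-streaming shift exceeds a quarter of the q grid"
            )
        if dt * np.abs(dV).max() > p_span / 4.0:
            raise StabilityError(
                "dt too large: potential kick exceeds a quarter of the p grid"
            )
        gamma = self.bath.gamma_fs
        if gamma * dt > 0.5:
            raise StabilityError("dt too large for the bath coupling (gamma*dt > 0.5)")

        # exact free streaming: shift phase in the q-Fourier domain.  A weak
        # exponential spectral filter rides on the top third of the modes:
        # phase-space dynamics generates ever finer filaments (turning
        # points, barrier shear) and unfiltered Nyquist-scale content would
        # make the spectral shift ring globally, violating local continuity
        # of the flux.  The filter is unity at k = 0, so mass is conserved.
        k = 2.0 * np.pi * sfft.fftfreq(q.size, grid.dq)
        filt_q = np.exp(-36.0 * (np.abs(k) / np.abs(k).max()) ** 16)
        self._stream_half = (
            np.exp(-1j * np.outer(k, p / mu) * (dt / 2.0)) * filt_q[:, None]
        )

        # potential term: phase in the p-Fourier (y) domain (same weak
        # anti-aliasing filter along p)
        y = 2.0 * np.pi * sfft.fftfreq(p.size, grid.dp)
        self._filt_p = np.exp(-36.0 * (np.abs(y) / np.abs(y).max()) ** 16)[None, :]
        if cfg.scheme == "spectral-kernel" and cfg.mode == "quantum":
            shift = 0.5 * HBAR * y
            phi = (Vf(q[:, None] + shift[None, :]) - Vf(q[:, None] - shift[None, :])) / HBAR
        else:
            phi = dV[:, None] * y[None, :]
            if cfg.effective_order >= 3:
                phi = phi + (HBAR**2 / 24.0) * d3V[:, None] * y[None, :] ** 3
        self._pot_half = np.exp(1j * phi * (dt / 2.0))

        # exact Ornstein-Uhlenbeck step: contraction + Gaussian convolution
        self._gamma = gamma
        if gamma > 0.0:
            f = math.exp(gamma * dt)
            idx = (p * f - p[0]) / grid.dp
            C = np.zeros((p.size, p.size))
            base = np.floor(idx).astype(int)
            frac = idx - base
            # 4-point cubic Lagrange interpolation weights
            t = frac
            w = np.stack(
                [
                    -t * (t - 1.0) * (t - 2.0) / 6.0,
                    (t + 1.0) * (t - 1.0) * (t - 2.0) / 2.0,
                    -(t + 1.0) * t * (t - 2.0) / 2.0,
                    (t + 1.0) * t * (t - 1.0) / 6.0,
                ],
                axis=0,
            )
            for off in range(4):
                src = base - 1 + off
                ok = (src >= 0) & (src < p.size)
                C[np.arange(p.size)[ok], src[ok]] = w[off][ok] * f
            # column-normalize so the contraction conserves mass exactly
            # (edge truncation would otherwise leak ~0.1% per ps)
            col = C.sum(axis=0)
            good = col > 0.5
            C[:, good] /= col[good]
            self._contract_T = C.T.copy()
            sigma2 = self.particle.mass * KB * self.bath.T_tilde * (
                1.0 - math.exp(-2.0 * gamma * dt)
            )
            self._gauss_y = np.exp(-0.5 * sigma2 * y**2)
        else:
            self._contract_T = None
            self._gauss_y = None

        # absorbing sponges: gentle exponential damping with a smooth onset,
        # so the absorber itself does not create sharp features the spectral
        # streaming would ring on.  The product-side sponge collects the
        # reacted density; a second sponge hides deep inside the reactant
        # wall — only where the wall already exceeds 75% of its full height,
        # so the physical density there is ~exp(-0.75 beta V_wall) — and
        # removes grid-scale debris before it can wrap around the periodic
        # q boundary.
        if cfg.boundary == "absorbing" and cfg.n_absorb > 0:
            n = cfg.n_absorb
            x = np.arange(1, n + 1) / n
            ramp = (x * x * (3.0 - 2.0 * x)) ** 2
            eta = np.zeros(q.size)
            eta[-n:] = cfg.absorb_rate * ramp
            lo_prof = self.profile.domain[0]
            deep = (q < lo_prof) & (self.V_grid >= 0.75 * cfg.wall_height)
            n_left = int(np.count_nonzero(deep))
            if n_left >= 2:
                xl = np.arange(1, n_left + 1) / n_left
                eta[:n_left] += cfg.absorb_rate * (
                    xl * xl * (3.0 - 2.0 * xl)
                )[::-1] ** 2
            self._mask = np.exp(-dt * eta)[:, None]
        else:
            self._mask = None

    def step(self, W: np.ndarray) -> np.ndarray:
        """Advance W by one time step (symmetric splitting, 2nd order)."""
        Wk = sfft.fft(W, axis=0)
        Wk *= self._stream_half
        W = sfft.ifft(Wk, axis=0).real

        Wy = sfft.fft(W, axis=1)
        Wy *= self._pot_half
        Wy *= self._filt_p
        W = sfft.ifft(Wy, axis=1).real

        if self._gamma > 0.0:
            W = W @ self._contract_T

        Wy = sfft.fft(W, axis=1)
        Wy *= self._pot_half
        Wy *= self._filt_p
        if self._gauss_y is not None:
            Wy *= self._gauss_y
        W = sfft.ifft(Wy, axis=1).real

        Wk = sfft.fft(W, axis=0)
        Wk *= self._stream_half
        W = sfft.ifft(Wk, axis=0).real

        if self._mask is not None:
            W = W * self._mask
        return W

    def run(
        self,
        state: WignerState,
        duration: float,
        callback=None,
        sample_every: int | None = None,
    ) -> WignerState:
        """Propagate for ``duration`` fs; ``callback(step, t, W)`` is called
        at every sampling interval (and at the final step)."""
        cfg = self.config
        n_steps = max(1, int(round(duration / cfg.dt)))
        every = sample_every if sample_every is not None else cfg.sample_every
        W = state.W.copy()
        t0 = state.time
        for istep in range(1, n_steps + 1):
            W = self.step(W)
            if istep % every == 0 or istep == n_steps:
                if not np.all(np.isfinite(W)):
                    raise DivergenceError("NaN/Inf in Wigner density", step=istep)
                if callback is not None:
                    callback(istep, t0 + istep * cfg.dt, W)
        return WignerState(W, self.grid, t0 + n_steps * cfg.dt)


def propagate(
    state: WignerState,
    profile: PESProfile,
    particle: ParticleSpec,
    bath: BathSpec,
    config: PropagatorConfig,
    duration: float,
    log_file=None,
    s_div: float | None = None,
) -> WignerState:
    """Functional front end: evolve ``state`` for ``duration`` fs.

    When ``log_file`` is given, line-oriented records
    (t, norm, <q>, <p>, flux) are appended at each sampling interval; the
    flux column requires ``s_div`` and is blank otherwise.
    """
    prop = Propagator(profile, particle, bath, config, grid=state.grid)
    callback = None
    fh = None
    if log_file is not None:
        fh = open(log_file, "w")
        fh.write("t_fs\tnorm\tmean_q\tmean_p\tflux\n")
        dqdp = state.grid.dq * state.grid.dp

        def callback(istep, t, W):
            st = WignerState(W, state.grid, t)
            flux = (
                f"{transition_state_flux(st, particle, s_div):.8e}"
                if s_div is not None
                else ""
            )
            fh.write(
                f"{t:.4f}\t{W.sum() * dqdp:.10f}\t{st.mean_q():.6f}\t"
                f"{st.mean_p():.6f}\t{flux}\n"
            )

    try:
        out = prop.run(state, duration, callback=callback)
    finally:
        if fh is not None:
            fh.close()
    return out


def transition_state_flux(
    state: WignerState, particle: ParticleSpec, s_div: float
) -> float:
    """Net probability flux J(s_div) = ∫ (p/μ) W(s_div, p) dp in 1/fs."""
    q = state.grid.q
    if not (q[0] <= s_div <= q[-1]):
        raise DomainError(f"dividing surface {s_div:g} outside the q grid")
    x = (s_div - q[0]) / state.grid.dq
    i = min(int(x), q.size - 2)
    w = x - i
    W_div = (1.0 - w) * state.W[i] + w * state.W[i + 1]
    return float((state.grid.p / particle.mass * W_div).sum() * state.grid.dp)


# ---------------------------------------------------------------------------
# thermal initial states


def _well_minimum_of(potential, a: float, b: float):
    """Locate the minimum of a potential callable on [a, b]."""
    s = np.linspace(a, b, 2001)
    e = np.asarray(potential(s), dtype=float)
    i = int(np.argmin(e))
    if i == 0 or i == s.size - 1:
        return float(s[i]), float(e[i]), False
    res = minimize_scalar(
        lambda x: float(potential(np.asarray([x]))[0]),
        bounds=(s[max(i - 2, 0)], s[min(i + 2, s.size - 1)]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(res.fun), True


def harmonic_thermal_variances(
    omega: float, particle: ParticleSpec, T: float, quantum: bool = True
) -> tuple[float, float]:
    """Closed-form thermal (Wigner) variances in a harmonic well.

    Returns (var_q, var_p) with the quantum-corrected effective temperature
    T_eff = (ħω/2k_B)·coth(ħω/2k_B T); the classical limit replaces T_eff by T.
    """
    if quantum:
        x = HBAR * omega / (2.0 * KB * T)
        T_eff = (HBAR * omega / (2.0 * KB)) / math.tanh(x)
    else:
        T_eff = T
    var_q = KB * T_eff / (particle.mass * omega**2)
    var_p = particle.mass * KB * T_eff
    return var_q, var_p


def thermal_initial_state(
    profile: PESProfile,
    well: tuple[float, float],
    particle: ParticleSpec,
    T: float,
    method: str = "eigen",
    grid: PhaseSpaceGrid | None = None,
    mode: str = "quantum",
    n_states: int = 32,
    potential=None,
) -> WignerState:
    """Normalized thermal Wigner state localized in the reactant well.

    method='eigen': Boltzmann-weighted Wigner transforms of the lowest
    eigenstates of the well-restricted 1-D Hamiltonian (finite-difference
    diagonalization with hard walls at the window edges).  Works for wells
    of any shape, including flat-bottomed ones.

    method='gaussian': thermal Gaussian from the harmonic approximation at
    the well minimum, with quantum-corrected widths (mode='quantum') or the
    plain Boltzmann widths (mode='classical').  Requires a strict interior
    minimum with positive curvature.

    ``potential`` optionally overrides the profile with a callable V(q)
    valid on the whole well window — used internally so the state is built
    on the same extended potential (confining wall included) that the
    propagator integrates, letting the eigenstates decay naturally into the
    wall instead of kinking at an artificial hard edge.
    """
    a, b = well
    if potential is None:
        lo, hi = profile.domain
        if not (lo - 1e-9 <= a < b <= hi + 1e-9):
            raise InvalidWellError(
                f"well window [{a:g}, {b:g}] outside profile domain"
            )
        potential = profile
    elif not a < b:
        raise InvalidWellError("well window must satisfy a < b")
    if grid is None:
        grid = PhaseSpaceGrid.for_profile(profile, particle, T)
    mu = particle.mass
    beta = 1.0 / (KB * T)

    if method == "gaussian":
        q0, e0, interior = _well_minimum_of(potential, a, b)
        if not interior:
            raise InvalidWellError("no interior minimum in the well window")
        if isinstance(potential, PESProfile):
            curv = float(potential(q0, nu=2))
        else:
            h = 1e-4 * (b - a)
            v = np.asarray(potential(np.array([q0 - h, q0, q0 + h])), dtype=float)
            curv = float((v[0] - 2.0 * v[1] + v[2]) / h**2)
        if curv <= 1e-8:
            raise InvalidWellError("well curvature non-positive at the minimum")
        omega = math.sqrt(curv / mu)
        var_q, var_p = harmonic_thermal_variances(
            omega, particle, T, quantum=(mode == "quantum")
        )
        Q, P = np.meshgrid(grid.q, grid.p, indexing="ij")
        W = np.exp(-0.5 * (Q - q0) ** 2 / var_q - 0.5 * P**2 / var_p)
    elif method == "eigen":
        m = 1024
        x = np.linspace(a, b, m)
        dx = x[1] - x[0]
        Vw = np.asarray(potential(x), dtype=float)
        kin = HBAR**2 / (2.0 * mu * dx**2)
        diag = 2.0 * kin + Vw
        off = np.full(m - 1, -kin)
        k = min(max(n_states, 4), m - 2)
        while True:
            try:
                evals, evecs = eigh_tridiagonal(
                    diag, off, select="i", select_range=(0, k - 1)
                )
            except Exception as exc:
                raise NumericalError(f"well eigensolver failed: {exc}") from exc
            if k >= m - 2 or beta * (evals[-1] - evals[0]) > 25.0:
                break
            k = min(2 * k, m - 2)
        weights = np.exp(-beta * (evals - evals[0]))
        weights /= weights.sum()
        psi = evecs / math.sqrt(dx)  # L2-normalized on the window
        # Wigner transform: W(q,p) = (1/πħ) ∫ ρ(q+y, q−y) cos(2py/ħ) dy
        y_max = b - a
        n_y = max(256, int(math.ceil(8.0 * np.abs(grid.p).max() * y_max / (math.pi * HBAR))))
        y = np.linspace(0.0, y_max, n_y)
        dy = y[1] - y[0]
        F = np.zeros((grid.q.size, n_y))
        qg = grid.q
        for n in range(k):
            if weights[n] < 1e-10:
                continue
            plus = np.interp(qg[:, None] + y[None, :], x, psi[:, n], left=0.0, right=0.0)
            minus = np.interp(qg[:, None] - y[None, :], x, psi[:, n], left=0.0, right=0.0)
            F += weights[n] * plus * minus
        trap = np.full(n_y, dy)
        trap[0] *= 0.5
        trap[-1] *= 0.5
        cosmat = np.cos(2.0 * np.outer(y, grid.p) / HBAR)
        W = (2.0 / (math.pi * HBAR)) * (F * trap[None, :]) @ cosmat
    else:
        raise ParameterError("method must be 'eigen' or 'gaussian'")

    state = WignerState(W, grid, 0.0)
    n = state.norm()
    if not np.isfinite(n) or n <= 0:
        raise NumericalError("thermal state construction produced a non-normalizable W")
    return state.normalized()


# ---------------------------------------------------------------------------
# rate extraction


@dataclass
class RateEstimate:
    """Raw dynamical rate from transition-state flux over population."""

    k_raw: float  # plateau of J/N, 1/fs
    k_expfit: float  # exponential-decay fit of N(t) over the same window, 1/fs
    mode: str
    s_div: float
    times: np.ndarray
    flux: np.ndarray
    population: np.ndarray
    norm: np.ndarray
    plateau: tuple[float, float]
    converged: bool


_K_FLOOR = 1e-25  # 1/fs; below this the flux signal is numerically meaningless


def compute_rate(
    profile: PESProfile,
    particle: ParticleSpec,
    bath: BathSpec,
    config: PropagatorConfig,
    T: float,
    initial_state: WignerState | None = None,
    s_div: float | None = None,
    well: tuple[float, float] | None = None,
) -> RateEstimate:
    """Raw barrier-crossing rate from the flux-over-population plateau.

    A thermal state is prepared in the reactant well, propagated under the
    configured mode, and the running ratio k(t) = J(s_div, t)/N_reactant(t)
    is monitored.  The rate is the mean of k over the first window of
    length ``plateau_hold`` in which the relative slope of k stays below
    ``plateau_slope_tol`` per 100 fs.  The reactant-population decay over
    the same window provides an independent exponential-fit rate.
    """
    bs = barrier_summary(profile)
    if s_div is None:
        s_div = bs.s_TS
    if initial_state is None:
        grid = PhaseSpaceGrid.for_profile(
            profile,
            particle,
            max(T, bath.T_tilde),
            n_q=config.n_q,
            n_p=config.n_p,
            p_sigmas=config.p_sigmas,
            pad_q=config.pad_q,
        )
        prop = Propagator(profile, particle, bath, config, grid=grid)
        # the state is built on the propagator's own extended potential
        # (confining wall included) so it is already near-stationary in the
        # well and decays smoothly into the wall region
        if well is None:
            well = (float(grid.q[0]), bs.s_TS)
        initial_state = thermal_initial_state(
            profile,
            well,
            particle,
            T,
            method=config.init_method,
            grid=grid,
            potential=prop.extended_V,
        )
    else:
        grid = initial_state.grid
        prop = Propagator(profile, particle, bath, config, grid=grid)
    dqdp = grid.dq * grid.dp
    reactant_cols = grid.q < s_div
    pvec = grid.p / particle.mass * grid.dp
    x_div = (s_div - grid.q[0]) / grid.dq
    i_div = min(int(x_div), grid.q.size - 2)
    w_div = x_div - i_div

    times: list[float] = []
    fluxes: list[float] = []
    pops: list[float] = []
    norms: list[float] = []
    result: dict = {}

    def record(istep, t, W):
        Wd = (1.0 - w_div) * W[i_div] + w_div * W[i_div + 1]
        times.append(t)
        fluxes.append(float((pvec * Wd).sum()))
        pops.append(float(W[reactant_cols].sum() * dqdp))
        norms.append(float(W.sum() * dqdp))

    def plateau_window():
        t = np.asarray(times)
        if t.size < 8 or t[-1] < config.transient_skip + config.plateau_hold:
            return None
        sel = t >= t[-1] - config.plateau_hold
        if t[sel][0] < config.transient_skip:
            return None
        kk = np.asarray(fluxes)[sel] / np.maximum(np.asarray(pops)[sel], 1e-300)
        kmean = kk.mean()
        if not np.isfinite(kmean) or kmean <= 0:
            return None
        slope = np.polyfit(t[sel], kk, 1)[0]
        if abs(slope) * 100.0 / kmean <= config.plateau_slope_tol:
            return sel, kmean
        return None

    chunk = config.dt * config.sample_every * 20
    state = initial_state
    converged = None
    while state.time < config.max_time and converged is None:
        dur = min(chunk, config.max_time - state.time)
        state = prop.run(state, dur, callback=record)
        converged = plateau_window()

    t_arr = np.asarray(times)
    f_arr = np.asarray(fluxes)
    n_arr = np.asarray(pops)
    nrm_arr = np.asarray(norms)
    if converged is None:
        partial = RateEstimate(
            k_raw=float("nan"),
            k_expfit=float("nan"),
            mode=config.mode,
            s_div=s_div,
            times=t_arr,
            flux=f_arr,
            population=n_arr,
            norm=nrm_arr,
            plateau=(float("nan"), float("nan")),
            converged=False,
        )
        raise NonConvergenceError(
            f"no rate plateau within {config.max_time:g} fs "
            f"(slope tolerance {config.plateau_slope_tol:g}/100 fs over "
            f"{config.plateau_hold:g} fs)",
            partial=partial,
        )
    sel, k_raw = converged
    if k_raw < _K_FLOOR:
        raise UnderflowError(
            f"plateau rate {k_raw:.3e}/fs is below the measurable floor; "
            "use the analytic transition-state estimate instead"
        )
    # independent cross-check: exponential decay of the reactant population
    lnN = np.log(np.maximum(n_arr[sel], 1e-300))
    k_expfit = -float(np.polyfit(t_arr[sel], lnN, 1)[0])
    return RateEstimate(
        k_raw=float(k_raw),
        k_expfit=k_expfit,
        mode=config.mode,
        s_div=s_div,
        times=t_arr,
        flux=f_arr,
        population=n_arr,
        norm=nrm_arr,
        plateau=(float(t_arr[sel][0]), float(t_arr[sel][-1])),
        converged=True,
    )


@dataclass
class KappaResult:
    """Tunnelling factor κ = quantum/classical plateau rate."""

    kappa: float
    quantum: RateEstimate
    classical: RateEstimate


def kappa(
    profile: PESProfile,
    particle: ParticleSpec,
    bath: BathSpec,
    config: PropagatorConfig,
    T: float,
) -> KappaResult:
    """Quantum-to-classical rate ratio on identical grids and initial states.

    The same thermal state (quantum preparation) seeds both propagations so
    the ratio isolates the dynamical quantum contribution; the bath drives
    each mode to its own quasi-stationary flux.
    """
    bs = barrier_summary(profile)
    grid = PhaseSpaceGrid.for_profile(
        profile,
        particle,
        max(T, bath.T_tilde),
        n_q=config.n_q,
        n_p=config.n_p,
        p_sigmas=config.p_sigmas,
        pad_q=config.pad_q,
    )
    cfg_q = dataclasses.replace(config, mode="quantum")
    cfg_c = dataclasses.replace(config, mode="classical")
    # shared preparation on the shared extended potential (V is identical in
    # both modes)
    prop_V = Propagator(profile, particle, bath, cfg_q, grid=grid).extended_V
    state = thermal_initial_state(
        profile,
        (float(grid.q[0]), bs.s_TS),
        particle,
        T,
        method=config.init_method,
        grid=grid,
        potential=prop_V,
    )
    rq = compute_rate(profile, particle, bath, cfg_q, T, initial_state=state.copy())
    rc = compute_rate(profile, particle, bath, cfg_c, T, initial_state=state.copy())
    return KappaResult(kappa=rq.k_raw / rc.k_raw, quantum=rq, classical=rc)


@dataclass
class KIEResult:
    """Kinetic isotope effect k(H)/k(D) with its tunnelling components."""

    kie: float
    basis: str
    kappa_H: KappaResult
    kappa_D: KappaResult
    k_H: float
    k_D: float


def kie(
    profile: PESProfile,
    bath: BathSpec,
    config: PropagatorConfig,
    T: float,
    f_forward: float = 0.0,
    f_reverse: float = 0.0,
    basis: str = "eyring",
) -> KIEResult:
    """KIE from deuterium substitution; only the effective mass changes.

    basis='eyring': forward rates are κ-corrected Eyring rates built from
    the profile's (optionally free-energy-corrected) forward barrier, so the
    KIE reduces to κ(H)/κ(D).  basis='raw' compares the raw dynamical
    quantum rates directly.
    """
    from .pes import apply_free_energy_correction
    from .rates import ThermoContext, eyring_rate

    if basis not in ("eyring", "raw"):
        raise ParameterError("basis must be 'eyring' or 'raw'")
    kH = kappa(profile, ParticleSpec.hydrogen(), bath, config, T)
    kD = kappa(profile, ParticleSpec.deuterium(), bath, config, T)
    if basis == "eyring":
        bs = barrier_summary(profile)
        G = apply_free_energy_correction(bs, f_forward, f_reverse)
        ctx = ThermoContext(T)
        k_H = eyring_rate(G.G_f, ctx, kappa=kH.kappa)
        k_D = eyring_rate(G.G_f, ctx, kappa=kD.kappa)
    else:
        k_H = kH.quantum.k_raw
        k_D = kD.quantum.k_raw
    return KIEResult(
        kie=k_H / k_D, basis=basis, kappa_H=kH, kappa_D=kD, k_H=k_H, k_D=k_D
    )


# ---------------------------------------------------------------------------
# closed-form oracles


def tst_rate(
    profile: PESProfile,
    particle: ParticleSpec,
    T: float,
    bath: BathSpec | None = None,
) -> float:
    """Classical transition-state/Kramers rate in 1/fs.

    k = F · sqrt(1/(2πβμ)) · exp(−βE_TS) / ∫_reactant exp(−βV) dq, with the
    reactant integral over [domain start, s_TS].  When a bath is supplied
    and the barrier top has negative curvature, the Kramers
    spatial-diffusion factor F = sqrt(1 + (γ/2ω_b)²) − γ/2ω_b is applied.
    """
    bs = barrier_summary(profile)
    beta = 1.0 / (KB * T)
    mu = particle.mass
    lo, _ = profile.domain
    sgrid = np.linspace(lo, bs.s_TS, 4001)
    Z = np.trapezoid(np.exp(-beta * profile(sgrid)), sgrid)
    e_top = float(profile(bs.s_TS))
    k = math.sqrt(1.0 / (2.0 * math.pi * beta * mu)) * math.exp(-beta * e_top) / Z
    if bath is not None and bath.gamma_fs > 0:
        curv = float(profile(bs.s_TS, nu=2))
        if curv < 0:
            omega_b = math.sqrt(-curv / mu)
            r = bath.gamma_fs / (2.0 * omega_b)
            k *= math.sqrt(1.0 + r**2) - r
    return k


def wigner_tunnelling_correction(
    profile: PESProfile, particle: ParticleSpec, T: float
) -> float:
    """High-temperature tunnelling factor 1 + (βħω‡)²/24 from the barrier curvature."""
    bs = barrier_summary(profile)
    curv = float(profile(bs.s_TS, nu=2))
    if curv >= 0:
        raise ParameterError("barrier top must have negative curvature")
    omega_b = math.sqrt(-curv / particle.mass)
    beta = 1.0 / (KB * T)
    return 1.0 + (beta * HBAR * omega_b) ** 2 / 24.0


# ---------------------------------------------------------------------------
# checkpoint / restore


def save_state(state: WignerState, file) -> None:
    """Checkpoint a Wigner state (arrays + JSON header) to an .npz file."""
    meta = json.dumps(
        {"time_fs": state.time, "units": "eV-Angstrom-fs", "layout": "W[q, p]"}
    )
    np.savez(file, W=state.W, q=state.grid.q, p=state.grid.p, meta=np.array(meta))


def load_state(file) -> WignerState:
    with np.load(file, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        grid = PhaseSpaceGrid(q=data["q"], p=data["p"])
        return WignerState(data["W"], grid, float(meta["time_fs"]))
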