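"""Synthetic reaction paths and trajectories with known ground truth.

Three fixture topologies emulate the morphologies of proton-transfer
minimum-energy paths:

* ``wobble-path`` — a long path with a flat collective-motion approach, a
  gentle pre-barrier rise (the compression penalty), a single asymmetric
  inner barrier, and a flat product region;
* ``trs-barrier`` — a short tunnelling-ready profile: one Eckart-type
  (sech²) barrier between flat flanks, optionally asymmetric;
* ``double-transfer`` — a compact profile with a small translation region,
  the main barrier, a post-TS shoulder (shallow intermediate), and a
  nearly thermoneutral product.

The barrier amplitude is calibrated numerically so the composed profile
reproduces the requested forward/reverse barriers essentially exactly; the
sech² core keeps the analytic Eckart transmission available for
validation.  Synthetic MD trajectories are Markov chains over state
template geometries (bound/TRS/unbound) with isotropic Gaussian coordinate
noise, returned together with the true state sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import SpecError
from .pes import Geometry, ReactionPath
from .trs import STATE_BOUND, STATE_TRS, STATE_UNBOUND, TrajectoryFrames

__all__ = [
    "FixturePESSpec",
    "SyntheticTrajectorySpec",
    "gen_fixture_pes",
    "gen_trajectory",
    "attach_linear_geometries",
    "write_trajectory",
    "write_reference",
]

_TOPOLOGIES = ("wobble-path", "trs-barrier", "double-transfer")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: C² monotone 0→1 on [0, 1]."""
    t = np.clip(x, 0.0, 1.0)
    return t**3 * (t * (6.0 * t - 15.0) + 10.0)


@dataclass(frozen=True)
class FixturePESSpec:
    """Parameters of a synthetic reaction-path profile.

    ``barrier_height``/``reverse_barrier`` are the target forward/reverse
    electronic barriers in eV, ``barrier_width`` the sech² length scale in
    Å, and the region lengths control the flat flanks; the pre-barrier rise
    models the energetic penalty of compressing into the tunnelling-ready
    geometry (wobble-path topology only).
    """

    topology: str = "wobble-path"
    barrier_height: float = 0.926
    reverse_barrier: float = 0.680
    barrier_width: float = 0.75
    pre_barrier_rise: float = 0.275
    region1_length: float = 4.0
    barrier_region_length: float = 3.5
    post_length: float = 2.0
    shoulder_fraction: float = 0.45  # double-transfer: shoulder height / E_f

    def __post_init__(self):
        if self.topology not in _TOPOLOGIES:
            raise SpecError(f"topology must be one of {_TOPOLOGIES}")
        if self.barrier_height <= 0 or self.reverse_barrier <= 0:
            raise SpecError("barrier heights must be positive")
        if self.barrier_width <= 0:
            raise SpecError("barrier width must be positive")
        if self.barrier_width * 3.0 > self.barrier_region_length + self.post_length:
            raise SpecError("barrier width too large for the requested domain")
        if not 0.0 <= self.pre_barrier_rise < self.barrier_height:
            raise SpecError("pre-barrier rise must lie in [0, barrier height)")

    @property
    def length(self) -> float:
        return self.region1_length + self.barrier_region_length + self.post_length

    @classmethod
    def wobble(cls, **kw) -> "FixturePESSpec":
        """Full mismatch-to-tautomer path (defaults: 0.926/0.680 eV barriers)."""
        return cls(topology="wobble-path", **kw)

    @classmethod
    def trs_barrier(
        cls,
        barrier_height: float = 0.25,
        reverse_barrier: float | None = None,
        barrier_width: float = 0.5,
        region1_length: float = 1.6,
        barrier_region_length: float = 2.2,
        post_length: float = 1.6,
    ) -> "FixturePESSpec":
        """Single Eckart-type inner barrier between flat flanks."""
        return cls(
            topology="trs-barrier",
            barrier_height=barrier_height,
            reverse_barrier=(
                barrier_height if reverse_barrier is None else reverse_barrier
            ),
            barrier_width=barrier_width,
            pre_barrier_rise=0.0,
            region1_length=region1_length,
            barrier_region_length=barrier_region_length,
            post_length=post_length,
        )

    @classmethod
    def double_transfer(
        cls,
        barrier_height: float = 0.356,
        asymmetry: float = 0.017,
        barrier_width: float = 0.28,
        **kw,
    ) -> "FixturePESSpec":
        """Compact double-proton-transfer profile (defaults: 0.356 eV, ΔE = 0.017)."""
        return cls(
            topology="double-transfer",
            barrier_height=barrier_height,
            reverse_barrier=barrier_height - asymmetry,
            barrier_width=barrier_width,
            pre_barrier_rise=0.0,
            region1_length=kw.pop("region1_length", 0.5),
            barrier_region_length=kw.pop("barrier_region_length", 1.9),
            post_length=kw.pop("post_length", 0.8),
            **kw,
        )


def _compose(spec: FixturePESSpec):
    """Return (E(s; A), calibration range) for the spec's topology."""
    L = spec.length
    delta_E = spec.barrier_height - spec.reverse_barrier  # product level
    if spec.topology == "wobble-path":
        r1 = spec.region1_length
        c = r1 + 0.5 * spec.barrier_region_length
        a = spec.barrier_width
        rise_lo, rise_hi = 0.25 * r1, 0.8 * r1
        step = delta_E - spec.pre_barrier_rise

        def E(s, A):
            s = np.asarray(s, dtype=float)
            out = spec.pre_barrier_rise * _smoothstep((s - rise_lo) / (rise_hi - rise_lo))
            out = out + step * _smoothstep((s - (c - a)) / (2.0 * a))
            out = out + A / np.cosh((s - c) / a) ** 2
            return out

    elif spec.topology == "trs-barrier":
        c = spec.region1_length + 0.5 * spec.barrier_region_length
        a = spec.barrier_width

        def E(s, A):
            s = np.asarray(s, dtype=float)
            out = delta_E * _smoothstep((s - (c - a)) / (2.0 * a))
            out = out + A / np.cosh((s - c) / a) ** 2
            return out

    else:  # double-transfer
        c1 = spec.region1_length + 0.6
        a1 = spec.barrier_width
        c2 = c1 + 1.0
        a2 = 0.2
        B = spec.shoulder_fraction * spec.barrier_height
        # product step overlaps the shoulder decay so the profile never dips
        # below the product plateau before reaching it
        step_lo = c2

        def E(s, A):
            s = np.asarray(s, dtype=float)
            out = A / np.cosh((s - c1) / a1) ** 2
            out = out + B / np.cosh((s - c2) / a2) ** 2
            out = out + delta_E * _smoothstep((s - step_lo) / 0.5)
            return out

    return E


def gen_fixture_pes(spec: FixturePESSpec, n_images: int = 201) -> ReactionPath:
    """Generate a reaction path whose barrier analysis reproduces the spec.

    The main barrier amplitude is calibrated by root finding so that the
    composed profile's maximum sits at ``barrier_height`` above the
    reactant minimum and the product plateau at
    ``barrier_height − reverse_barrier``; residual calibration error is
    below 1e-6 eV on the dense composition grid.
    """
    if n_images < 10:
        raise SpecError("at least 10 images are required")
    E = _compose(spec)
    L = spec.length
    dense = np.linspace(0.0, L, 20001)

    def overshoot(A):
        e = E(dense, A)
        return float(e.max() - e[0]) - spec.barrier_height

    try:
        A = brentq(overshoot, 0.05 * spec.barrier_height, 2.0 * spec.barrier_height,
                   xtol=1e-12)
    except ValueError as exc:
        raise SpecError(
            "could not calibrate the barrier amplitude for this spec"
        ) from exc
    s = np.linspace(0.0, L, n_images)
    return ReactionPath(s=s, energy=E(s, A), label=spec.topology)


def attach_linear_geometries(
    path: ReactionPath,
    n_atoms: int = 8,
    delta_per_image: float = 0.096,
    seed: int = 1234,
) -> ReactionPath:
    """Equip a path with synthetic geometries advancing uniformly in Δ.

    Every image is displaced rigidly along a fixed unit vector by
    ``delta_per_image`` Å relative to its predecessor, so the RMS distance
    between any two consecutive images equals ``delta_per_image`` exactly —
    mirroring how the spacing of real path images sets the
    tunnelling-ready threshold.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(-1.5, 1.5, size=(n_atoms, 3))
    elements = tuple(np.resize(["N", "C", "O", "H"], n_atoms))
    direction = np.array([1.0, 0.0, 0.0])
    geoms = tuple(
        Geometry(elements, base + i * delta_per_image * direction)
        for i in range(path.n_images)
    )
    return ReactionPath(
        s=path.s, energy=path.energy, geometries=geoms, label=path.label
    )


# ---------------------------------------------------------------------------
# synthetic trajectories


def _default_templates(n_atoms: int = 8):
    """Deterministic bound/TRS/unbound template geometries.

    Two four-atom 'bases' facing each other; the TRS template is the
    compressed arrangement, the bound (wobble-like) template is displaced
    by 0.5 Å RMS, and the unbound template is rigidly translated 3 Å away.
    """
    rng = np.random.default_rng(20221223)
    half = n_atoms // 2
    left = rng.uniform(-1.2, 1.2, size=(half, 3)) + np.array([-2.0, 0.0, 0.0])
    right = rng.uniform(-1.2, 1.2, size=(n_atoms - half, 3)) + np.array([2.0, 0.0, 0.0])
    trs = np.vstack([left, right])
    disp = rng.normal(size=(n_atoms, 3))
    disp *= 0.5 / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    bound = trs + disp
    unbound = trs + np.array([3.0, 0.0, 0.0])
    elements = tuple(np.resize(["N", "C", "O", "H"], n_atoms))
    return elements, {STATE_BOUND: bound, STATE_TRS: trs, STATE_UNBOUND: unbound}


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Markov-chain trajectory generator over state template geometries."""

    templates: dict
    elements: tuple[str, ...]
    transition: np.ndarray  # rows sum to 1, ordered as `states`
    states: tuple[str, ...]
    noise_sigma: float = 0.02
    n_frames: int = 100_000
    frame_interval_ps: float = 1.0
    seed: int = 0
    start: str | None = None  # None: draw from the stationary distribution

    def __post_init__(self):
        if self.start is not None and self.start not in self.states:
            raise SpecError(f"start state {self.start!r} not in {self.states}")
        P = np.asarray(self.transition, dtype=float)
        k = len(self.states)
        if P.shape != (k, k):
            raise SpecError("transition matrix shape must match the state list")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise SpecError("transition matrix rows must be non-negative and sum to 1")
        if self.noise_sigma < 0:
            raise SpecError("noise sigma must be non-negative")
        if self.n_frames < 1:
            raise SpecError("at least one frame is required")
        shapes = {np.asarray(self.templates[s]).shape for s in self.states}
        if len(shapes) != 1:
            raise SpecError("all state templates must share one atom count")
        object.__setattr__(self, "transition", P)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (left Perron eigenvector)."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    @classmethod
    def default(
        cls,
        n_frames: int = 100_000,
        seed: int = 0,
        p_trs: float = 0.01,
        p_unbound: float = 0.05,
        persistence: float = 0.9,
        noise_sigma: float = 0.02,
        frame_interval_ps: float = 1.0,
        n_atoms: int = 8,
    ) -> "SyntheticTrajectorySpec":
        """Chain with exact stationary occupancies (bound, TRS, unbound).

        P = ρ·I + (1−ρ)·1πᵀ has stationary distribution π for any
        persistence ρ ∈ [0, 1), so the generated occupancies are known in
        closed form.
        """
        if not 0.0 <= persistence < 1.0:
            raise SpecError("persistence must be in [0, 1)")
        pi = np.array([1.0 - p_trs - p_unbound, p_trs, p_unbound])
        if np.any(pi <= 0):
            raise SpecError("state probabilities must be positive and sum below 1")
        elements, templates = _default_templates(n_atoms)
        states = (STATE_BOUND, STATE_TRS, STATE_UNBOUND)
        P = persistence * np.eye(3) + (1.0 - persistence) * np.outer(np.ones(3), pi)
        return cls(
            templates=templates,
            elements=elements,
            transition=P,
            states=states,
            noise_sigma=noise_sigma,
            n_frames=n_frames,
            frame_interval_ps=frame_interval_ps,
            seed=seed,
        )


def gen_trajectory(
    spec: SyntheticTrajectorySpec,
) -> tuple[TrajectoryFrames, tuple[str, ...]]:
    """Sample the Markov chain and emit noisy frames plus true state labels.

    The initial state is drawn from the stationary distribution;
    reproducibility is exact for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.states)
    cum = np.cumsum(spec.transition, axis=1)
    u = rng.random(spec.n_frames)
    idx = np.empty(spec.n_frames, dtype=np.int64)
    if spec.start is not None:
        idx[0] = spec.states.index(spec.start)
    else:
        idx[0] = min(
            int(np.searchsorted(np.cumsum(spec.stationary()), u[0], side="right")),
            k - 1,
        )
    for i in range(1, spec.n_frames):
        j = int(np.searchsorted(cum[idx[i - 1]], u[i], side="right"))
        idx[i] = min(j, k - 1)
    tmpl = np.stack([np.asarray(spec.templates[s], dtype=float) for s in spec.states])
    coords = tmpl[idx]
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    labels = tuple(spec.states[i] for i in idx)
    traj = TrajectoryFrames(
        coords=coords,
        frame_interval_ps=spec.frame_interval_ps,
        elements=spec.elements,
    )
    return traj, labels


# ---------------------------------------------------------------------------
# writers (same dialects the readers consume)


def _memory_universe(coords: np.ndarray, elements):
    import MDAnalysis as mda

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.add_TopologyAttr("names", [str(e) for e in elements])
    u.add_TopologyAttr("elements", [str(e) for e in elements])
    u.load_new(coords.astype(np.float32), order="fac")
    return u


def write_trajectory(traj: TrajectoryFrames, file) -> None:
    """Write a multi-frame XYZ or PDB trajectory (format from extension)."""
    import warnings

    import MDAnalysis as mda

    elements = traj.elements or tuple("C" for _ in range(traj.n_atoms))
    u = _memory_universe(traj.coords, elements)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(file), n_atoms=traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_reference(coords: np.ndarray, elements, file) -> None:
    """Write a single-frame XYZ or PDB reference geometry."""
    import warnings

    import MDAnalysis as mda

    u = _memory_universe(coords, elements)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(file), n_atoms=u.atoms.n_atoms) as w:
            w.write(u.atoms)
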