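"""Tunnelling-ready-state occupancy analysis of MD trajectories.

The compressed "tunnelling-ready" state (TRS) of the mismatched base pair
is a reference geometry; each trajectory frame is scored by Δ, the
root-mean-square Cartesian distance of the selected atoms from that
reference.  Frames with Δ below a lower threshold (default 0.096 Å) count
as TRS/compressed, frames above an upper threshold (default 2.0 Å) as
unbound, everything else as bound.  From the labelled series the module
derives per-state occupancy fractions, the empirical cumulative likelihood
of Δ, and — assuming uniformly distributed compression events — the mean
waiting time between TRS visits, frame_interval / TRS_fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    MissingGeometryError,
    ParameterError,
    SelectionError,
)
from .pes import ReactionPath

__all__ = [
    "ReferenceGeometry",
    "TrajectoryFrames",
    "DeltaSeries",
    "OccupancyStats",
    "delta_metric",
    "compute_delta_series",
    "classify",
    "occupancy",
    "trs_cut_from_path",
    "load_reference",
    "load_trajectory",
    "write_delta_table",
]

TRS_CUT_DEFAULT = 0.096  # Å
UNBOUND_CUT_DEFAULT = 2.0  # Å

STATE_TRS = "TRS"
STATE_BOUND = "bound"
STATE_UNBOUND = "unbound"


@dataclass(frozen=True)
class ReferenceGeometry:
    """Reference structure and the atom selection entering Δ."""

    elements: tuple[str, ...]
    coords: np.ndarray
    selection: tuple[int, ...] | None = None  # 0-based indices; None = all atoms
    label: str = "TRS"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ParameterError("reference coordinates must have shape (n, 3)")
        if not np.all(np.isfinite(coords)):
            raise ParameterError("reference coordinates must be finite")
        sel = self.selection
        if sel is not None:
            sel = tuple(int(i) for i in sel)
            if any(i < 0 or i >= coords.shape[0] for i in sel):
                raise SelectionError("selection index outside the reference atom set")
            object.__setattr__(self, "selection", sel)
        n_sel = len(sel) if sel is not None else coords.shape[0]
        if n_sel < 2:
            raise SelectionError("at least 2 atoms must enter the Δ metric")
        object.__setattr__(self, "coords", coords)

    @property
    def selected_coords(self) -> np.ndarray:
        if self.selection is None:
            return self.coords
        return self.coords[list(self.selection)]


@dataclass(frozen=True)
class TrajectoryFrames:
    """Per-frame coordinates (n_frames, n_atoms, 3) in Å at a fixed interval."""

    coords: np.ndarray
    frame_interval_ps: float
    elements: tuple[str, ...] | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ParameterError("trajectory coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise EmptyInputError("trajectory contains no frames")
        if self.frame_interval_ps <= 0:
            raise ParameterError("frame interval must be positive")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])


def _superpose(ref: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``."""
    from scipy.spatial.transform import Rotation

    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + ref.mean(axis=0)


def delta_metric(
    frame_coords: np.ndarray, ref: ReferenceGeometry, align: bool = False
) -> float:
    """Δ = RMS Cartesian distance of the selected atoms from the reference.

    With ``align`` the optimal rigid rotation+translation is removed first
    (RMSD after superposition); the default is the raw deviation in the
    laboratory/insertion-site frame.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    if frame_coords.ndim != 2 or frame_coords.shape[1] != 3:
        raise SelectionError("frame coordinates must have shape (n, 3)")
    if frame_coords.shape[0] != ref.coords.shape[0]:
        raise SelectionError(
            f"frame has {frame_coords.shape[0]} atoms, reference "
            f"{ref.coords.shape[0]}"
        )
    sel = list(ref.selection) if ref.selection is not None else slice(None)
    a = ref.coords[sel]
    b = frame_coords[sel]
    if align:
        b = _superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((b - a) ** 2, axis=1))))


@dataclass(frozen=True)
class DeltaSeries:
    """Per-frame Δ values with thresholds and (optionally) state labels."""

    delta: np.ndarray
    frame_interval_ps: float
    trs_cut: float = TRS_CUT_DEFAULT
    unbound_cut: float = UNBOUND_CUT_DEFAULT
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        d = np.asarray(self.delta, dtype=float)
        if d.ndim != 1:
            raise ParameterError("delta series must be 1-D")
        if d.size == 0:
            raise EmptyInputError("empty delta series")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ParameterError("Δ values must be finite and non-negative")
        if not 0.0 < self.trs_cut < self.unbound_cut:
            raise ParameterError("thresholds must satisfy 0 < trs_cut < unbound_cut")
        if self.frame_interval_ps <= 0:
            raise ParameterError("frame interval must be positive")
        object.__setattr__(self, "delta", d)

    @property
    def n_frames(self) -> int:
        return int(self.delta.size)


def compute_delta_series(
    traj: TrajectoryFrames,
    ref: ReferenceGeometry,
    align: bool = False,
    trs_cut: float = TRS_CUT_DEFAULT,
    unbound_cut: float = UNBOUND_CUT_DEFAULT,
) -> DeltaSeries:
    """Score every frame against the reference and classify the series."""
    if traj.n_atoms != ref.coords.shape[0]:
        raise SelectionError(
            f"trajectory has {traj.n_atoms} atoms, reference {ref.coords.shape[0]}"
        )
    deltas = np.array(
        [delta_metric(f, ref, align=align) for f in traj.coords], dtype=float
    )
    series = DeltaSeries(
        delta=deltas,
        frame_interval_ps=traj.frame_interval_ps,
        trs_cut=trs_cut,
        unbound_cut=unbound_cut,
    )
    return classify(series)


def classify(
    series: DeltaSeries,
    trs_cut: float | None = None,
    unbound_cut: float | None = None,
) -> DeltaSeries:
    """Attach state labels: Δ < trs_cut → TRS, Δ > unbound_cut → unbound.

    Both inequalities are strict, so a frame exactly at a threshold falls
    into the middle (bound) class.
    """
    trs_cut = series.trs_cut if trs_cut is None else trs_cut
    unbound_cut = series.unbound_cut if unbound_cut is None else unbound_cut
    if not 0.0 < trs_cut < unbound_cut:
        raise ParameterError("thresholds must satisfy 0 < trs_cut < unbound_cut")
    d = series.delta
    labels = np.full(d.size, STATE_BOUND, dtype=object)
    labels[d < trs_cut] = STATE_TRS
    labels[d > unbound_cut] = STATE_UNBOUND
    return DeltaSeries(
        delta=d,
        frame_interval_ps=series.frame_interval_ps,
        trs_cut=trs_cut,
        unbound_cut=unbound_cut,
        labels=tuple(labels),
    )


@dataclass(frozen=True)
class OccupancyStats:
    """Per-state occupancy, waiting time, and the cumulative Δ likelihood."""

    fractions: dict
    mean_waiting_time_ps: float | None  # None when no TRS frame was seen
    delta_sorted: np.ndarray
    n_frames: int
    frame_interval_ps: float

    def cumulative_likelihood(self, x) -> np.ndarray | float:
        """P(Δ ≤ x): empirical cumulative distribution of the series."""
        idx = np.searchsorted(self.delta_sorted, np.asarray(x, dtype=float), side="right")
        out = idx / self.n_frames
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "fractions": dict(self.fractions),
            "mean_waiting_time_ps": self.mean_waiting_time_ps,
            "waiting_time_defined": self.mean_waiting_time_ps is not None,
            "n_frames": self.n_frames,
            "frame_interval_ps": self.frame_interval_ps,
        }


def occupancy(series: DeltaSeries) -> OccupancyStats:
    """Occupancy fractions, cumulative likelihood, and TRS waiting time.

    The mean waiting time between compression events assumes the events are
    uniformly distributed over the trajectory: frame interval divided by
    the TRS occupancy fraction.  It is undefined (None) when no frame is
    classified TRS.
    """
    if series.labels is None:
        series = classify(series)
    labels = np.asarray(series.labels, dtype=object)
    n = series.n_frames
    fractions = {
        state: float(np.count_nonzero(labels == state)) / n
        for state in (STATE_TRS, STATE_BOUND, STATE_UNBOUND)
    }
    f_trs = fractions[STATE_TRS]
    waiting = series.frame_interval_ps / f_trs if f_trs > 0 else None
    return OccupancyStats(
        fractions=fractions,
        mean_waiting_time_ps=waiting,
        delta_sorted=np.sort(series.delta),
        n_frames=n,
        frame_interval_ps=series.frame_interval_ps,
    )


def trs_cut_from_path(path: ReactionPath, i: int = 4) -> float:
    """TRS threshold from the geometric gap between consecutive path images.

    Returns the Δ (RMS Cartesian distance, no alignment) between images
    ``i`` and ``i+1`` of a reaction path that carries per-image geometries;
    the spacing of the images bracketing the start of the proton-transfer
    barrier defines how close a snapshot must be to count as
    tunnelling-ready.
    """
    if path.geometries is None:
        raise MissingGeometryError("path carries no per-image geometries")
    if i < 0 or i + 1 >= path.n_images:
        raise InsufficientDataError(
            f"path has {path.n_images} images; cannot compare {i} and {i + 1}"
        )
    g0 = path.geometries[i]
    g1 = path.geometries[i + 1]
    if g0 is None or g1 is None:
        raise MissingGeometryError(f"images {i}/{i + 1} carry no geometry")
    ref = ReferenceGeometry(elements=g0.elements, coords=g0.coords, label="image")
    return delta_metric(g1.coords, ref, align=False)


# ---------------------------------------------------------------------------
# I/O (XYZ / PDB via MDAnalysis)


def _universe(file):
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(file))


def load_reference(
    file, selection: tuple[int, ...] | None = None, label: str = "TRS"
) -> ReferenceGeometry:
    """Read a single-frame XYZ/PDB reference geometry."""
    u = _universe(file)
    elements = tuple(str(n) for n in u.atoms.names)
    return ReferenceGeometry(
        elements=elements,
        coords=u.atoms.positions.astype(float),
        selection=selection,
        label=label,
    )


def load_trajectory(file, frame_interval_ps: float) -> TrajectoryFrames:
    """Read a multi-frame XYZ/PDB trajectory of the selected atom set."""
    u = _universe(file)
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if frames.shape[0] < 1:
        raise EmptyInputError(f"{file} contains no frames")
    elements = tuple(str(n) for n in u.atoms.names)
    return TrajectoryFrames(
        coords=frames, frame_interval_ps=frame_interval_ps, elements=elements
    )


def write_delta_table(series: DeltaSeries, file) -> None:
    """Per-frame TSV: frame, time_ps, delta_A, state."""
    if series.labels is None:
        series = classify(series)
    with open(file, "w") as fh:
        fh.write("frame\ttime_ps\tdelta_A\tstate\n")
        for i, (d, lab) in enumerate(zip(series.delta, series.labels)):
            fh.write(f"{i}\t{i * series.frame_interval_ps:.6g}\t{d:.6f}\t{lab}\n")
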