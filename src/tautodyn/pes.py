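"""Reaction-path potentials: loading, interpolation, and barrier analysis.

A proton-transfer reaction path is consumed as a table of images
(path coordinate s in Å, potential energy E in eV), e.g. the output of a
nudged-elastic-band optimization.  This module turns such tables into a C²
continuous profile, locates stationary points and barriers, segments the
path into collective-motion / proton-transfer / post-transfer regions,
crops the tunnelling-ready inner barrier, and applies fractional
free-energy corrections to electronic barriers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_closing, uniform_filter1d
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .errors import (
    DomainError,
    InsufficientDataError,
    InvalidWindowError,
    MalformedPathError,
    MissingGeometryError,
    NoBarrierError,
    ParameterError,
    PathParseError,
)

__all__ = [
    "Geometry",
    "ReactionPath",
    "PESProfile",
    "BarrierSummary",
    "Region",
    "RegionSegmentation",
    "BarrierFreeEnergy",
    "load_path",
    "save_path",
    "interpolate",
    "barrier_summary",
    "segment_regions",
    "extract_trs_subpath",
    "apply_free_energy_correction",
]

# CSV dialect for path tables
COL_S = "s_angstrom"
COL_E = "energy_ev"


@dataclass(frozen=True)
class Geometry:
    """Cartesian geometry of one image: element labels plus (n, 3) coordinates in Å."""

    elements: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ParameterError("geometry coordinates must have shape (n_atoms, 3)")
        if coords.shape[0] != len(self.elements):
            raise ParameterError("element labels and coordinates disagree in length")
        if not np.all(np.isfinite(coords)):
            raise ParameterError("geometry coordinates must be finite")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class ReactionPath:
    """Discrete reaction path: images (s_i, E_i), optionally with geometries.

    Energies are normalized on construction so that the first image defines
    the zero, E[0] = 0.  Path coordinates must be strictly increasing and at
    least three images are required.
    """

    s: np.ndarray
    energy: np.ndarray
    geometries: tuple[Geometry | None, ...] | None = None
    label: str = ""

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        e = np.asarray(self.energy, dtype=float)
        if s.ndim != 1 or e.ndim != 1 or s.size != e.size:
            raise MalformedPathError("s and energy must be 1-D arrays of equal length")
        if s.size < 3:
            raise InsufficientDataError(
                f"a reaction path needs at least 3 images, got {s.size}"
            )
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(e))):
            raise MalformedPathError("path coordinates and energies must be finite")
        if not np.all(np.diff(s) > 0):
            raise MalformedPathError("path coordinate s must be strictly increasing")
        if self.geometries is not None and len(self.geometries) != s.size:
            raise MalformedPathError("one geometry (or None) required per image")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "energy", e - e[0])

    @property
    def n_images(self) -> int:
        return int(self.s.size)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.s[0]), float(self.s[-1])


class PESProfile:
    """C² continuous interpolant of a :class:`ReactionPath`.

    Natural cubic spline through the image energies; node-exact, with
    derivatives available up to third order (the third derivative is the
    spline's piecewise-constant value, discontinuous at knots).  Queries
    outside the image domain raise :class:`DomainError`.
    """

    def __init__(self, path: ReactionPath):
        self.path = path
        self.spline = CubicSpline(path.s, path.energy, bc_type="natural")
        self._derivs = {1: self.spline.derivative(1)}

    @property
    def domain(self) -> tuple[float, float]:
        return self.path.domain

    def _check_domain(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        lo, hi = self.domain
        eps = 1e-9 * max(1.0, hi - lo)
        if np.any(s < lo - eps) or np.any(s > hi + eps):
            raise DomainError(
                f"query outside profile domain [{lo:g}, {hi:g}] Å"
            )
        return np.clip(s, lo, hi)

    def __call__(self, s, nu: int = 0):
        """Energy (eV) or its nu-th derivative at path coordinate s (Å)."""
        s = self._check_domain(s)
        if nu == 0:
            return self.spline(s)
        if nu not in self._derivs:
            if not 1 <= nu <= 3:
                raise ParameterError("derivative order must be in 0..3")
            self._derivs[nu] = self.spline.derivative(nu)
        return self._derivs[nu](s)

    def energy(self, s):
        return self(s)

    def gradient(self, s):
        return self(s, nu=1)


def load_path(
    file: str | Path,
    geometry_sidecar: str | Path | None = None,
    label: str | None = None,
) -> ReactionPath:
    """Load a two-column CSV path table (columns s_angstrom, energy_ev).

    An optional JSON sidecar supplies per-image geometries as
    ``{"elements": [...], "coordinates": [[[x,y,z]...], ...]}``.
    Energies are shifted so the first image is zero.
    """
    file = Path(file)
    if not file.exists():
        raise FileNotFoundError(file)
    try:
        table = pd.read_csv(file, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PathParseError(f"could not read {file}: {exc}") from exc
    cols = {c.strip().lower(): c for c in table.columns}
    if COL_S not in cols or COL_E not in cols:
        raise PathParseError(
            f"{file} must have header columns '{COL_S}' and '{COL_E}'", line=1
        )
    s_raw = pd.to_numeric(table[cols[COL_S]], errors="coerce")
    e_raw = pd.to_numeric(table[cols[COL_E]], errors="coerce")
    bad = np.where(s_raw.isna() | e_raw.isna())[0]
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise PathParseError(f"non-numeric entry in {file}", line=int(bad[0]) + 2)
    if len(table) < 3:
        raise InsufficientDataError(
            f"{file} has {len(table)} rows; at least 3 images required"
        )
    geometries = None
    if geometry_sidecar is not None:
        with open(geometry_sidecar) as fh:
            data = json.load(fh)
        elements = tuple(data["elements"])
        coords = data["coordinates"]
        if len(coords) != len(table):
            raise PathParseError(
                "geometry sidecar image count does not match the path table"
            )
        geometries = tuple(
            Geometry(elements, np.asarray(c, dtype=float)) for c in coords
        )
    return ReactionPath(
        s=s_raw.to_numpy(),
        energy=e_raw.to_numpy(),
        geometries=geometries,
        label=label if label is not None else file.stem,
    )


def save_path(path: ReactionPath, file: str | Path,
              geometry_sidecar: str | Path | None = None) -> None:
    """Write the CSV dialect that :func:`load_path` consumes (round-trip safe)."""
    pd.DataFrame({COL_S: path.s, COL_E: path.energy}).to_csv(file, index=False)
    if geometry_sidecar is not None:
        if path.geometries is None or any(g is None for g in path.geometries):
            raise MissingGeometryError(
                "path has no complete per-image geometries to write"
            )
        data = {
            "elements": list(path.geometries[0].elements),
            "coordinates": [g.coords.tolist() for g in path.geometries],
        }
        with open(geometry_sidecar, "w") as fh:
            json.dump(data, fh)


def interpolate(path: ReactionPath) -> PESProfile:
    """Build the continuous C² profile for a validated reaction path."""
    return PESProfile(path)


@dataclass(frozen=True)
class BarrierSummary:
    """Stationary-point analysis of a profile with a single global TS.

    E_f/E_r are the forward/reverse electronic barriers in eV measured from
    the reactant/product minima to the global transition state;
    ΔE = E_f − E_r is the product-minus-reactant asymmetry.
    """

    E_f: float
    E_r: float
    delta_E: float
    s_reactant: float
    s_TS: float
    s_product: float
    intermediate_minima: tuple[tuple[float, float], ...] = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intermediate_minima"] = [list(m) for m in self.intermediate_minima]
        return d


_TIE_TOL_EV = 1e-9


def _refine_extremum(profile: PESProfile, s_lo: float, s_hi: float,
                     kind: str) -> tuple[float, float]:
    sign = -1.0 if kind == "max" else 1.0
    res = minimize_scalar(
        lambda x: sign * float(profile(x)),
        bounds=(s_lo, s_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(profile(res.x))


def barrier_summary(profile: PESProfile, n_dense: int = 8001) -> BarrierSummary:
    """Locate reactant/product minima and the global transition state.

    Stationary points are found from sign structure on a dense grid and
    refined by bounded minimization on the spline.  The global TS is the
    highest interior maximum between the terminal minima; equal-energy
    candidates (within 1e-9 eV) are broken toward the path midpoint.
    All intermediate minima between reactant and product are reported.
    """
    lo, hi = profile.domain
    grid = np.linspace(lo, hi, n_dense)
    e = profile(grid)
    prominence = 1e-6
    imax, _ = find_peaks(e, prominence=prominence)
    imin, _ = find_peaks(-e, prominence=prominence)
    maxima = [
        _refine_extremum(profile, grid[max(i - 2, 0)], grid[min(i + 2, n_dense - 1)], "max")
        for i in imax
    ]
    minima = [
        _refine_extremum(profile, grid[max(i - 2, 0)], grid[min(i + 2, n_dense - 1)], "min")
        for i in imin
    ]
    # domain endpoints always qualify as candidate terminal minima
    minima = [(lo, float(e[0]))] + minima + [(hi, float(e[-1]))]
    if not maxima:
        raise NoBarrierError("profile has no interior maximum (monotone or flat)")

    s_first_min = minima[0][0]
    s_last_min = minima[-1][0]
    interior = [m for m in maxima if s_first_min < m[0] < s_last_min]
    if not interior:
        raise NoBarrierError("no interior maximum between terminal minima")
    e_top = max(m[1] for m in interior)
    mid = 0.5 * (lo + hi)
    candidates = [m for m in interior if m[1] >= e_top - _TIE_TOL_EV]
    s_TS, E_TS = min(candidates, key=lambda m: abs(m[0] - mid))

    left = [m for m in minima if m[0] < s_TS]
    right = [m for m in minima if m[0] > s_TS]
    if not left or not right:
        raise NoBarrierError("transition state is not flanked by minima")
    s_reactant, e_reactant = min(left, key=lambda m: m[1])
    s_product, e_product = min(right, key=lambda m: m[1])
    inter = tuple(
        (s, ev)
        for s, ev in minima
        if s_reactant < s < s_product and s != s_reactant and s != s_product
    )
    E_f = E_TS - e_reactant
    E_r = E_TS - e_product
    return BarrierSummary(
        E_f=E_f,
        E_r=E_r,
        delta_E=E_f - E_r,
        s_reactant=s_reactant,
        s_TS=s_TS,
        s_product=s_product,
        intermediate_minima=inter,
    )


LABEL_COLLECTIVE = "collective-motion"
LABEL_TRANSFER = "proton-transfer"
LABEL_POST = "post-transfer"


@dataclass(frozen=True)
class Region:
    s_lo: float
    s_hi: float
    label: str


@dataclass(frozen=True)
class RegionSegmentation:
    """Contiguous, non-overlapping cover of the path domain."""

    boundaries: tuple[Region, ...]

    def __post_init__(self):
        b = self.boundaries
        if not b:
            raise ParameterError("segmentation must contain at least one region")
        for prev, nxt in zip(b, b[1:]):
            if abs(prev.s_hi - nxt.s_lo) > 1e-9:
                raise ParameterError("regions must be contiguous")

    def region_of(self, label: str) -> Region | None:
        for r in self.boundaries:
            if r.label == label:
                return r
        return None

    def to_dict(self) -> dict:
        return {
            "boundaries": [
                {"s_lo": r.s_lo, "s_hi": r.s_hi, "label": r.label}
                for r in self.boundaries
            ]
        }


def segment_regions(
    profile: PESProfile,
    gradient_threshold: float = 0.05,
    smoothing_window: float = 0.25,
) -> RegionSegmentation:
    """Split the path into flat flanks and the steep proton-transfer region.

    The |dE/ds| magnitude (smoothed over ``smoothing_window`` Å) is
    thresholded; the contiguous above-threshold run containing the global
    transition state is labelled proton-transfer, everything before it
    collective-motion and everything after post-transfer.  Degenerate
    profiles with no barrier or no steep region collapse to a single
    collective-motion region.
    """
    if gradient_threshold <= 0 or smoothing_window <= 0:
        raise ParameterError("threshold and smoothing window must be positive")
    lo, hi = profile.domain
    n = 4001
    grid = np.linspace(lo, hi, n)
    ds = grid[1] - grid[0]
    g = np.abs(profile(grid, nu=1))
    win = max(1, int(round(smoothing_window / ds)))
    g = uniform_filter1d(g, size=win, mode="nearest")
    steep = g > gradient_threshold

    whole = RegionSegmentation((Region(lo, hi, LABEL_COLLECTIVE),))
    if not steep.any():
        return whole
    try:
        bs = barrier_summary(profile)
    except NoBarrierError:
        return whole
    # close sub-window gaps (e.g. the zero-gradient dip at the barrier top)
    steep = binary_closing(steep, structure=np.ones(2 * win + 1))
    i_ts = int(np.clip(round((bs.s_TS - lo) / ds), 0, n - 1))
    if not steep[i_ts]:
        # TS sits in a closed gap wider than the window; attach nearest run
        idx = np.where(steep)[0]
        i_ts = int(idx[np.argmin(np.abs(idx - i_ts))])
    i0 = i_ts
    while i0 > 0 and steep[i0 - 1]:
        i0 -= 1
    i1 = i_ts
    while i1 < n - 1 and steep[i1 + 1]:
        i1 += 1
    s_lo, s_hi = float(grid[i0]), float(grid[i1])
    regions: list[Region] = []
    if s_lo > lo + 1e-9:
        regions.append(Region(lo, s_lo, LABEL_COLLECTIVE))
    else:
        s_lo = lo
    if s_hi < hi - 1e-9:
        regions.append(Region(s_lo, s_hi, LABEL_TRANSFER))
        regions.append(Region(s_hi, hi, LABEL_POST))
    else:
        regions.append(Region(s_lo, hi, LABEL_TRANSFER))
    return RegionSegmentation(tuple(regions))


def extract_trs_subpath(
    profile: PESProfile, s_lo: float, s_hi: float, label: str | None = None
) -> ReactionPath:
    """Crop the inner (tunnelling-ready) barrier from a full reaction path.

    The window must lie inside the profile domain and contain the global
    transition state.  The cropped path keeps the original images inside
    the window, gains exact boundary images evaluated from the spline when
    the window edges are not nodes, and is re-origined (s → s − s_lo) and
    re-zeroed at its own first image.
    """
    lo, hi = profile.domain
    if not (lo - 1e-9 <= s_lo < s_hi <= hi + 1e-9):
        raise InvalidWindowError(
            f"window [{s_lo:g}, {s_hi:g}] outside profile domain [{lo:g}, {hi:g}]"
        )
    s_lo = max(s_lo, lo)
    s_hi = min(s_hi, hi)
    bs = barrier_summary(profile)
    if not (s_lo <= bs.s_TS <= s_hi):
        raise InvalidWindowError(
            f"window [{s_lo:g}, {s_hi:g}] does not contain the transition state "
            f"at {bs.s_TS:.4g} Å"
        )
    path = profile.path
    inside = (path.s >= s_lo - 1e-12) & (path.s <= s_hi + 1e-12)
    s_new = list(path.s[inside])
    e_new = list(path.energy[inside])
    geoms = None
    if path.geometries is not None:
        geoms = [g for g, m in zip(path.geometries, inside) if m]
    if not s_new or s_new[0] > s_lo + 1e-12:
        s_new.insert(0, s_lo)
        e_new.insert(0, float(profile(s_lo)))
        if geoms is not None:
            geoms.insert(0, None)
    if s_new[-1] < s_hi - 1e-12:
        s_new.append(s_hi)
        e_new.append(float(profile(s_hi)))
        if geoms is not None:
            geoms.append(None)
    s_arr = np.asarray(s_new) - s_lo
    e_arr = np.asarray(e_new)
    return ReactionPath(
        s=s_arr,
        energy=e_arr,
        geometries=tuple(geoms) if geoms is not None else None,
        label=label if label is not None else f"{path.label}[{s_lo:g},{s_hi:g}]",
    )


@dataclass(frozen=True)
class BarrierFreeEnergy:
    """Forward/reverse Gibbs barriers in eV and how they were obtained."""

    G_f: float
    G_r: float
    source: str = "direct"

    def __post_init__(self):
        if self.G_f < 0 or self.G_r < 0:
            raise ParameterError("Gibbs barriers must be non-negative")


def apply_free_energy_correction(
    barriers: BarrierSummary, f_forward: float, f_reverse: float
) -> BarrierFreeEnergy:
    """Reduce electronic barriers by stated fractions to obtain Gibbs barriers.

    Vibrational/entropic contributions from a normal-mode analysis enter as
    fractional reductions: G_f = E_f (1 − f_forward), G_r = E_r (1 − f_reverse).
    """
    for f in (f_forward, f_reverse):
        if not 0.0 <= f < 1.0:
            raise ParameterError(f"correction fraction must be in [0, 1), got {f}")
    return BarrierFreeEnergy(
        G_f=barriers.E_f * (1.0 - f_forward),
        G_r=barriers.E_r * (1.0 - f_reverse),
        source="fractional-correction",
    )
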