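"""Chamber / tumor-ROI / EPR-shell geometry and collision primitives.

The simulated tissue volume is an axis-aligned box (the imaging field of
view, FOV) containing two concentric spheres centred on the tumor: an inner
region of interest (ROI, the tumor itself) and an outer EPR sphere whose
shell between the two radii models the zone of leaky vasculature around the
tumor.  All coordinates are dimensionless chamber-lengths; the engine's
frame is the time unit.

Every primitive here operates on ``(..., 3)`` float arrays so the engine can
resolve collisions for thousands of particles per frame without Python
loops; the scalar signatures documented below are the ``(3,)`` special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Vec3",
    "Region",
    "Surface",
    "Geometry",
    "Crossing",
    "CrossingBatch",
    "classify_region",
    "classify_region_codes",
    "reflect_specular",
    "first_crossing",
    "first_crossings",
    "GeometryError",
]

#: A point or direction in chamber coordinates: float array of shape (3,).
Vec3 = np.ndarray


class GeometryError(ValueError):
    """Invalid geometry or a point/segment outside the valid domain."""


class Region(Enum):
    """Compartment a point belongs to.

    ``EPR`` exists only while the EPR zone is enabled; with the zone off the
    shell between the two sphere radii is ordinary FOV.
    """

    FOV = "fov"
    EPR = "epr"
    ROI = "roi"


# Integer region codes used by the vectorized engine hot path.
REGION_FOV, REGION_EPR, REGION_ROI = 0, 1, 2
_REGION_FROM_CODE = {REGION_FOV: Region.FOV, REGION_EPR: Region.EPR, REGION_ROI: Region.ROI}


class Surface(Enum):
    """Identity of a collision surface."""

    WALL = "wall"
    ROI_SPHERE = "roi_sphere"
    EPR_SPHERE = "epr_sphere"


# Surface codes for the batch solver: 0..5 walls (axis*2 + (sign<0)),
# 6 ROI sphere, 7 EPR sphere, -1 no hit.
SURF_ROI = 6
SURF_EPR = 7
SURF_NONE = -1

#: Parametric hits closer than this to t=0 are ignored (the particle is
#: sitting on the surface it just interacted with).
T_EPS = 1e-9
#: Grazing hits with t within this of 1 are deferred to the next frame so a
#: single contact is never processed twice.
T_DEFER = 1e-9


def _as_vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError("vector components must be finite")
    return a


@dataclass(frozen=True)
class Geometry:
    """Static scene: box chamber, concentric ROI/EPR spheres, site points.

    Defaults place the tumor at the origin of a 2 x 1.2 x 1.2 chamber with
    an ROI radius of 0.15 and an EPR radius of 0.30, the injection site at
    the centre of the x = -1 wall and the clearance site parked outside the
    chamber (cleared particles are inert there).
    """

    chamber_half_extents: tuple = (1.0, 0.6, 0.6)
    roi_center: tuple = (0.0, 0.0, 0.0)
    roi_radius: float = 0.15
    epr_radius: float = 0.30
    injection_site: tuple = (-1.0, 0.0, 0.0)
    clearance_site: tuple = (1.5, 0.0, 0.0)

    def __post_init__(self):
        h = _as_vec(self.chamber_half_extents)
        c = _as_vec(self.roi_center)
        inj = _as_vec(self.injection_site)
        clr = _as_vec(self.clearance_site)
        object.__setattr__(self, "chamber_half_extents", tuple(h))
        object.__setattr__(self, "roi_center", tuple(c))
        object.__setattr__(self, "injection_site", tuple(inj))
        object.__setattr__(self, "clearance_site", tuple(clr))
        if not (h > 0).all():
            raise GeometryError("chamber_half_extents: all components must be positive")
        if not 0 < self.roi_radius < self.epr_radius:
            raise GeometryError("require 0 < roi_radius < epr_radius")
        if np.any(np.abs(c) + self.epr_radius > h + 1e-12):
            raise GeometryError("EPR sphere must lie entirely inside the chamber")
        if np.any(np.abs(inj) > h + 1e-12):
            raise GeometryError("injection_site must be on or inside the chamber walls")
        if np.linalg.norm(inj - c) < self.epr_radius:
            raise GeometryError("injection_site must be outside the EPR sphere")
        if np.all(np.abs(clr) <= h - 1e-12):
            raise GeometryError("clearance_site must be outside the chamber's active volume")

    # -- cached arrays for the hot path -------------------------------------
    @property
    def _h(self) -> np.ndarray:
        return np.asarray(self.chamber_half_extents)

    @property
    def _c(self) -> np.ndarray:
        return np.asarray(self.roi_center)

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points lie in the closed chamber box."""
        p = np.asarray(points, dtype=float)
        return np.all(np.abs(p) <= self._h + atol, axis=-1)

    def inward_release_axis(self) -> tuple[int, float] | None:
        """Axis index and inward sign of the wall carrying the injection site.

        ``None`` if the site is strictly interior (release directions then
        cover the full sphere rather than a hemisphere).
        """
        inj = np.asarray(self.injection_site)
        on_wall = np.isclose(np.abs(inj), self._h, atol=1e-9)
        if not on_wall.any():
            return None
        axis = int(np.argmax(on_wall))
        return axis, -float(np.sign(inj[axis]))


def classify_region_codes(points: np.ndarray, geometry: Geometry, epr_enabled: bool) -> np.ndarray:
    """Vectorized region classification returning integer codes.

    ROI if the point is strictly inside the ROI sphere, EPR if it lies in
    the shell and the zone is enabled, FOV otherwise.  Points outside the
    chamber indicate an engine collision-handling bug and raise.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if not geometry.contains(p).all():
        raise GeometryError("point outside chamber: cannot classify region")
    d = np.linalg.norm(p - geometry._c, axis=-1)
    codes = np.full(p.shape[0], REGION_FOV, dtype=np.int8)
    codes[d < geometry.roi_radius] = REGION_ROI
    if epr_enabled:
        codes[(d >= geometry.roi_radius) & (d < geometry.epr_radius)] = REGION_EPR
    return codes


def classify_region(point: Vec3, geometry: Geometry, epr_enabled: bool) -> Region:
    """Which compartment a single in-chamber point belongs to."""
    code = classify_region_codes(_as_vec(point)[None, :], geometry, epr_enabled)[0]
    return _REGION_FROM_CODE[int(code)]


def reflect_specular(velocity: Vec3, unit_normal: Vec3) -> Vec3:
    """Mirror ``velocity`` across the plane orthogonal to ``unit_normal``.

    Returns ``v - 2 (v.n) n``; the speed is preserved exactly.  Broadcasts
    over leading axes.  A zero-norm normal is rejected.
    """
    v = np.asarray(velocity, dtype=float)
    n = np.asarray(unit_normal, dtype=float)
    norms = np.linalg.norm(n, axis=-1)
    if np.any(norms < 1e-12):
        raise GeometryError("reflect_specular: zero-norm normal")
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise GeometryError("reflect_specular: normal must be unit length")
    return v - 2.0 * np.sum(v * n, axis=-1, keepdims=True) * n


@dataclass(frozen=True)
class Crossing:
    """First intersection of a motion segment with an active surface."""

    t: float
    surface: Surface
    #: for walls: (axis, sign of the wall plane); None for spheres
    wall: tuple[int, int] | None
    point: Vec3
    normal: Vec3  # outward unit normal of the surface at the hit point
    entering: bool  # True if the segment crosses from outside to inside


@dataclass
class CrossingBatch:
    """Struct-of-arrays result of :func:`first_crossings` for N segments."""

    has_hit: np.ndarray  # (N,) bool
    t: np.ndarray  # (N,) float, inf where no hit
    surface: np.ndarray  # (N,) int8 codes: 0..5 wall, SURF_ROI, SURF_EPR, SURF_NONE
    point: np.ndarray  # (N, 3) hit points (undefined where no hit)
    normal: np.ndarray  # (N, 3) outward unit normals (undefined where no hit)
    entering: np.ndarray  # (N,) bool, crossing direction for spheres


def _sphere_crossing_t(p: np.ndarray, d: np.ndarray, center: np.ndarray, radius: float):
    """Earliest valid parametric hit of N segments with one sphere.

    Returns ``(t, exiting)`` with ``t = inf`` where the segment does not
    reach the sphere in ``(T_EPS, 1 - T_DEFER]``.  ``exiting`` is True where
    the radial velocity at the hit points outward (inside -> out crossing).
    """
    rel = p - center
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", d, rel)
    c = np.einsum("ij,ij->i", rel, rel) - radius * radius
    disc = b * b - 4.0 * a * c
    t = np.full(p.shape[0], np.inf)
    ok = (disc >= 0) & (a > 0)
    if ok.any():
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b - sq) / (2.0 * a)
            t2 = (-b + sq) / (2.0 * a)
        for root in (t1, t2):  # t1 <= t2, keep earliest valid
            valid = ok & (root > T_EPS) & (root <= 1.0 - T_DEFER) & (root < t)
            t[valid] = root[valid]
    hit = np.isfinite(t)
    exiting = np.zeros(p.shape[0], dtype=bool)
    if hit.any():
        hp = p[hit] + t[hit, None] * d[hit]
        exiting[hit] = np.einsum("ij,ij->i", d[hit], hp - center) > 0
    return t, exiting


def _wall_crossing_t(p: np.ndarray, d: np.ndarray, h: np.ndarray):
    """Earliest wall-plane hit per segment (slab method).

    Returns ``(t, axis, sign)`` with ``t = inf`` where no wall is reached.
    """
    n = p.shape[0]
    t = np.full(n, np.inf)
    axis = np.zeros(n, dtype=np.int8)
    sign = np.zeros(n, dtype=np.int8)
    for i in range(3):
        di = d[:, i]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_pos = np.where(di > 0, (h[i] - p[:, i]) / di, np.inf)
            t_neg = np.where(di < 0, (-h[i] - p[:, i]) / di, np.inf)
        ti = np.minimum(t_pos, t_neg)
        si = np.where(di > 0, 1, -1).astype(np.int8)
        valid = (ti > T_EPS) & (ti <= 1.0 - T_DEFER) & (ti < t)
        t[valid] = ti[valid]
        axis[valid] = i
        sign[valid] = si[valid]
    return t, axis, sign


def first_crossings(
    starts: np.ndarray,
    displacements: np.ndarray,
    geometry: Geometry,
    epr_enabled: bool,
) -> CrossingBatch:
    """Earliest surface crossing for each of N motion segments.

    Active surfaces are the six chamber walls, the ROI sphere and — only
    when the EPR zone is enabled — the EPR sphere.  Hits are parametric
    ``t`` in ``(T_EPS, 1 - T_DEFER]`` along ``start + t * displacement``;
    grazing contacts at ``t ~ 1`` are deferred to the next frame.  On exact
    ties the wall wins over the ROI sphere which wins over the EPR sphere
    (ties are measure-zero and only affect which contact is processed
    first).
    """
    p = np.atleast_2d(np.asarray(starts, dtype=float))
    d = np.atleast_2d(np.asarray(displacements, dtype=float))
    n = p.shape[0]
    h = geometry._h
    c = geometry._c

    t_wall, w_axis, w_sign = _wall_crossing_t(p, d, h)
    t_roi, roi_exit = _sphere_crossing_t(p, d, c, geometry.roi_radius)
    if epr_enabled:
        t_epr, epr_exit = _sphere_crossing_t(p, d, c, geometry.epr_radius)
    else:
        t_epr = np.full(n, np.inf)
        epr_exit = np.zeros(n, dtype=bool)

    stacked = np.stack([t_wall, t_roi, t_epr])  # priority order on ties
    which = np.argmin(stacked, axis=0)
    t = stacked[which, np.arange(n)]
    has_hit = np.isfinite(t)

    surface = np.full(n, SURF_NONE, dtype=np.int8)
    wall_hit = has_hit & (which == 0)
    roi_hit = has_hit & (which == 1)
    epr_hit = has_hit & (which == 2)
    surface[wall_hit] = (w_axis[wall_hit] * 2 + (w_sign[wall_hit] < 0)).astype(np.int8)
    surface[roi_hit] = SURF_ROI
    surface[epr_hit] = SURF_EPR

    point = np.where(has_hit[:, None], p + np.where(has_hit, t, 0.0)[:, None] * d, 0.0)
    normal = np.zeros((n, 3))
    if wall_hit.any():
        normal[wall_hit, w_axis[wall_hit]] = w_sign[wall_hit]
    sphere_hit = roi_hit | epr_hit
    if sphere_hit.any():
        rad = point[sphere_hit] - c
        normal[sphere_hit] = rad / np.linalg.norm(rad, axis=-1, keepdims=True)

    entering = np.zeros(n, dtype=bool)
    entering[roi_hit] = ~roi_exit[roi_hit]
    entering[epr_hit] = ~epr_exit[epr_hit]
    return CrossingBatch(has_hit=has_hit, t=t, surface=surface, point=point, normal=normal, entering=entering)


def first_crossing(
    start: Vec3,
    displacement: Vec3,
    geometry: Geometry,
    epr_enabled: bool,
) -> Crossing | None:
    """Scalar convenience wrapper around :func:`first_crossings`."""
    s = _as_vec(start)
    d = _as_vec(displacement)
    if not geometry.contains(s):
        raise GeometryError("first_crossing: start point outside chamber")
    if np.linalg.norm(d) == 0.0:
        return None
    batch = first_crossings(s[None, :], d[None, :], geometry, epr_enabled)
    if not batch.has_hit[0]:
        return None
    code = int(batch.surface[0])
    if code == SURF_ROI:
        surf, wall = Surface.ROI_SPHERE, None
    elif code == SURF_EPR:
        surf, wall = Surface.EPR_SPHERE, None
    else:
        surf, wall = Surface.WALL, (code // 2, -1 if code % 2 else 1)
    return Crossing(
        t=float(batch.t[0]),
        surface=surf,
        wall=wall,
        point=batch.point[0].copy(),
        normal=batch.normal[0].copy(),
        entering=bool(batch.entering[0]),
    )
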