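"""Idealized vessel geometries for stent deployment and desk-scale CFD.

Vessels are represented by a sampled centerline with per-point lumen radius
and rotation-minimizing orthonormal frames.  Geometry is classified
implicitly (point-in-lumen / point-in-sac predicates) rather than meshed:
the structured-grid solver masks cells, so no surface mesh is ever needed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VesselGeometry",
    "AneurysmSpec",
    "AneurysmAttachment",
    "make_straight_vessel",
    "make_curved_vessel",
    "attach_aneurysm",
    "read_centerline_csv",
]


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


@dataclass
class VesselGeometry:
    """Sampled vessel centerline with radii and orthonormal frames.

    Attributes
    ----------
    points : (n, 3) float array
        Centerline sample points in meters, uniformly spaced in arc length.
    radii : (n,) float array
        Lumen radius at each point (m), strictly positive.
    tangents, normals, binormals : (n, 3) float arrays
        Rotation-minimizing orthonormal frame at each point.
    arc_length : (n,) float array
        Cumulative arc length from the first point (m), strictly increasing.
    """

    points: np.ndarray
    radii: np.ndarray
    tangents: np.ndarray
    normals: np.ndarray
    binormals: np.ndarray
    arc_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise GeometryError("lumen radius must be positive everywhere")
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        self._validate_frames()
        self._validate_spacing()

    def _validate_frames(self) -> None:
        for a, b in (
            (self.tangents, self.normals),
            (self.tangents, self.binormals),
            (self.normals, self.binormals),
        ):
            if np.max(np.abs(np.sum(a * b, axis=1))) > 1e-10:
                raise GeometryError("frames are not orthogonal to 1e-10")
        for a in (self.tangents, self.normals, self.binormals):
            if np.max(np.abs(np.linalg.norm(a, axis=1) - 1.0)) > 1e-10:
                raise GeometryError("frame vectors are not unit length to 1e-10")
        if np.any(np.diff(self.arc_length) <= 0):
            raise GeometryError("arc length must be strictly increasing")

    def _validate_spacing(self) -> None:
        seg = np.diff(self.arc_length)
        if seg.size and (seg.max() - seg.min()) > 0.01 * seg.mean():
            raise GeometryError("centerline spacing non-uniform beyond 1%")

    # -- queries -----------------------------------------------------------

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def radius_at(self, s: float | np.ndarray) -> np.ndarray:
        """Lumen radius interpolated at arc position ``s`` (m)."""
        return np.interp(s, self.arc_length, self.radii)

    def frame_at(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (point, tangent, normal, binormal) at arc position s.

        Frame vectors are linearly interpolated and re-orthonormalized;
        adequate for the fine samplings used here.
        """
        s = float(np.clip(s, self.arc_length[0], self.arc_length[-1]))
        i = int(np.searchsorted(self.arc_length, s, side="right") - 1)
        i = min(max(i, 0), self.n_points - 2)
        w = (s - self.arc_length[i]) / (self.arc_length[i + 1] - self.arc_length[i])
        p = (1 - w) * self.points[i] + w * self.points[i + 1]
        t = (1 - w) * self.tangents[i] + w * self.tangents[i + 1]
        t /= np.linalg.norm(t)
        n = (1 - w) * self.normals[i] + w * self.normals[i + 1]
        n -= t * (n @ t)
        n /= np.linalg.norm(n)
        b = np.cross(t, n)
        return p, t, n, b

    def surface_point(self, s: float, theta: float) -> np.ndarray:
        """Point on the lumen wall at arc position s and angular position theta.

        theta = 0 lies along the frame normal; positive theta rotates toward
        the binormal.
        """
        p, _t, n, b = self.frame_at(s)
        r = float(self.radius_at(s))
        return p + r * (np.cos(theta) * n + np.sin(theta) * b)


@dataclass(frozen=True)
class AneurysmSpec:
    """Spherical sidewall aneurysm attached to the vessel wall.

    ``dome_radius`` and ``neck_radius`` in meters; ``position`` is the arc
    position of the neck center along the centerline; ``direction`` is the
    offset direction of the dome center expressed in the local (normal,
    binormal) frame, default along the frame normal.
    """

    dome_radius: float
    neck_radius: float
    position: float
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.dome_radius <= 0:
            raise GeometryError("dome_radius must be positive")
        if not (0 < self.neck_radius <= self.dome_radius):
            raise GeometryError("need 0 < neck_radius <= dome_radius")


@dataclass
class AneurysmAttachment:
    """Point-classification for a vessel with a sidewall aneurysm.

    Provides a label for any point in space (lumen / sac / wall / exterior)
    plus the neck disk (center, unit normal, radius) used for inflow
    integration.
    """

    vessel: VesselGeometry
    spec: AneurysmSpec
    dome_center: np.ndarray
    neck_center: np.ndarray
    neck_normal: np.ndarray

    LUMEN, SAC, EXTERIOR = 0, 1, 2

    def classify(self, pts: np.ndarray) -> np.ndarray:
        """Label points (m, 3) as LUMEN, SAC or EXTERIOR.

        Sac points are inside the dome sphere but outside the lumen; the
        lumen wins ties so the neck opening belongs to the parent artery.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        lum = self._in_lumen(pts)
        sac = (
            np.linalg.norm(pts - self.dome_center, axis=1) <= self.spec.dome_radius
        ) & ~lum
        out = np.full(pts.shape[0], self.EXTERIOR, dtype=np.int8)
        out[sac] = self.SAC
        out[lum] = self.LUMEN
        return out

    def _in_lumen(self, pts: np.ndarray) -> np.ndarray:
        # distance from each point to the nearest centerline sample
        from scipy.spatial import cKDTree

        if not hasattr(self, "_ctree"):
            self._ctree = cKDTree(self.vessel.points)
        d, j = self._ctree.query(pts)
        return d <= self.vessel.radii[j]

    def sac_volume(self, voxel: float) -> float:
        """Sac volume by voxel counting at spacing ``voxel`` (m)."""
        c = self.dome_center
        r = self.spec.dome_radius
        ax = [np.arange(c[k] - r, c[k] + r + voxel, voxel) for k in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        lab = self.classify(pts)
        return float(np.count_nonzero(lab == self.SAC)) * voxel**3


def _straight_frames(n: int, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.tile(axis / np.linalg.norm(axis), (n, 1))
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9 * np.linalg.norm(axis):
        ref = np.array([0.0, 1.0, 0.0])
    nrm = np.cross(ref, t[0])
    nrm /= np.linalg.norm(nrm)
    return t, np.tile(nrm, (n, 1)), np.tile(np.cross(t[0], nrm), (n, 1))


def make_straight_vessel(radius: float, length: float, spacing: float) -> VesselGeometry:
    """Straight tube along +x.

    Parameters are all in meters; ``length`` must be at least ten radii so a
    stent can actually be landed.
    """
    if radius <= 0 or length <= 0 or spacing <= 0:
        raise GeometryError("radius, length and spacing must be positive")
    if length < 10 * radius:
        raise GeometryError("length must be >= 10*radius")
    n = int(round(length / spacing)) + 1
    s = np.linspace(0.0, length, n)
    pts = np.column_stack([s, np.zeros(n), np.zeros(n)])
    t, nrm, b = _straight_frames(n, np.array([1.0, 0.0, 0.0]))
    return VesselGeometry(pts, np.full(n, radius), t, nrm, b, arc_length=s)


def make_curved_vessel(
    radius: float, bend_radius: float, bend_angle: float, spacing: float
) -> VesselGeometry:
    """Planar circular-arc tube in the x-y plane, starting along +x.

    The bend curves toward +y; frames are parallel-transported so the frame
    normal always points toward the bend center (no torsion spin).  A zero
    bend angle degenerates to a straight vessel of length ~10 radii.
    """
    if radius <= 0 or bend_radius <= 0 or spacing <= 0 or bend_angle < 0:
        raise GeometryError("dimensions must be positive")
    if bend_radius <= 2 * radius:
        raise GeometryError("bend_radius <= 2*radius would kink the lumen")
    if bend_angle == 0:
        return make_straight_vessel(radius, max(10 * radius, spacing * 4), spacing)
    length = bend_radius * bend_angle
    n = max(int(round(length / spacing)) + 1, 4)
    phi = np.linspace(0.0, bend_angle, n)
    # arc center at (0, bend_radius, 0); start point at origin heading +x
    pts = np.column_stack(
        [bend_radius * np.sin(phi), bend_radius * (1 - np.cos(phi)), np.zeros(n)]
    )
    t = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    nrm = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros(n)])  # toward center
    b = np.cross(t, nrm)
    return VesselGeometry(pts, np.full(n, radius), t, nrm, b, arc_length=bend_radius * phi)


def attach_aneurysm(vessel: VesselGeometry, spec: AneurysmSpec) -> AneurysmAttachment:
    """Attach a spherical sidewall sac and return the point classifier.

    The dome center is placed outward from the wall along the requested
    direction so that the sphere's chord at the wall surface has the neck
    radius; the neck disk (recorded for inflow integration) lies in the
    plane tangent to the wall at the attachment point.
    """
    if not (spec.dome_radius <= spec.position <= vessel.length - spec.dome_radius):
        raise GeometryError("attachment must be at least one dome radius from the ends")
    p, _t, n, b = vessel.frame_at(spec.position)
    dvec = spec.direction[0] * n + spec.direction[1] * b
    nn = np.linalg.norm(dvec)
    if nn == 0:
        raise GeometryError("direction must be a nonzero vector")
    dvec = dvec / nn
    r_wall = float(vessel.radius_at(spec.position))
    neck_center = p + r_wall * dvec
    # sphere center offset so the wall-plane chord radius equals neck_radius
    h = np.sqrt(spec.dome_radius**2 - spec.neck_radius**2)
    dome_center = neck_center + h * dvec
    return AneurysmAttachment(vessel, spec, dome_center, neck_center, dvec)


def read_centerline_csv(path) -> VesselGeometry:
    """Read an external centerline: columns x,y,z,radius (meters), header required.

    Frames are built by rotation-minimizing parallel transport.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = {c.lower().strip() for c in reader.fieldnames or []}
        if not {"x", "y", "z", "radius"} <= cols:
            raise GeometryError("centerline CSV needs header columns x,y,z,radius")
        rows = [
            (float(r["x"]), float(r["y"]), float(r["z"]), float(r["radius"]))
            for r in reader
        ]
    if len(rows) < 2:
        raise GeometryError("need at least two centerline points")
    arr = np.asarray(rows, dtype=float)
    pts, radii = arr[:, :3], arr[:, 3]
    t, n, b = parallel_transport_frames(pts)
    return VesselGeometry(pts, radii, t, n, b)


def parallel_transport_frames(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation-minimizing frames along a polyline (double-reflection style).

    Tangents are central-differenced; each normal is the previous normal with
    the tangent component removed, which avoids the undefined Frenet normal
    on straight runs.
    """
    pts = np.asarray(pts, dtype=float)
    m = pts.shape[0]
    t = np.gradient(pts, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n = np.zeros_like(t)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n[0] = np.cross(ref, t[0])
    n[0] /= np.linalg.norm(n[0])
    for i in range(1, m):
        v = n[i - 1] - t[i] * (n[i - 1] @ t[i])
        n[i] = v / np.linalg.norm(v)
    return t, n, np.cross(t, n)
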