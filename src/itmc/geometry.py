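"""Quadric-surface zone geometry and the voxel phantom.

Two queries drive particle tracking and nothing else does: ``locate`` (which
zone / voxel contains a point) and distance-to-boundary along a direction.
The electron boundary-crossing algorithm additionally needs a safe
perpendicular distance to the nearest boundary.

Surfaces are general axis-aligned quadrics

    F(x, y, z) = sum_c [Q_c1 (c - c0)^2 + Q_c2 (c - c0)] + Q_r,

which covers planes, circular cylinders, cones and spheres.  A zone is the
intersection of surface half-spaces (given by the sign of F) minus its
child zones; zones form a containment hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: guard distance against re-intersecting the surface just left (cm)
SURFACE_EPS = 1e-8

OUTSIDE = -1


@dataclass(frozen=True)
class QuadricSurface:
    """Axis-aligned quadric; coefficients (Q_c1, Q_c2) per axis plus Q_r."""

    quad: tuple[float, float, float]     # Q_x1, Q_y1, Q_z1
    lin: tuple[float, float, float]      # Q_x2, Q_y2, Q_z2
    const: float                         # Q_r
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not any(self.quad) and not any(self.lin):
            raise ValueError("surface with all zero coefficients")

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Signed surface function F at (..., 3) points."""
        d = np.asarray(points, dtype=float) - np.asarray(self.origin)
        q = np.asarray(self.quad)
        l = np.asarray(self.lin)
        return (d**2 @ q) + (d @ l) + self.const

    def gradient(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - np.asarray(self.origin)
        return 2.0 * d * np.asarray(self.quad) + np.asarray(self.lin)

    def ray_distance(self, points: np.ndarray, dirs: np.ndarray,
                     eps: float = SURFACE_EPS) -> np.ndarray:
        """Smallest intersection distance > eps, or +inf if none."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.atleast_2d(np.asarray(dirs, dtype=float))
        d = p - np.asarray(self.origin)
        q = np.asarray(self.quad)
        lin = np.asarray(self.lin)
        A = u**2 @ q
        B = 2.0 * (d * u) @ q + u @ lin
        C = (d**2 @ q) + d @ lin + self.const
        out = np.full(p.shape[0], np.inf)
        # linear case
        is_lin = np.abs(A) < 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lin = -C / B
        ok = is_lin & (np.abs(B) > 0) & (t_lin > eps)
        out[ok] = t_lin[ok]
        # quadratic case
        disc = B**2 - 4.0 * A * C
        has = (~is_lin) & (disc >= 0.0)
        sq = np.sqrt(np.clip(disc, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = (-B - sq) / (2.0 * A)
            r2 = (-B + sq) / (2.0 * A)
        lo = np.minimum(r1, r2)
        hi = np.maximum(r1, r2)
        t = np.where(lo > eps, lo, np.where(hi > eps, hi, np.inf))
        out[has] = t[has]
        return out if np.asarray(points).ndim > 1 else float(out[0])

    def perpendicular_distance(self, points: np.ndarray) -> np.ndarray:
        """Safe lower bound on the distance to the surface.

        Solves |F| <= |grad F| d + Q_max d^2 for d, which underestimates
        the true distance for any quadric (exact for planes).
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        F = np.abs(self.evaluate(p))
        g = np.linalg.norm(self.gradient(p), axis=-1)
        qmax = float(np.sum(np.abs(self.quad)))
        if qmax == 0.0:
            with np.errstate(divide="ignore", invalid="ignore"):
                d = F / g
            return d if np.asarray(points).ndim > 1 else float(d[0])
        d = (np.sqrt(g**2 + 4.0 * qmax * F) - g) / (2.0 * qmax)
        return d if np.asarray(points).ndim > 1 else float(d[0])


def plane(axis: str, value: float) -> QuadricSurface:
    """Plane {axis} = value; F > 0 on the +axis side."""
    i = "xyz".index(axis)
    lin = [0.0, 0.0, 0.0]
    lin[i] = 1.0
    origin = [0.0, 0.0, 0.0]
    origin[i] = value
    return QuadricSurface((0.0, 0.0, 0.0), tuple(lin), 0.0, tuple(origin))


def sphere(center, radius: float) -> QuadricSurface:
    """Sphere; F < 0 inside."""
    return QuadricSurface((1.0, 1.0, 1.0), (0.0, 0.0, 0.0),
                          -radius**2, tuple(center))


def cylinder(axis: str, c1: float, c2: float, radius: float) -> QuadricSurface:
    """Infinite circular cylinder along ``axis``; F < 0 inside.

    (c1, c2) are the center coordinates in the two transverse axes, in
    xyz order with ``axis`` removed.
    """
    i = "xyz".index(axis)
    quad = [1.0, 1.0, 1.0]
    quad[i] = 0.0
    origin = [0.0, 0.0, 0.0]
    others = [j for j in range(3) if j != i]
    origin[others[0]], origin[others[1]] = c1, c2
    return QuadricSurface(tuple(quad), (0.0, 0.0, 0.0),
                          -radius**2, tuple(origin))


@dataclass
class Zone:
    """Intersection of surface half-spaces, minus child zones."""

    zone_id: int
    surfaces: list[tuple[int, int]]      # (surface index, sense = +/-1)
    material: str
    density: float | None = None         # override, g/cm^3
    parent: int | None = None
    children: list[int] = field(default_factory=list)


class GeometrySystem:
    """Zone hierarchy over a shared surface list, plus optional voxel grid."""

    def __init__(self, surfaces: list[QuadricSurface], zones: list[Zone],
                 voxel_grid: "VoxelGrid | None" = None,
                 voxel_zone: int | None = None):
        self.surfaces = surfaces
        self.zones = zones
        self.voxel_grid = voxel_grid
        self.voxel_zone = voxel_zone
        by_id = {z.zone_id: z for z in zones}
        if len(by_id) != len(zones):
            raise ValueError("duplicate zone ids")
        for z in zones:
            z.children = [c.zone_id for c in zones if c.parent == z.zone_id]
        self._by_id = by_id

    # -- membership -------------------------------------------------------
    def _in_zone_shape(self, zone: Zone, points: np.ndarray) -> np.ndarray:
        """Inside the zone's surface intersection (children not excluded)."""
        ok = np.ones(points.shape[0], dtype=bool)
        for s_idx, sense in zone.surfaces:
            F = self.surfaces[s_idx].evaluate(points)
            ok &= (F * sense) > 0.0
        return ok

    def locate(self, points, dirs=None) -> np.ndarray:
        """Deepest zone id for each point; OUTSIDE when in no zone.

        Points exactly on a surface (|F| ~ 0) are nudged by SURFACE_EPS
        along ``dirs`` when given, so boundary points belong to the zone
        ahead along the direction of motion.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if dirs is not None:
            p = p + SURFACE_EPS * np.atleast_2d(np.asarray(dirs))
        out = np.full(p.shape[0], OUTSIDE, dtype=int)
        roots = [z for z in self.zones if z.parent is None]
        stack = [(z, np.arange(p.shape[0])) for z in roots]
        while stack:
            zone, idx = stack.pop()
            if idx.size == 0:
                continue
            inside = self._in_zone_shape(zone, p[idx])
            hit = idx[inside]
            out[hit] = zone.zone_id
            for cid in zone.children:
                stack.append((self._by_id[cid], hit))
        if np.asarray(points).ndim > 1:
            return out
        return int(out[0])

    def _boundary_surfaces(self, zone: Zone) -> list[int]:
        own = [s for s, _ in zone.surfaces]
        for cid in zone.children:
            own += [s for s, _ in self._by_id[cid].surfaces]
        return sorted(set(own))

    def distance_to_boundary(self, points, dirs, zone_ids) -> np.ndarray:
        """Distance to the first surface bounding the current zone."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.atleast_2d(np.asarray(dirs, dtype=float))
        ids = np.atleast_1d(np.asarray(zone_ids, dtype=int))
        out = np.full(p.shape[0], np.inf)
        for zone in self.zones:
            sel = np.nonzero(ids == zone.zone_id)[0]
            if sel.size == 0:
                continue
            best = np.full(sel.size, np.inf)
            for s_idx in self._boundary_surfaces(zone):
                d = self.surfaces[s_idx].ray_distance(p[sel], u[sel])
                best = np.minimum(best, d)
            out[sel] = best
        if np.asarray(points).ndim > 1:
            return out
        return float(out[0])

    def perpendicular_distance(self, points, zone_ids) -> np.ndarray:
        """Safe distance to the nearest boundary of the current zone."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        ids = np.atleast_1d(np.asarray(zone_ids, dtype=int))
        out = np.full(p.shape[0], np.inf)
        for zone in self.zones:
            sel = np.nonzero(ids == zone.zone_id)[0]
            if sel.size == 0:
                continue
            best = np.full(sel.size, np.inf)
            for s_idx in self._boundary_surfaces(zone):
                best = np.minimum(
                    best, self.surfaces[s_idx].perpendicular_distance(p[sel]))
            out[sel] = best
        if np.asarray(points).ndim > 1:
            return out
        return float(out[0])

    def zone_by_id(self, zone_id: int) -> Zone:
        return self._by_id[zone_id]


class VoxelGrid:
    """Regular grid of voxels with per-voxel material index and density.

    Voxel (i, j, k) spans the half-open box
    [origin + i*delta, origin + (i+1)*delta).  Indices are 0-based and
    flattened x-fastest where a flat index is needed.
    """

    def __init__(self, origin, shape, voxel_size, material_index=None,
                 density=None):
        self.origin = np.asarray(origin, dtype=float)
        self.shape = tuple(int(n) for n in shape)
        self.voxel_size = np.asarray(voxel_size, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")
        self.n_voxels = int(np.prod(self.shape))
        if material_index is None:
            material_index = np.zeros(self.shape, dtype=np.int16)
        if density is None:
            density = np.ones(self.shape, dtype=float)
        self.material_index = np.asarray(material_index)
        self.density = np.asarray(density, dtype=float)
        self.extent = self.origin + np.asarray(self.shape) * self.voxel_size

    def voxel_index(self, points) -> np.ndarray:
        """(..., 3) integer indices; -1 marks outside points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        f = (p - self.origin) / self.voxel_size
        idx = np.floor(f).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)
        idx[~inside] = -1
        return idx if np.asarray(points).ndim > 1 else idx[0]

    def flat_index(self, idx3) -> np.ndarray:
        i3 = np.atleast_2d(np.asarray(idx3, dtype=int))
        nx, ny, nz = self.shape
        flat = i3[:, 0] + nx * (i3[:, 1] + ny * i3[:, 2])
        flat[np.any(i3 < 0, axis=-1)] = -1
        return flat if np.asarray(idx3).ndim > 1 else int(flat[0])

    def wall_distance(self, points, dirs) -> np.ndarray:
        """Distance to the first voxel face crossed along dirs."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.atleast_2d(np.asarray(dirs, dtype=float))
        idx = np.floor((p - self.origin) / self.voxel_size)
        lo = self.origin + idx * self.voxel_size
        hi = lo + self.voxel_size
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lo - p) / u
            t_hi = (hi - p) / u
        t = np.where(u > 0, t_hi, np.where(u < 0, t_lo, np.inf))
        # clamp: rounding can place a wall-grazing point fractionally past
        # the face, which would yield a (tiny) negative distance and stall
        # the stepping loop
        out = np.maximum(np.min(t, axis=-1), 0.0)
        return out if np.asarray(points).ndim > 1 else float(out[0])

    def perpendicular_distance(self, points) -> np.ndarray:
        """Min distance over the 6 faces of the containing voxel."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        f = np.mod(p - self.origin, self.voxel_size)
        d = np.minimum(f, self.voxel_size - f)
        out = np.min(d, axis=-1)
        return out if np.asarray(points).ndim > 1 else float(out[0])

    def contains(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        ok = np.all((p >= self.origin) & (p < self.extent), axis=-1)
        return ok if np.asarray(points).ndim > 1 else bool(ok[0])

    def voxel_queries(self, points, dirs):
        """(voxel index, wall distance, perpendicular distance) bundle."""
        return (self.voxel_index(points), self.wall_distance(points, dirs),
                self.perpendicular_distance(points))
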