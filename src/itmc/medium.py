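"""Uniform medium interface over the two geometry representations.

The transport loops only need: which region a particle is in, the material
index and density factor of that region, the distance to the region
boundary along a direction, a safe perpendicular distance to the nearest
boundary, and where to deposit energy.  ``VoxelMedium`` serves the voxel
phantom; ``ZoneMedium`` serves quadric-zone systems (e.g. an ion chamber).
Material index -1 denotes vacuum; region -1 denotes outside the system.
"""

from __future__ import annotations

import numpy as np

from .geometry import OUTSIDE, SURFACE_EPS, GeometrySystem, VoxelGrid


class VoxelMedium:
    """Voxel phantom: region ids are flat voxel indices (x fastest)."""

    is_voxel = True

    def __init__(self, grid: VoxelGrid, material_names: list[str],
                 ref_densities: np.ndarray):
        self.grid = grid
        self.material_names = material_names
        mat = grid.material_index.reshape(-1, order="F").astype(int)
        rho = grid.density.reshape(-1, order="F")
        self.mat_flat = mat
        self.rho_fac_flat = rho / np.asarray(ref_densities)[mat]

    def locate(self, pos, dirs):
        idx3 = self.grid.voxel_index(pos + SURFACE_EPS * dirs)
        return self.grid.flat_index(idx3)

    def lookup(self, region):
        r = np.clip(region, 0, None)
        mat = self.mat_flat[r]
        fac = self.rho_fac_flat[r]
        mat = np.where(region < 0, -1, mat)
        return mat, fac

    def boundary_distance(self, pos, dirs, region):
        return self.grid.wall_distance(pos, dirs)

    def perp_distance(self, pos, region):
        return self.grid.perpendicular_distance(pos)

    def deposit(self, tally, region, energy, weight, batch):
        tally.deposit(region, energy, weight, batch)


class ZoneMedium:
    """Quadric-zone system: region ids are zone ids (0..n_zones-1)."""

    is_voxel = False

    def __init__(self, system: GeometrySystem, zone_materials: list[int],
                 zone_rho_fac: list[float]):
        self.system = system
        self.zone_mat = np.asarray(zone_materials, dtype=int)
        self.zone_rho_fac = np.asarray(zone_rho_fac, dtype=float)

    def locate(self, pos, dirs):
        return self.system.locate(pos, dirs)

    def lookup(self, region):
        r = np.clip(region, 0, None)
        mat = np.where(region == OUTSIDE, -1, self.zone_mat[r])
        return mat, self.zone_rho_fac[r]

    def boundary_distance(self, pos, dirs, region):
        return self.system.distance_to_boundary(pos, dirs, region)

    def perp_distance(self, pos, region):
        return self.system.perpendicular_distance(pos, region)

    def deposit(self, tally, region, energy, weight, batch):
        tally.deposit_zone(region, energy, weight, batch)
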