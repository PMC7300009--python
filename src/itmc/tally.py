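"""Energy-deposition tallies with batch statistics.

Deposits are accumulated as energy x weight (MeV) per voxel and per batch;
``finalize`` converts to dose (Gy) via the voxel masses and returns the
batch mean and the standard error of the mean.  For parallel beams doses
are reported per unit incident fluence (Gy cm^2): multiply by
``field_area / n_histories``.  Named scalar regions (e.g. an ion-chamber
cavity) are tallied alongside the grid.
"""

from __future__ import annotations

import numpy as np

from .constants import MEV_PER_G_TO_GY
from .geometry import VoxelGrid


class DoseTally:
    def __init__(self, grid: VoxelGrid | None, n_batches: int = 10,
                 region_masses: dict[str, float] | None = None,
                 zone_masses: np.ndarray | None = None):
        if n_batches < 1:
            raise ValueError("need at least one batch")
        self.grid = grid
        self.n_batches = n_batches
        n_vox = grid.n_voxels if grid is not None else 0
        self.energy = np.zeros((n_batches, n_vox))
        self.escaped = np.zeros(n_batches)
        self.regions = {name: np.zeros(n_batches)
                        for name in (region_masses or {})}
        self.region_masses = dict(region_masses or {})
        self.zone_masses = (None if zone_masses is None
                            else np.asarray(zone_masses, dtype=float))
        self.zone_energy = (None if zone_masses is None
                            else np.zeros((n_batches,
                                           self.zone_masses.size)))

    def deposit_zone(self, zone_idx, energy, weight, batch) -> None:
        """Accumulate energy*weight into per-zone bins; idx < 0 escapes."""
        z = np.atleast_1d(np.asarray(zone_idx, dtype=int))
        e = np.atleast_1d(np.asarray(energy, dtype=float)) \
            * np.atleast_1d(np.asarray(weight, dtype=float))
        b = np.broadcast_to(np.atleast_1d(np.asarray(batch, dtype=int)),
                            z.shape)
        ok = (z >= 0) & (z < self.zone_energy.shape[1])
        np.add.at(self.zone_energy, (b[ok], z[ok]), e[ok])
        np.add.at(self.escaped, b[~ok], e[~ok])

    def finalize_zone(self, zone_idx: int, norm: float = 1.0):
        """(mean, sigma) dose in one zone (Gy x norm units)."""
        dose_b = (self.zone_energy[:, zone_idx]
                  / self.zone_masses[zone_idx] * MEV_PER_G_TO_GY * norm)
        return (float(dose_b.mean()),
                float(dose_b.std(ddof=1) / np.sqrt(self.n_batches)))

    # -- accumulation -----------------------------------------------------
    def deposit(self, flat_index, energy, weight, batch) -> None:
        """Accumulate energy*weight; out-of-grid indices go to 'escaped'."""
        flat = np.atleast_1d(np.asarray(flat_index, dtype=int))
        e = np.atleast_1d(np.asarray(energy, dtype=float)) \
            * np.atleast_1d(np.asarray(weight, dtype=float))
        b = np.broadcast_to(np.atleast_1d(np.asarray(batch, dtype=int)),
                            flat.shape)
        ok = (flat >= 0) & (flat < self.energy.shape[1])
        np.add.at(self.energy, (b[ok], flat[ok]), e[ok])
        np.add.at(self.escaped, b[~ok], e[~ok])

    def deposit_region(self, name, energy, weight, batch) -> None:
        e = np.asarray(energy, dtype=float) * np.asarray(weight, dtype=float)
        np.add.at(self.regions[name],
                  np.broadcast_to(np.asarray(batch, dtype=int),
                                  np.shape(e)), e)

    def add_escaped(self, energy, weight, batch) -> None:
        e = np.asarray(energy, dtype=float) * np.asarray(weight, dtype=float)
        np.add.at(self.escaped,
                  np.broadcast_to(np.asarray(batch, dtype=int),
                                  np.shape(e)), e)

    # -- reduction --------------------------------------------------------
    @property
    def total_energy(self) -> float:
        zones = 0.0 if self.zone_energy is None else self.zone_energy.sum()
        return float(self.energy.sum() + self.escaped.sum() + zones
                     + sum(v.sum() for v in self.regions.values()))

    def voxel_masses(self) -> np.ndarray:
        vol = float(np.prod(self.grid.voxel_size))
        return (self.grid.density * vol).reshape(-1, order="F")

    def finalize(self, norm: float = 1.0):
        """Per-voxel dose mean and standard error (Gy x norm units).

        ``norm`` multiplies the per-batch doses; pass
        ``field_area * n_batches / n_histories`` for dose per unit fluence
        (each batch holds n_histories / n_batches particles).
        """
        if self.n_batches < 2:
            raise ValueError("batch statistics need at least 2 batches")
        masses = self.voxel_masses()
        dose_b = self.energy / masses * MEV_PER_G_TO_GY * norm
        mean = dose_b.mean(axis=0)
        sigma = dose_b.std(axis=0, ddof=1) / np.sqrt(self.n_batches)
        shape = self.grid.shape
        return (mean.reshape(shape, order="F"),
                sigma.reshape(shape, order="F"))

    def finalize_region(self, name: str, norm: float = 1.0):
        """(mean, sigma) dose in a named region (Gy x norm units)."""
        dose_b = (self.regions[name] / self.region_masses[name]
                  * MEV_PER_G_TO_GY * norm)
        return (float(dose_b.mean()),
                float(dose_b.std(ddof=1) / np.sqrt(self.n_batches)))


def extract_pdd(dose: np.ndarray, axis: int = 2) -> np.ndarray:
    """Central-axis depth curve.

    Odd transverse dimensions use the central column; even dimensions
    average the four central columns.
    """
    dose = np.moveaxis(np.asarray(dose), axis, 2)
    nx, ny, _ = dose.shape
    xs = [nx // 2] if nx % 2 else [nx // 2 - 1, nx // 2]
    ys = [ny // 2] if ny % 2 else [ny // 2 - 1, ny // 2]
    cols = [dose[i, j, :] for i in xs for j in ys]
    return np.mean(cols, axis=0)


def extract_profile(dose: np.ndarray, depth_index: int, axis: int = 2,
                    along: int = 0) -> np.ndarray:
    """Lateral profile at a given depth voxel index."""
    dose = np.moveaxis(np.asarray(dose), axis, 2)
    if not 0 <= depth_index < dose.shape[2]:
        raise IndexError("requested depth outside grid")
    plane = dose[:, :, depth_index]
    if along == 0:
        ny = plane.shape[1]
        ys = [ny // 2] if ny % 2 else [ny // 2 - 1, ny // 2]
        return plane[:, ys].mean(axis=1)
    nx = plane.shape[0]
    xs = [nx // 2] if nx % 2 else [nx // 2 - 1, nx // 2]
    return plane[xs, :].mean(axis=0)
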