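"""Batched simulation driver coupling the photon and electron loops.

A run is split into batches (default 10) with independent RNG substreams
spawned deterministically from the master seed; per-voxel batch spreads
give the statistical uncertainties.  Within a batch, primaries are chunked
and each chunk's photon/electron banks are drained alternately until every
history is complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electron import transport_electrons
from .geometry import VoxelGrid
from .materials import Material, get_material
from .medium import VoxelMedium, ZoneMedium
from .mscatter import MsTables, get_ms_tables
from .particles import Bank, make_state
from .photon import transport_photons
from .sources import BeamSpec, sample_primary
from .tables import TableSet, TransportSettings, get_table_set
from .tally import DoseTally

_CHUNK = 100_000


@dataclass
class RunResult:
    dose: np.ndarray | None
    sigma: np.ndarray | None
    tally: DoseTally
    diag: dict
    source_energy: float
    n_histories: int
    settings: TransportSettings
    norm: float = 1.0

    @property
    def energy_closure(self) -> float:
        """|tallied + escaped - source| / source (analog runs only)."""
        return abs(self.tally.total_energy - self.source_energy) \
            / max(self.source_energy, 1e-300)


def run_coupled(state, kind, medium, tset, tally, rng, ms_tables, diag,
                range_reject_fn=None) -> None:
    """Transport one chunk of primaries plus all their secondaries."""
    p_bank, e_bank = Bank(), Bank()
    if kind == "photon":
        p_bank.push(state)
    else:
        q = np.full(state["E"].size, 1 if kind == "positron" else 0,
                    dtype=np.int8)
        state = dict(state, q=q)
        e_bank.push(state)
    while len(p_bank) or len(e_bank):
        chunk = p_bank.pop(_CHUNK)
        if chunk is not None:
            transport_photons(chunk, medium, tset, tally, rng, e_bank,
                              p_bank, diag)
        chunk = e_bank.pop(_CHUNK)
        if chunk is not None:
            if "q" not in chunk:
                chunk["q"] = np.zeros(chunk["E"].size, np.int8)
            transport_electrons(chunk, medium, tset, tally, rng, p_bank,
                                diag, ms_tables, electron_bank=e_bank,
                                range_reject_fn=range_reject_fn)


class Simulation:
    """Reusable driver for a fixed (medium, materials, settings) setup."""

    def __init__(self, medium, materials: list[Material],
                 settings: TransportSettings, tally: DoseTally,
                 ms_tables: MsTables | None = None):
        self.medium = medium
        self.settings = settings
        self.tally = tally
        self.tset = get_table_set(materials, settings)
        self.ms_tables = ms_tables or get_ms_tables()
        self.range_reject_fn = None

    def run_beam(self, beam: BeamSpec, histories: int, seed: int,
                 diag: dict | None = None) -> RunResult:
        n_batches = self.tally.n_batches
        if histories < n_batches:
            raise ValueError("histories must be >= number of batches")
        diag = {} if diag is None else diag
        streams = np.random.SeedSequence(seed).spawn(n_batches)
        per_batch = histories // n_batches
        source_energy = 0.0
        for b in range(n_batches):
            rng = np.random.default_rng(streams[b])
            left = per_batch
            while left > 0:
                m = min(left, _CHUNK)
                left -= m
                prim = sample_primary(beam, rng, m)
                source_energy += float(np.sum(prim["E"] * prim["weight"]))
                state = make_state(prim["pos"], prim["dir"], prim["E"],
                                   prim["weight"],
                                   np.full(m, b, dtype=int))
                run_coupled(state, beam.particle, self.medium, self.tset,
                            self.tally, rng, self.ms_tables, diag,
                            self.range_reject_fn)
        dose = sigma = None
        norm = 1.0
        if self.tally.grid is not None:
            norm = beam.field_area * n_batches / (per_batch * n_batches)
            dose, sigma = self.tally.finalize(norm)
        return RunResult(dose=dose, sigma=sigma, tally=self.tally,
                         diag=diag, source_energy=source_energy,
                         n_histories=per_batch * n_batches,
                         settings=self.settings, norm=norm)

    def run_phase_space(self, psp, seed: int,
                        diag: dict | None = None) -> RunResult:
        """Transport the particles of a phase-space file.

        Rows are dealt round-robin into the tally's batches; statistical
        weights are preserved through transport and scoring.  Dose
        normalization (per history / per unit fluence) is left to the
        caller since a phase-space source has no intrinsic field area.
        """
        diag = {} if diag is None else diag
        n_batches = self.tally.n_batches
        streams = np.random.SeedSequence(seed).spawn(n_batches)
        kinds = np.asarray(psp.kinds)
        batch_of = np.arange(len(psp)) % n_batches
        source_energy = float(np.sum(psp.E * psp.weights))
        for b in range(n_batches):
            rng = np.random.default_rng(streams[b])
            in_b = batch_of == b
            for kind in ("photon", "electron", "positron"):
                sel = in_b & (kinds == kind)
                if not np.any(sel):
                    continue
                state = make_state(psp.pos[sel], psp.dirs[sel],
                                   psp.E[sel], psp.weights[sel],
                                   np.full(int(sel.sum()), b, dtype=int))
                run_coupled(state, kind, self.medium, self.tset,
                            self.tally, rng, self.ms_tables, diag,
                            self.range_reject_fn)
        dose = sigma = None
        if self.tally.grid is not None:
            dose, sigma = self.tally.finalize(1.0)
        return RunResult(dose=dose, sigma=sigma, tally=self.tally,
                         diag=diag, source_energy=source_energy,
                         n_histories=len(psp), settings=self.settings)


def slab_phantom_simulation(
        layers: list[tuple[str, float]], beam: BeamSpec,
        nxy: int = 15, dxy: float = 2.0, dz: float = 0.4,
        settings: TransportSettings | None = None,
        n_batches: int = 10,
        ms_tables: MsTables | None = None) -> Simulation:
    """Voxel phantom of stacked material slabs, beam entering at z = 0.

    ``layers`` is a list of (material name, thickness cm); the grid is
    nxy x nxy x nz with (dxy, dxy, dz) voxels covering the stack.
    """
    settings = settings or TransportSettings()
    names = []
    for name, _ in layers:
        if name not in names:
            names.append(name)
    mats = [get_material(n) for n in names]
    total = sum(t for _, t in layers)
    nz = int(round(total / dz))
    half = nxy * dxy / 2.0
    grid = VoxelGrid((-half, -half, 0.0), (nxy, nxy, nz),
                     (dxy, dxy, dz))
    mat_idx = np.zeros(grid.shape, dtype=np.int16)
    dens = np.ones(grid.shape)
    z_edges = np.arange(nz + 1) * dz
    z_cent = 0.5 * (z_edges[:-1] + z_edges[1:])
    z0 = 0.0
    for name, thick in layers:
        m = names.index(name)
        sel = (z_cent >= z0 - 1e-9) & (z_cent < z0 + thick - 1e-9)
        mat_idx[:, :, sel] = m
        dens[:, :, sel] = get_material(name).mass_density
        z0 += thick
    grid.material_index = mat_idx
    grid.density = dens
    medium = VoxelMedium(grid, names,
                         np.array([m.mass_density for m in mats]))
    tally = DoseTally(grid, n_batches=n_batches)
    return Simulation(medium, mats, settings, tally, ms_tables)
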