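"""Fano cavity test harness.

Under uniform atomic composition the equilibrium charged-particle fluence
— and hence the cavity dose — is independent of density.  With the photon
field idealized (scattered photons regenerated in place, bremsstrahlung
off, no density correction, boosted cross section), the simulated cavity
dose per unit fluence must equal E * mu_tr/rho computed from the
free-electron Klein-Nishina energy-transfer cross section.  Deviations
measure the step-size artifacts of the condensed-history electron
algorithm, which is the point of the sweep over the fractional energy-loss
limit.

Geometry: a cylindrical chamber (diameter 3 cm, 4 mm walls) with a
coaxial low-density cavity (diameter 2 cm, 2 mm thick), irradiated along
the axis by a broad parallel 1.25 MeV photon beam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import MEV_PER_G_TO_GY
from .engine import RunResult, Simulation
from .geometry import GeometrySystem, Zone, cylinder, plane, sphere
from .materials import get_material
from .medium import ZoneMedium
from .mscatter import MsTables
from .sources import BeamSpec
from .tables import TransportSettings
from . import xs

WALL, CAVITY = 1, 2          # zone ids (0 is the vacuum world)


@dataclass
class FanoConfig:
    wall_material: str = "graphite"
    wall_thickness: float = 0.4          # cm, each side
    cavity_thickness: float = 0.2        # cm
    chamber_diameter: float = 3.0        # cm
    cavity_diameter: float = 2.0         # cm
    beam_energy: float = 1.25            # MeV
    cavity_density_factor: float = 1e-3
    xs_boost: float = 100.0
    f_E_values: tuple = (0.1,)
    histories: int = 200_000
    n_batches: int = 10
    beam_margin: float = 0.35            # cm beyond the cavity radius

    def __post_init__(self):
        if self.wall_material not in ("graphite", "aluminum"):
            raise ValueError("wall material must be graphite or aluminum")
        if self.xs_boost < 1.0:
            raise ValueError("cross-section boost must be >= 1")


def theoretical_fano_dose(material_name: str, E: float = 1.25) -> float:
    """Idealized cavity dose per unit fluence, Gy cm^2.

    E * mu_tr/rho with the energy-transfer coefficient from the
    free-electron Klein-Nishina cross section (bremsstrahlung disabled, so
    energy transferred equals energy absorbed).
    """
    mat = get_material(material_name)
    mu_tr = float(xs.kn_energy_transfer_coeff(mat, np.array([E]))[0])
    return E * mu_tr * MEV_PER_G_TO_GY


def build_fano_setup(config: FanoConfig, f_E: float,
                     ms_tables: MsTables | None = None):
    """(Simulation, beam, cavity zone index, wall/cavity masses)."""
    mat = get_material(config.wall_material)
    length = 2.0 * config.wall_thickness + config.cavity_thickness
    r_ch = config.chamber_diameter / 2.0
    r_cav = config.cavity_diameter / 2.0
    z_lo = config.wall_thickness
    z_hi = config.wall_thickness + config.cavity_thickness
    surfaces = [
        sphere((0.0, 0.0, length / 2.0), 4.0 * length + r_ch),   # 0 world
        cylinder("z", 0.0, 0.0, r_ch),                           # 1
        plane("z", 0.0),                                         # 2
        plane("z", length),                                      # 3
        cylinder("z", 0.0, 0.0, r_cav),                          # 4
        plane("z", z_lo),                                        # 5
        plane("z", z_hi),                                        # 6
    ]
    zones = [
        Zone(0, [(0, -1)], "vacuum"),
        Zone(WALL, [(1, -1), (2, 1), (3, -1)], config.wall_material,
             parent=0),
        Zone(CAVITY, [(4, -1), (5, 1), (6, -1)], config.wall_material,
             density=mat.mass_density * config.cavity_density_factor,
             parent=WALL),
    ]
    system = GeometrySystem(surfaces, zones)
    medium = ZoneMedium(system, [-1, 0, 0],
                        [1.0, 1.0, config.cavity_density_factor])
    vol_cav = math.pi * r_cav**2 * config.cavity_thickness
    vol_ch = math.pi * r_ch**2 * length
    masses = np.array([
        0.0,
        (vol_ch - vol_cav) * mat.mass_density,
        vol_cav * mat.mass_density * config.cavity_density_factor,
    ])
    settings = TransportSettings.fano(f_E=f_E, boost=config.xs_boost)
    from .tally import DoseTally
    tally = DoseTally(None, n_batches=config.n_batches,
                      zone_masses=masses)
    sim = Simulation(medium, [mat], settings, tally, ms_tables)

    rho_wall = mat.mass_density
    z_mid = 0.5 * (z_lo + z_hi)
    half_cav = config.cavity_thickness / 2.0

    def range_reject(pos, residual_mass_range):
        dz = np.maximum(np.abs(pos[:, 2] - z_mid) - half_cav, 0.0)
        dr = np.maximum(np.hypot(pos[:, 0], pos[:, 1]) - r_cav, 0.0)
        d = np.hypot(dz, dr)
        return d * rho_wall > 1.2 * residual_mass_range + 0.02

    sim.range_reject_fn = range_reject
    r_beam = r_cav + config.beam_margin
    if r_beam > r_ch:
        raise ValueError("beam margin exceeds the chamber radius")
    beam = BeamSpec("photon", ("mono", config.beam_energy),
                    ("disk", r_beam, -1.0))
    return sim, beam, masses


def run_fano(config: FanoConfig, seed: int = 1,
             ms_tables: MsTables | None = None) -> list[dict]:
    """Sweep the fractional energy-loss limit; returns one row per f_E.

    Each row: f_E, simulated cavity dose per unit fluence (Gy cm^2), its
    sigma, the theoretical dose, the ratio and the ratio sigma.
    """
    theory = theoretical_fano_dose(config.wall_material,
                                   config.beam_energy)
    rows = []
    for i, f_E in enumerate(config.f_E_values):
        sim, beam, _ = build_fano_setup(config, f_E, ms_tables)
        diag = {}
        res = sim.run_beam(beam, config.histories, seed + 7919 * i, diag)
        norm = beam.field_area / (config.histories / config.n_batches)
        dose, sig = sim.tally.finalize_zone(CAVITY, norm)
        rows.append({
            "f_E": f_E,
            "dose": dose, "sigma": sig,
            "theory": theory,
            "ratio": dose / theory, "ratio_sigma": sig / theory,
            "diag": diag,
        })
    return rows
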