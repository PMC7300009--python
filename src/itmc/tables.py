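"""Per-material transport tables and run settings.

Tables are built once per (material, thresholds) combination on shared
log-energy grids, so the vectorized transport loops can gather values for
mixed-material particle batches with one ``searchsorted`` plus fancy
indexing.  Cross sections and stopping powers scale linearly with local
density; voxel density overrides multiply by ``rho / rho_ref``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import Material
from .sampling_tables import (
    build_brems_k_table,
    build_coherent_mu_map,
    build_incoherent_mu_map,
    build_compton_profile_tables,
    build_moller_w_table,
)
from . import xs

#: shared electron kinetic-energy grid (MeV)
ELEC_GRID = np.geomspace(5e-4, 100.0, 240)
LOG_ELEC_GRID = np.log(ELEC_GRID)

#: shared photon energy grid (MeV)
PHOT_GRID = np.geomspace(1e-3, 100.0, 240)
LOG_PHOT_GRID = np.log(PHOT_GRID)


@dataclass(frozen=True)
class TransportSettings:
    """Physics thresholds and step-size limits (cm / MeV units)."""

    photon_cutoff: float = 0.010
    electron_cutoff: float = 0.189      # kinetic energy
    E_M: float = 0.200                  # Moller (knock-on) threshold
    E_B: float = 0.010                  # bremsstrahlung threshold
    S_MAX: float = 5.0                  # global step cap (cm)
    f_E: float = 0.25                   # max fractional energy loss / step
    N_k: int = 300                      # skin depth in elastic MFPs
    doppler: str = "auto"               # on | off | auto (< 1 MeV)
    pe_biased_fluorescence: bool = False
    roulette_survival: float = 1.0      # 1.0 disables roulette
    roulette_weight_floor: float = 0.0
    strict_positron_stop: bool = False  # deposit instead of annihilating
    multiple_scattering: bool = True    # off: straight CSDA slowing-down
    # Fano-mode idealizations
    fano_mode: bool = False
    xs_boost: float = 1.0
    brems_on: bool = True
    coherent_on: bool = True
    include_delta: bool = True
    free_electron_compton: bool = False
    regenerate_photons: bool = False
    range_rejection: bool = False

    def __post_init__(self):
        if not 0.0 < self.f_E < 1.0:
            raise ValueError("f_E must be in (0, 1)")
        if min(self.S_MAX, self.N_k, self.E_B, self.E_M,
               self.electron_cutoff, self.photon_cutoff) <= 0:
            raise ValueError("limits must be positive")

    @staticmethod
    def fano(f_E: float = 0.1, boost: float = 100.0) -> "TransportSettings":
        """The idealized cavity-test configuration: scattered-photon
        regeneration, bremsstrahlung and coherent scattering disabled, no
        density correction, 10 keV / 1 keV cutoffs, boosted photon cross
        section, free-electron Compton sampling."""
        return TransportSettings(
            photon_cutoff=0.010, electron_cutoff=0.001, f_E=f_E,
            doppler="off", fano_mode=True, xs_boost=boost, brems_on=False,
            coherent_on=False, include_delta=False,
            free_electron_compton=True, regenerate_photons=True,
            range_rejection=True)


def interp_stacked(stack: np.ndarray, log_grid: np.ndarray,
                   mat_idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Linear interpolation of per-material rows at log(x)."""
    lx = np.log(np.clip(x, math.exp(log_grid[0]), math.exp(log_grid[-1])))
    i = np.clip(np.searchsorted(log_grid, lx) - 1, 0, log_grid.size - 2)
    f = (lx - log_grid[i]) / (log_grid[i + 1] - log_grid[i])
    return (1.0 - f) * stack[mat_idx, i] + f * stack[mat_idx, i + 1]


@dataclass
class MaterialTables:
    """Everything the transport loops evaluate for one material."""

    material: Material
    settings: TransportSettings
    # photon side
    sigma_total: np.ndarray = field(repr=False, default=None)
    branch_cdf: np.ndarray = field(repr=False, default=None)  # (4, nE)
    mu_coherent: object = None
    mu_incoherent: object = None
    pe_elem_cdf: np.ndarray = field(repr=False, default=None)
    # electron side
    L: np.ndarray = field(repr=False, default=None)
    sigma_moller: np.ndarray = field(repr=False, default=None)
    sigma_brems: np.ndarray = field(repr=False, default=None)
    sigma_cat: np.ndarray = field(repr=False, default=None)
    sigma_majorant: np.ndarray = field(repr=False, default=None)
    eta: np.ndarray = field(repr=False, default=None)
    sigma_sr: np.ndarray = field(repr=False, default=None)
    mass_range: np.ndarray = field(repr=False, default=None)  # g/cm^2
    moller_w: object = None
    brems_k: object = None
    profiles: dict = field(repr=False, default=None)


def build_material_tables(material: Material,
                          settings: TransportSettings) -> MaterialTables:
    t = MaterialTables(material=material, settings=settings)
    # ---- photon ----
    sig = {}
    for ch in xs.PHOTON_CHANNELS:
        tot = np.zeros_like(PHOT_GRID)
        for elem, n in zip(material.elements, material.number_densities):
            tot += n * xs.element_photon_xs(elem, PHOT_GRID, ch)
        sig[ch] = tot
    if not settings.coherent_on:
        sig["coherent"] = np.zeros_like(PHOT_GRID)
    if settings.fano_mode:
        # idealized test: the only active channel is Compton
        sig["photoelectric"] = np.zeros_like(PHOT_GRID)
        sig["pair"] = np.zeros_like(PHOT_GRID)
    order = ("coherent", "incoherent", "photoelectric", "pair")
    stack = np.array([sig[ch] for ch in order])
    t.sigma_total = stack.sum(axis=0) * settings.xs_boost
    with np.errstate(invalid="ignore", divide="ignore"):
        t.branch_cdf = np.cumsum(stack, axis=0) / stack.sum(axis=0)
    t.mu_coherent = build_coherent_mu_map(material)
    t.mu_incoherent = build_incoherent_mu_map(
        material, free_electron=settings.free_electron_compton)
    pe_stack = np.array(
        [n * xs.photoelectric(elem, PHOT_GRID)[0]
         for elem, n in zip(material.elements, material.number_densities)])
    tot_pe = np.maximum(pe_stack.sum(axis=0), 1e-300)
    t.pe_elem_cdf = np.cumsum(pe_stack, axis=0) / tot_pe
    t.profiles = {elem.symbol: build_compton_profile_tables(elem)
                  for elem in material.elements}
    # ---- electron ----
    T = ELEC_GRID
    t.L = xs.restricted_stopping_power(
        T, material, settings.E_M, settings.E_B,
        include_delta=settings.include_delta)
    if not settings.brems_on:
        # radiative losses disabled entirely: collision term only
        t.L = t.L - _lb_only(material, settings.E_B, T)
    sig_m = xs.moller_xs(T, settings.E_M, material)
    sig_b = xs.brems_xs(T, settings.E_B, material) \
        if settings.brems_on else np.zeros_like(T)
    t.sigma_moller = sig_m
    t.sigma_brems = sig_b
    t.sigma_cat = sig_m + sig_b
    # majorant over the energy window one step can span
    window = 1.0 - settings.f_E
    maj = t.sigma_cat.copy()
    for j in range(T.size):
        lo = np.searchsorted(T, window * T[j])
        maj[j] = t.sigma_cat[max(lo - 1, 0):j + 1].max(initial=maj[j])
    t.sigma_majorant = maj * 1.02
    t.eta, t.sigma_sr = xs.elastic_parameters(T, material)
    # cumulative CSDA-style mass range from the restricted stopping power
    inv = material.mass_density / t.L
    dr = 0.5 * (inv[1:] + inv[:-1]) * np.diff(T)
    t.mass_range = np.concatenate([[T[0] * inv[0]], T[0] * inv[0]
                                   + np.cumsum(dr)])
    t.moller_w = build_moller_w_table(material, settings.E_M)
    if settings.brems_on:
        t.brems_k = build_brems_k_table(material, settings.E_B)
    return t


def _lb_only(material: Material, E_B: float, T: np.ndarray) -> np.ndarray:
    beta2 = 1.0 - 1.0 / (1.0 + T / 0.51099895) ** 2
    out = np.zeros_like(T)
    eb = np.minimum(E_B, T)
    for elem, n in zip(material.elements, material.number_densities):
        out += (elem.brems_a * n * elem.Z**2 * eb / beta2
                * (1.0 - elem.brems_b * eb / (2.0 * T)))
    return out


class TableSet:
    """Tables for every material in a run, with stacked gather arrays."""

    def __init__(self, materials: list[Material],
                 settings: TransportSettings):
        self.settings = settings
        self.materials = materials
        self.per_mat = [build_material_tables(m, settings)
                        for m in materials]
        self.sigma_total = np.stack([t.sigma_total for t in self.per_mat])
        self.branch_cdf = np.stack([t.branch_cdf for t in self.per_mat])
        self.L = np.stack([t.L for t in self.per_mat])
        self.sigma_moller = np.stack([t.sigma_moller for t in self.per_mat])
        self.sigma_brems = np.stack([t.sigma_brems for t in self.per_mat])
        self.sigma_cat = np.stack([t.sigma_cat for t in self.per_mat])
        self.sigma_majorant = np.stack(
            [t.sigma_majorant for t in self.per_mat])
        self.eta = np.stack([t.eta for t in self.per_mat])
        self.sigma_sr = np.stack([t.sigma_sr for t in self.per_mat])
        self.mass_range = np.stack([t.mass_range for t in self.per_mat])
        self.rho = np.array([m.mass_density for m in materials])

    def index_of(self, material: Material) -> int:
        return self.materials.index(material)


_TABLE_SET_CACHE: dict = {}


def get_table_set(materials: list[Material],
                  settings: TransportSettings) -> TableSet:
    """Cached TableSet lookup keyed by material names and settings."""
    key = (tuple(m.name for m in materials), settings)
    if key not in _TABLE_SET_CACHE:
        if len(_TABLE_SET_CACHE) > 32:
            _TABLE_SET_CACHE.clear()
        _TABLE_SET_CACHE[key] = TableSet(materials, settings)
    return _TABLE_SET_CACHE[key]
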