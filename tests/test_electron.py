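"""Condensed-history electron transport: step algebra, catastrophic
events, conservation and slowing-down oracles."""

import math

import numpy as np
import pytest

from itmc.constants import M_E_C2
from itmc.electron import (
    brems_photon_angle,
    equivalent_energy,
    moller_angles,
    transport_electrons,
)
from itmc.engine import slab_phantom_simulation
from itmc.geometry import VoxelGrid
from itmc.materials import get_material
from itmc.medium import VoxelMedium
from itmc.particles import Bank, make_state
from itmc.sources import BeamSpec
from itmc.tables import (
    LOG_ELEC_GRID,
    TransportSettings,
    get_table_set,
    interp_stacked,
)
from itmc.tally import DoseTally, extract_pdd
from itmc import xs


class TestEquivalentEnergy:
    def test_zero_step_is_identity(self, water):
        L = lambda T: xs.restricted_stopping_power(T, water, 0.2, 0.01)
        assert equivalent_energy(1.0, 0.0, L) == pytest.approx(1.0)

    def test_strictly_decreasing_in_path(self, water):
        L = lambda T: xs.restricted_stopping_power(T, water, 0.2, 0.01)
        s = np.linspace(0, 0.3, 20)
        vals = equivalent_energy(np.full(20, 1.0), s, L)
        assert np.all(np.diff(vals) < 0)

    def test_matches_fine_step_slowing_down(self, water):
        """Mid-step recipe vs 100-substep numerical integration."""
        L = lambda T: xs.restricted_stopping_power(T, water, 0.2, 0.01)
        T0 = 2.0
        S = 0.25 * T0 / float(L(np.array([T0]))[0])      # one S_E step
        # reference: integrate dT/ds = -L over the step
        T = T0
        for _ in range(100):
            T -= float(L(np.array([T]))[0]) * S / 100
        dE_fine = T0 - T
        T_til = float(equivalent_energy(np.array([T0]), np.array([S]),
                                        L)[0])
        dE_mid = S * float(L(np.array([T_til]))[0])
        assert dE_mid == pytest.approx(dE_fine, rel=5e-3)


class TestMollerEvent:
    def test_forward_limit(self):
        assert moller_angles(1.0, 1.0) == pytest.approx(1.0)

    def test_equal_split_value(self):
        # T = 1.022, T' = 0.511: cos(theta) = sqrt(0.5*2.044/1.533)
        got = moller_angles(2 * M_E_C2, M_E_C2)
        assert got == pytest.approx(0.8165, abs=2e-4)

    def test_event_conservation(self, rng, water):
        settings = TransportSettings(E_M=0.2)
        tset = get_table_set([get_material("water")], settings)
        eps = tset.per_mat[0].moller_w.sample(rng.random(5000),
                                              np.full(5000, np.log(2.0)))
        W = eps * 2.0
        assert np.all(W >= 0.2 - 1e-9) and np.all(W <= 1.0 + 1e-9)


class TestBremsEvent:
    def test_photon_angle_formula(self):
        assert float(brems_photon_angle(10.0)) == pytest.approx(
            0.511 / 10.511, rel=1e-3)

    def test_energy_sharing(self, rng):
        settings = TransportSettings()
        tset = get_table_set([get_material("water")], settings)
        T = 5.0
        k = tset.per_mat[0].brems_k.sample(rng.random(5000),
                                           np.full(5000, np.log(T)))
        assert np.all(k >= 0.01 / T - 1e-9)
        # photon kT + electron (1-k)T = T trivially; support is the check
        assert np.all(k <= 1.0 + 1e-9)


def _uniform_block(material_name, settings, size=50.0):
    m = get_material(material_name)
    tset = get_table_set([m], settings)
    g = VoxelGrid((-size / 2, -size / 2, -size / 2), (2, 2, 2),
                  (size / 2, size / 2, size / 2))
    g.density[:] = m.mass_density
    med = VoxelMedium(g, [material_name], np.array([m.mass_density]))
    return tset, med, g


class TestTransport:
    def test_energy_ledger_closes(self, ms_tables):
        settings = TransportSettings()
        tset, med, g = _uniform_block("water", settings)
        tally = DoseTally(g, 2)
        n = 300
        st = make_state(np.tile([0.0, 0, 0], (n, 1)),
                        np.tile([0.0, 0, 1.0], (n, 1)),
                        np.full(n, 5.0), np.ones(n), np.zeros(n, int),
                        q=np.zeros(n))
        p_bank, e_bank = Bank(), Bank()
        diag = {}
        transport_electrons(st, med, tset, tally,
                            np.random.default_rng(2), p_bank, diag,
                            ms_tables, electron_bank=e_bank)
        while len(e_bank):
            transport_electrons(e_bank.pop(None), med, tset, tally,
                                np.random.default_rng(3), p_bank, diag,
                                ms_tables, electron_bank=e_bank)
        total = tally.total_energy + p_bank.energy
        assert total == pytest.approx(n * 5.0, rel=1e-9)

    def test_csda_range_oracle(self, ms_tables):
        """MS off + catastrophic channels off: the track ends at the
        range integral int dT/L within 2%."""
        settings = TransportSettings(multiple_scattering=False,
                                     E_M=60.0, brems_on=False)
        sim = slab_phantom_simulation(
            [("water", 3.0)], None, nxy=3, dxy=4.0, dz=0.01,
            settings=settings, n_batches=2, ms_tables=ms_tables)
        beam = BeamSpec("electron", ("mono", 2.0),
                        ("parallel", 0.5, 0.5, 0.0))
        res = sim.run_beam(beam, 400, seed=6)
        pdd = extract_pdd(res.dose)
        z = (np.arange(pdd.size) + 0.5) * 0.01
        end = z[np.nonzero(pdd > 0)[0][-1]]
        r = interp_stacked(sim.tset.mass_range, LOG_ELEC_GRID,
                           np.array([0, 0]),
                           np.array([2.0, settings.electron_cutoff]))
        expected = r[0] - r[1]      # tracks stop at the energy cutoff
        assert end == pytest.approx(expected, rel=0.02)

    def test_hinge_reduces_to_straight_line_without_ms(self, ms_tables):
        """With deflection forced off the endpoint lies on the initial
        axis: the hinge preserves total path length exactly."""
        settings = TransportSettings(multiple_scattering=False,
                                     E_M=60.0, brems_on=False)
        tset, med, g = _uniform_block("water", settings)
        tally = DoseTally(g, 2)
        st = make_state([[0.0, 0, -24.0]], [[0.0, 0, 1.0]], [1.0], [1.0],
                        [0], q=[0])
        diag = {}
        transport_electrons(st, med, tset, tally,
                            np.random.default_rng(1), Bank(), diag,
                            ms_tables, electron_bank=Bank())
        # the whole track stays on the +z axis: all energy lands in the
        # single voxel column the electron entered
        dose = tally.energy.sum(axis=0).reshape(g.shape, order="F")
        assert dose[1, 1, 0] == pytest.approx(1.0, rel=1e-9)

    def test_catastrophic_event_rate(self, ms_tables, rng):
        """Null-event (fictitious interaction) bookkeeping: the realized
        number of Moller events along full tracks matches a fine-step
        integration of Sigma_M over the slowing-down trajectory."""
        settings = TransportSettings(multiple_scattering=False,
                                     brems_on=False, E_M=0.2)
        tset, med, g = _uniform_block("water", settings)
        tally = DoseTally(g, 2)
        n = 4000
        T0 = 2.0
        st = make_state(np.tile([0.0, 0, 0], (n, 1)),
                        np.tile([0.0, 0, 1.0], (n, 1)),
                        np.full(n, T0), np.ones(n), np.zeros(n, int),
                        q=np.zeros(n))
        diag = {}
        transport_electrons(st, med, tset, tally,
                            np.random.default_rng(8), Bank(), diag,
                            ms_tables, electron_bank=Bank())
        got = diag.get("moller", 0) / n
        # fine-step energy-domain oracle: march every track (primaries
        # and knock-ons) down in tiny steps, firing events at the local
        # Sigma_M(T), with knock-on energies drawn by rejection
        w = get_material("water")
        T_grid = np.geomspace(settings.electron_cutoff, T0, 600)
        sig_g = xs.moller_xs(T_grid, 0.2, w)
        L_g = xs.restricted_stopping_power(T_grid, w, 0.2, 1e-12)
        orng = np.random.default_rng(123)
        n_o = 500
        events = 0
        for _ in range(n_o):
            stack = [T0]
            while stack:
                T = stack.pop()
                while T > settings.electron_cutoff:
                    L = np.interp(T, T_grid, L_g)
                    sig = np.interp(T, T_grid, sig_g)
                    ds = 0.004 * T / L
                    if T > 0.4 and orng.random() < sig * ds:
                        events += 1
                        while True:        # rejection draw of W
                            W = 0.2 + orng.random() * (T / 2 - 0.2)
                            f = float(xs.moller_dcs(T, W))
                            if orng.random() * float(
                                    xs.moller_dcs(T, 0.2)) < f:
                                break
                        T -= W
                        if W > settings.electron_cutoff:
                            stack.append(W)
                    else:
                        T -= L * ds
        expected = events / n_o
        sd = math.sqrt(expected) * math.sqrt(1 / n + 1 / n_o)
        assert got == pytest.approx(expected, abs=max(3.0 * sd,
                                                      0.015 * expected))

    def test_positron_annihilation_photons(self, ms_tables):
        settings = TransportSettings()
        tset, med, g = _uniform_block("water", settings)
        tally = DoseTally(g, 2)
        st = make_state([[0.0, 0, 0]], [[0.0, 0, 1.0]], [0.05], [1.0],
                        [0], q=[1])
        p_bank = Bank()
        transport_electrons(st, med, tset, tally,
                            np.random.default_rng(0), p_bank, {},
                            ms_tables, electron_bank=Bank())
        ph = p_bank.pop(None)
        assert ph["E"].size == 2
        assert np.allclose(ph["E"], M_E_C2)
        # back-to-back
        assert np.allclose(ph["dir"][0], -ph["dir"][1])

    def test_mean_deflection_identity(self, ms_tables, rng):
        """<mu> over many single condensed steps equals exp(-t g1)."""
        from itmc.mscatter import gs_moment
        t, eta = 50.0, 1e-4
        n = 100_000
        mu = ms_tables.sample_mu(rng.random(n), np.full(n, t),
                                 np.full(n, eta))
        want = math.exp(-t * gs_moment(1, eta))
        sd = math.sqrt(np.var(mu) / n)
        assert abs(mu.mean() - want) < 3 * sd
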