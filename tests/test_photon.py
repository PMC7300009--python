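"""Photon transport: free paths, interaction channels, conservation."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare, ks_1samp

from itmc import xs
from itmc.constants import M_E_C2, PAIR_THRESHOLD
from itmc.geometry import VoxelGrid
from itmc.materials import get_material
from itmc.medium import VoxelMedium
from itmc.particles import Bank, make_state
from itmc.photon import (
    compton_scatter,
    russian_roulette,
    sample_free_path,
    transport_photons,
)
from itmc.tables import TransportSettings, get_table_set
from itmc.tally import DoseTally


def _water_setup(settings=None, size=100.0, n_cells=4):
    w = get_material("water")
    settings = settings or TransportSettings()
    tset = get_table_set([w], settings)
    d = size / n_cells
    g = VoxelGrid((-size / 2, -size / 2, 0.0),
                  (n_cells, n_cells, n_cells), (d, d, d))
    med = VoxelMedium(g, ["water"], np.array([1.0]))
    return tset, med, g


class TestFreePath:
    def test_xi_one_gives_zero(self):
        assert sample_free_path(2.0, 1.0) == 0.0

    def test_mean_is_inverse_sigma(self, rng):
        sig = 0.31
        s = sample_free_path(np.full(100_000, sig),
                             1.0 - rng.random(100_000))
        sd = s.std() / math.sqrt(s.size)
        assert abs(s.mean() - 1 / sig) < 3 * sd

    def test_doubling_sigma_halves_mean(self, rng):
        xi = 1.0 - rng.random(50_000)
        a = sample_free_path(np.full(xi.size, 0.2), xi)
        b = sample_free_path(np.full(xi.size, 0.4), xi)
        assert np.allclose(a, 2 * b)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sample_free_path(0.0, 0.5)
        with pytest.raises(ValueError):
            sample_free_path(1.0, 0.0)


class TestRoulette:
    def test_certain_survival(self):
        alive, w = russian_roulette(np.ones(10), 1.0, np.zeros(10))
        assert alive.all() and np.allclose(w, 1.0)

    def test_kill_case(self):
        alive, _ = russian_roulette(np.ones(1), 0.5, np.array([0.7]))
        assert not alive[0]

    def test_unbiased_weight(self, rng):
        n = 100_000
        alive, w = russian_roulette(np.ones(n), 0.3, rng.random(n))
        surviving = w[alive].sum() / n
        sd = math.sqrt(0.3 * 0.7 / n) / 0.3
        assert abs(surviving - 1.0) < 3 * sd


class TestComptonEvent:
    def test_pz_zero_reduces_to_free_value(self, water):
        tset, _, _ = _water_setup()
        a = np.array([2.0])
        mu = np.array([0.0])
        ap, eb = compton_scatter(a, mu, np.random.default_rng(0),
                                 tset.per_mat[0], doppler=False)
        assert ap[0] == pytest.approx(a[0] / (1 + a[0]), rel=1e-12)
        assert eb[0] == 0.0

    def test_doppler_broadens_at_fixed_angle(self, rng):
        tset, _, _ = _water_setup()
        n = 4000
        a = np.full(n, 0.5 / M_E_C2)
        mu = np.zeros(n)
        ap_off, _ = compton_scatter(a, mu, rng, tset.per_mat[0], False)
        ap_on, _ = compton_scatter(a, mu, rng, tset.per_mat[0], True)
        assert np.var(ap_off) < 1e-30      # roundoff only
        assert np.var(ap_on) > 1e-6

    def test_energy_balance_per_event(self, rng):
        tset, _, _ = _water_setup()
        n = 2000
        a = np.full(n, 1.0 / M_E_C2)
        mu = rng.uniform(-1, 1, n)
        ap, eb = compton_scatter(a, mu, rng, tset.per_mat[0], True)
        T_e = (a - ap) * M_E_C2 - eb
        # E = E' + T + E_binding restores the incident energy exactly
        total = ap * M_E_C2 + T_e + eb
        assert np.allclose(total, 1.0, atol=1e-12)
        assert np.all(T_e > -1e-12)


class TestTransport:
    def test_vacuum_phantom_escapes(self):
        settings = TransportSettings()
        w = get_material("water")
        tset = get_table_set([w], settings)
        g = VoxelGrid((-5, -5, 0), (2, 2, 2), (5, 5, 5))
        g.density[:] = 1e-12          # effectively vacuum
        med = VoxelMedium(g, ["water"], np.array([1.0]))
        tally = DoseTally(g, 2)
        st = make_state([[0, 0, 0.01]], [[0, 0, 1.0]], [1.0], [1.0], [0])
        diag = {}
        transport_photons(st, med, tset, tally, np.random.default_rng(0),
                          Bank(), Bank(), diag)
        assert tally.escaped.sum() == pytest.approx(1.0)
        assert tally.energy.sum() < 1e-9

    def test_energy_ledger_closes(self, rng):
        tset, med, g = _water_setup(size=60.0, n_cells=3)
        tally = DoseTally(g, 2)
        n = 400
        st = make_state(np.tile([0.0, 0, 0.01], (n, 1)),
                        np.tile([0.0, 0, 1.0], (n, 1)),
                        np.full(n, 1.25), np.ones(n),
                        np.zeros(n, int))
        e_bank, p_bank = Bank(), Bank()
        diag = {}
        transport_photons(st, med, tset, tally,
                          np.random.default_rng(11), e_bank, p_bank, diag)
        total = tally.total_energy + e_bank.energy + p_bank.energy
        assert total == pytest.approx(n * 1.25, rel=1e-9)

    def test_two_slab_transmission(self, rng):
        """Piecewise exponential attenuation through two materials.

        At 12 keV the photoelectric channel dominates, so escaping
        photons are (almost all) photons that never interacted."""
        settings = TransportSettings()
        w = get_material("water")
        b = get_material("cortical_bone")
        tset = get_table_set([w, b], settings)
        d1 = d2 = 0.04
        g = VoxelGrid((-10, -10, 0), (1, 1, 2), (20, 20, d1))
        g.material_index = np.array([[[0, 1]]], dtype=np.int16)
        g.density = np.array([[[w.mass_density, b.mass_density]]])
        med = VoxelMedium(g, ["water", "cortical_bone"],
                          np.array([w.mass_density, b.mass_density]))
        tally = DoseTally(g, 2)
        E = 0.012
        s1 = float(xs.photon_macro_xs(w, np.array([E]))[0][0])
        s2 = float(xs.photon_macro_xs(b, np.array([E]))[0][0])
        expect = math.exp(-s1 * d1 - s2 * d2)
        n = 40_000
        st = make_state(np.tile([0.0, 0, 1e-6], (n, 1)),
                        np.tile([0.0, 0, 1.0], (n, 1)),
                        np.full(n, E), np.ones(n), np.zeros(n, int))
        diag = {}
        transport_photons(st, med, tset, tally,
                          np.random.default_rng(4), Bank(), Bank(), diag)
        got = diag.get("photon_escaped", 0) / n
        sd = math.sqrt(expect * (1 - expect) / n)
        assert abs(got - expect) < max(3 * sd, 0.01)

    def test_interaction_count_matches_analog_oracle(self, rng):
        """Mean number of photon interactions before absorption at
        50 keV in (effectively infinite) water: engine vs an independent
        scalar Monte Carlo built on rejection sampling."""
        E0, cutoff = 0.05, 0.01
        w = get_material("water")

        def oracle_counts(n):
            out = np.empty(n)
            for i in range(n):
                E, count = E0, 0
                while True:
                    count += 1
                    tot, probs = xs.photon_macro_xs(w, np.array([E]))
                    u = rng.random()
                    p_coh = float(probs["coherent"][0])
                    p_inc = p_coh + float(probs["incoherent"][0])
                    if u < p_coh:
                        continue
                    if u >= p_inc:          # photoelectric: absorbed
                        break
                    a = E / M_E_C2
                    # rejection sampling of the bound-Compton angle;
                    # envelope: n_e * 2 pi r_e^2 bounds n S K everywhere
                    env = 0.2
                    while True:
                        mu = rng.uniform(-1, 1)
                        f = sum(nn * float(xs.incoherent_dcs(el, E, mu))
                                for el, nn in zip(w.elements,
                                                  w.number_densities))
                        if rng.random() * env < f:
                            break
                    E = float(a / (1 + a * (1 - mu))) * M_E_C2
                    if E < cutoff:
                        break
                out[i] = count
            return out

        n_oracle = 600
        counts = oracle_counts(n_oracle)
        tset, med, g = _water_setup(size=400.0, n_cells=2)
        tally = DoseTally(g, 2)
        n = 3000
        st = make_state(np.tile([0.0, 0, 200.0], (n, 1)),
                        np.tile([0.0, 0, 1.0], (n, 1)),
                        np.full(n, E0), np.ones(n), np.zeros(n, int))
        diag = {}
        transport_photons(st, med, tset, tally,
                          np.random.default_rng(9), Bank(), Bank(), diag)
        engine_mean = (diag.get("coherent", 0) + diag.get("incoherent", 0)
                       + diag.get("photoelectric", 0)) / n
        sd = counts.std() * math.sqrt(1 / n_oracle + 1 / n)
        assert abs(engine_mean - counts.mean()) < 3.5 * sd


class TestPairEvent:
    def test_energy_split_conservation_and_uniformity(self, rng):
        tset, med, g = _water_setup(size=3000.0, n_cells=2)
        tally = DoseTally(g, 2)
        n = 3000
        E0 = 12.0
        st = make_state(np.tile([0.0, 0, 0.01], (n, 1)),
                        np.tile([0.0, 0, 1.0], (n, 1)),
                        np.full(n, E0), np.ones(n), np.zeros(n, int))
        e_bank = Bank()
        diag = {}
        # force the pair channel by zeroing other columns of the branch cdf
        import copy
        ts2 = copy.copy(tset)
        ts2.branch_cdf = np.zeros_like(tset.branch_cdf)
        transport_photons(st, med, ts2, tally,
                          np.random.default_rng(3), e_bank, Bank(), diag)
        assert diag["pair"] == n
        chunks = e_bank.pop(None)
        assert chunks["E"].size == 2 * n
        kin = chunks["E"].reshape(2, -1) if False else None
        total = chunks["E"].sum() / n
        assert total == pytest.approx(E0 - PAIR_THRESHOLD, rel=1e-9)
        # the electron share is uniform on (0, E - 2 m_e c^2)
        elec = chunks["E"][chunks["q"] == 0]
        u = elec / (E0 - PAIR_THRESHOLD)
        assert ks_1samp(u, lambda x: x).pvalue > 0.01


class TestPhotoelectricEvent:
    def test_photoelectron_energy(self):
        el = get_material("graphite").elements[0]
        eb = el.binding_energies["K"]
        assert eb == pytest.approx(2.842e-4, rel=1e-3)
        assert 0.100 - eb == pytest.approx(0.0997, abs=2e-4)

    def test_subshell_frequencies_match_probabilities(self, rng):
        """Sampled subshell choice follows sigma_i / sigma_pe."""
        el = get_material("aluminum").elements[0]
        E = np.array([0.01])
        _, probs = xs.photoelectric(el, E)
        p = probs[:, 0]
        n = 100_000
        cdf = np.cumsum(p)
        pick = np.minimum((rng.random(n)[:, None] >= cdf).sum(axis=1),
                          p.size - 1)
        counts = np.bincount(pick, minlength=p.size)
        keep = p > 1e-4
        res = chisquare(counts[keep], n * p[keep] / p[keep].sum())
        assert res.pvalue > 0.01

    def test_biased_fluorescence_unbiased_in_expectation(self, rng):
        """Weighted fluorescence energy in biased mode matches the
        analog expectation."""
        settings_a = TransportSettings(photon_cutoff=0.001)
        settings_b = TransportSettings(photon_cutoff=0.001,
                                       pe_biased_fluorescence=True)
        fe = get_material("steel")
        out = {}
        for tag, settings in (("analog", settings_a),
                              ("biased", settings_b)):
            tset = get_table_set([fe], settings)
            g = VoxelGrid((-10, -10, 0), (1, 1, 1), (20, 20, 0.0005))
            g.density[:] = fe.mass_density
            med = VoxelMedium(g, ["steel"],
                              np.array([fe.mass_density]))
            tally = DoseTally(g, 2)
            n = 60_000
            st = make_state(np.tile([0.0, 0, 1e-6], (n, 1)),
                            np.tile([0.0, 0, 1.0], (n, 1)),
                            np.full(n, 0.02), np.ones(n),
                            np.zeros(n, int))
            p_bank = Bank()
            diag = {}
            transport_photons(st, med, tset, tally,
                              np.random.default_rng(7), Bank(), p_bank,
                              diag)
            fl = p_bank.pop(None)
            out[tag] = 0.0 if fl is None else \
                float(np.sum(fl["E"] * fl["wt"])) / n
        assert out["biased"] == pytest.approx(out["analog"], rel=0.1)
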