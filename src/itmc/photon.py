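"""Analog photon transport.

History loop: exponential free path with the local total cross section,
one-random-number branch selection among {coherent, incoherent,
photoelectric, pair}, and inverse-CDF sampling inside every channel.
Histories end at the energy cutoff (local deposit), by Russian roulette
when enabled, or by leaving the system.  Secondaries go to the electron /
photon banks.

In the Fano idealization the scattered photon is discarded and the
incident photon is regenerated in place (same energy and direction), so
the primary fluence is uniform and unattenuated; recoil electrons carry
weight 1/boost to compensate the cross-section boost.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import M_E_C2, PAIR_THRESHOLD
from .kinematics import isotropic_directions, rotate_direction
from .particles import make_state, select
from .tables import LOG_PHOT_GRID, TableSet, interp_stacked

_MAX_LOOPS = 200_000


def sample_free_path(sigma_total, xi):
    """Exponential free path -ln(xi)/Sigma; xi in (0, 1]."""
    sigma = np.asarray(sigma_total, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(sigma <= 0.0):
        raise ValueError("total cross section must be positive")
    if np.any((xi <= 0.0) | (xi > 1.0)):
        raise ValueError("xi must lie in (0, 1]")
    return -np.log(xi) / sigma


def russian_roulette(weights, survival_prob, xi):
    """(survivor mask, adjusted weights); unbiased in expectation."""
    if not 0.0 < survival_prob <= 1.0:
        raise ValueError("survival probability must be in (0, 1]")
    xi = np.asarray(xi, dtype=float)
    alive = xi < survival_prob
    return alive, np.asarray(weights, dtype=float) / survival_prob


def compton_scatter(alpha, mu, rng, mtab, doppler: bool, diag=None):
    """Scattered photon energy alpha' and binding deposit per event.

    Free kinematics when ``doppler`` is off.  Doppler path: select a
    subshell by occupancy among those energetically open, draw the
    projected momentum p_z from the shell Compton profile (one uniform
    number through its inverse CDF), and solve the broadened-energy
    relation for alpha'; kinematically impossible draws are retried once,
    then fall back to p_z = 0 (counted).
    Returns (alpha_prime, binding_deposit_MeV).
    """
    alpha = np.asarray(alpha, dtype=float)
    mu = np.asarray(mu, dtype=float)
    free = alpha / (1.0 + alpha * (1.0 - mu))
    if not doppler:
        return free, np.zeros_like(alpha)
    material = mtab.material
    shells = [(elem, sh, n * sh.occupancy)
              for elem, n in zip(material.elements,
                                 material.number_densities)
              for sh in elem.shells]
    weights = np.array([w for _, _, w in shells])
    binding = np.array([sh.binding_energy for _, sh, _ in shells])
    open_mask = binding[None, :] < (alpha * M_E_C2)[:, None]
    w = weights[None, :] * open_mask
    cdf = np.cumsum(w, axis=1)
    pick = (rng.random(alpha.size) * cdf[:, -1])[:, None]
    shell_idx = np.minimum(np.sum(pick >= cdf, axis=1), len(shells) - 1)

    a_prime = np.empty_like(alpha)
    e_bind = binding[shell_idx]
    fallbacks = 0
    for attempt in range(2):
        todo = np.isnan(a_prime) if attempt else np.ones(alpha.size, bool)
        if not np.any(todo):
            break
        pz = np.empty(alpha.size)
        for s_i in np.unique(shell_idx[todo]):
            elem, sh, _ = shells[s_i]
            m = todo & (shell_idx == s_i)
            table = mtab.profiles[elem.symbol][sh.label]
            pz[m] = table.sample(rng.random(int(m.sum())))
        kappa = pz / 137.036
        A1 = 1.0 + alpha * (1.0 - mu)
        aa = A1**2 - kappa**2
        bb = -2.0 * alpha * (A1 - kappa**2 * mu)
        cc = alpha**2 * (1.0 - kappa**2)
        disc = bb**2 - 4.0 * aa * cc
        with np.errstate(invalid="ignore", divide="ignore"):
            sq = np.sqrt(np.clip(disc, 0.0, None))
            r1 = (-bb - sq) / (2.0 * aa)
            r2 = (-bb + sq) / (2.0 * aa)
        # the physical root has sign(alpha' A1 - alpha) == sign(kappa)
        want = np.sign(kappa)
        ok1 = (np.sign(r1 * A1 - alpha) == want) | (kappa == 0.0)
        cand = np.where(ok1, r1, r2)
        e_max = alpha - e_bind / M_E_C2
        good = (disc >= 0.0) & (cand > 0.0) & (cand <= e_max) & todo
        a_prime[todo] = np.nan
        a_prime[good] = cand[good]
    bad = np.isnan(a_prime)
    if np.any(bad):
        fallbacks = int(bad.sum())
        a_prime[bad] = np.minimum(free[bad],
                                  alpha[bad] - e_bind[bad] / M_E_C2)
    if diag is not None:
        diag["doppler_fallback"] = diag.get("doppler_fallback", 0) \
            + fallbacks
    return a_prime, e_bind


def recoil_direction(alpha, alpha_prime, mu, dirs, phi):
    """Compton recoil electron direction from momentum conservation."""
    denom = np.sqrt(np.clip(alpha**2 + alpha_prime**2
                            - 2.0 * alpha * alpha_prime * mu, 1e-300, None))
    mu_e = np.clip((alpha - alpha_prime * mu) / denom, -1.0, 1.0)
    return rotate_direction(dirs, mu_e, phi + math.pi)


def transport_photons(state, medium, tset: TableSet, tally, rng,
                      electron_bank, photon_bank, diag) -> None:
    """Run a photon population to extinction; mutates tally and banks."""
    s = tset.settings
    n_mat = len(tset.materials)
    pos, dirs = state["pos"].copy(), state["dir"].copy()
    E, wt, batch = state["E"].copy(), state["wt"].copy(), \
        state["batch"].copy()
    for _ in range(_MAX_LOOPS):
        n = E.size
        if n == 0:
            return
        region = medium.locate(pos, dirs)
        outside = region < 0
        if np.any(outside):
            diag["photon_escaped"] = diag.get("photon_escaped", 0) \
                + int(outside.sum())
            tally.add_escaped(E[outside], wt[outside], batch[outside])
            keep = ~outside
            pos, dirs, E, wt, batch, region = (
                pos[keep], dirs[keep], E[keep], wt[keep], batch[keep],
                region[keep])
            if E.size == 0:
                return
        mat, rho_fac = medium.lookup(region)
        vac = mat < 0
        sigma = np.zeros(E.size)
        nz = ~vac
        sigma[nz] = interp_stacked(tset.sigma_total, LOG_PHOT_GRID,
                                   mat[nz], E[nz]) * rho_fac[nz]
        t_b = medium.boundary_distance(pos, dirs, region)
        with np.errstate(divide="ignore"):
            path = np.where(sigma > 0,
                            -np.log(1.0 - rng.random(E.size))
                            / np.maximum(sigma, 1e-300), np.inf)
        cross = path >= t_b
        step = np.where(cross, t_b + 1e-9, path)
        step = np.minimum(step, 1e9)
        pos = pos + dirs * step[:, None]
        inter = ~cross
        if not np.any(inter):
            continue
        # ---- interaction branch, one uniform number ----
        idx = np.nonzero(inter)[0]
        xi_b = rng.random(idx.size)
        m_i, E_i = mat[idx], E[idx]
        c_coh = interp_stacked(tset.branch_cdf[:, 0, :], LOG_PHOT_GRID,
                               m_i, E_i)
        c_inc = interp_stacked(tset.branch_cdf[:, 1, :], LOG_PHOT_GRID,
                               m_i, E_i)
        c_pe = interp_stacked(tset.branch_cdf[:, 2, :], LOG_PHOT_GRID,
                              m_i, E_i)
        channel = ((xi_b >= c_coh).astype(int) + (xi_b >= c_inc)
                   + (xi_b >= c_pe))
        kill = np.zeros(E.size, dtype=bool)

        for mi in range(n_mat):
            mtab = tset.per_mat[mi]
            msk = m_i == mi
            if not np.any(msk):
                continue
            # -------- coherent --------
            sel = idx[msk & (channel == 0)]
            if sel.size:
                diag["coherent"] = diag.get("coherent", 0) + sel.size
                mu = mtab.mu_coherent.sample(rng.random(sel.size),
                                             np.log(E[sel]))
                phi = 2.0 * math.pi * rng.random(sel.size)
                dirs[sel] = rotate_direction(dirs[sel], mu, phi)
            # -------- incoherent --------
            sel = idx[msk & (channel == 1)]
            if sel.size:
                diag["incoherent"] = diag.get("incoherent", 0) + sel.size
                alpha = E[sel] / M_E_C2
                mu = np.clip(mtab.mu_incoherent.sample(
                    rng.random(sel.size), np.log(E[sel])), -1.0, 1.0)
                use_doppler = {"on": True, "off": False}.get(
                    s.doppler, None)
                if use_doppler is None:
                    dop_mask = E[sel] < 1.0
                else:
                    dop_mask = np.full(sel.size, use_doppler)
                a_p = np.empty(sel.size)
                e_bind = np.zeros(sel.size)
                if np.any(~dop_mask):
                    a_p[~dop_mask], _ = compton_scatter(
                        alpha[~dop_mask], mu[~dop_mask], rng, mtab,
                        False)
                if np.any(dop_mask):
                    a_p[dop_mask], e_bind[dop_mask] = compton_scatter(
                        alpha[dop_mask], mu[dop_mask], rng, mtab, True,
                        diag)
                T_e = np.clip((alpha - a_p) * M_E_C2 - e_bind, 0.0, None)
                phi = 2.0 * math.pi * rng.random(sel.size)
                e_dir = recoil_direction(alpha, a_p, mu, dirs[sel], phi)
                e_wt = wt[sel] / (s.xs_boost if s.regenerate_photons
                                  else 1.0)
                live_e = T_e > s.electron_cutoff
                electron_bank.push(make_state(
                    pos[sel][live_e], e_dir[live_e], T_e[live_e],
                    e_wt[live_e], batch[sel][live_e],
                    q=np.zeros(int(live_e.sum()))))
                low_e = ~live_e
                medium.deposit(tally, region[sel][low_e], T_e[low_e],
                               e_wt[low_e], batch[sel][low_e])
                medium.deposit(tally, region[sel], e_bind, e_wt,
                               batch[sel])
                if s.regenerate_photons:
                    pass        # photon keeps its energy and direction
                else:
                    dirs[sel] = rotate_direction(dirs[sel], mu, phi)
                    E[sel] = a_p * M_E_C2
                    below = E[sel] < s.photon_cutoff
                    bsel = sel[below]
                    medium.deposit(tally, region[bsel], E[bsel], wt[bsel],
                                   batch[bsel])
                    kill[bsel] = True
            # -------- photoelectric --------
            sel = idx[msk & (channel == 2)]
            if sel.size:
                diag["photoelectric"] = diag.get("photoelectric", 0) \
                    + sel.size
                _photoelectric_events(
                    sel, pos, dirs, E, wt, batch, region, medium, tally,
                    rng, mtab, s, electron_bank, photon_bank)
                kill[sel] = True
            # -------- pair --------
            sel = idx[msk & (channel == 3)]
            if sel.size:
                diag["pair"] = diag.get("pair", 0) + sel.size
                if np.any(E[sel] < PAIR_THRESHOLD - 1e-9):
                    raise RuntimeError(
                        "pair production selected below threshold")
                _pair_events(sel, pos, dirs, E, wt, batch, rng,
                             electron_bank)
                kill[sel] = True
        # roulette on low-weight photons
        if s.roulette_survival < 1.0:
            cand = (~kill) & (wt < s.roulette_weight_floor)
            if np.any(cand):
                alive, neww = russian_roulette(
                    wt[cand], s.roulette_survival,
                    rng.random(int(cand.sum())))
                wt[cand] = neww
                dead = np.nonzero(cand)[0][~alive]
                diag["roulette_killed"] = diag.get("roulette_killed", 0) \
                    + dead.size
                kill[dead] = True
        keep = ~kill
        pos, dirs, E, wt, batch = (pos[keep], dirs[keep], E[keep],
                                   wt[keep], batch[keep])
    raise RuntimeError("photon loop exceeded iteration cap")


def _photoelectric_events(sel, pos, dirs, E, wt, batch, region, medium,
                          tally, rng, mtab, s, electron_bank, photon_bank):
    """Subshell selection, photoelectron, K fluorescence or local deposit."""
    material = mtab.material
    n = sel.size
    # element choice proportional to its macroscopic photoelectric xs
    n_elem = len(material.elements)
    xi = rng.random(n)
    elem_idx = np.zeros(n, dtype=int)
    for j in range(n_elem - 1):
        cdf_j = interp_stacked(mtab.pe_elem_cdf[j][None, :],
                               LOG_PHOT_GRID, np.zeros(n, int), E[sel])
        elem_idx += (xi >= cdf_j).astype(int)
    for j, elem in enumerate(material.elements):
        m = elem_idx == j
        if not np.any(m):
            continue
        g = sel[m]
        from .xs import photoelectric as pe_probs
        _, probs = pe_probs(elem, E[g])          # (n_shell, m)
        cdf = np.cumsum(probs, axis=0)
        pick = rng.random(g.size)
        sh_idx = np.minimum(np.sum(pick[None, :] >= cdf, axis=0),
                            len(elem.shells) - 1)
        e_bind = np.array([elem.shells[k].binding_energy
                           for k in sh_idx])
        T = np.clip(E[g] - e_bind, 0.0, None)
        live = T > s.electron_cutoff
        electron_bank.push(make_state(
            pos[g][live], dirs[g][live], T[live], wt[g][live],
            batch[g][live], q=np.zeros(int(live.sum()))))
        medium.deposit(tally, region[g][~live], T[~live], wt[g][~live],
                       batch[g][~live])
        # relaxation: K vacancies may fluoresce, others deposit locally
        is_k = sh_idx == 0
        e_ka = elem.k_alpha_energy
        if s.pe_biased_fluorescence:
            emit = is_k & (e_ka > s.photon_cutoff)
            f_wt = wt[g] * elem.fluorescence_yield_K
            local = e_bind - np.where(
                emit, elem.fluorescence_yield_K * e_ka, 0.0)
            medium.deposit(tally, region[g], local, wt[g], batch[g])
        else:
            emit = is_k & (rng.random(g.size)
                           < elem.fluorescence_yield_K) \
                & (e_ka > s.photon_cutoff)
            f_wt = wt[g]
            local = e_bind - np.where(emit, e_ka, 0.0)
            medium.deposit(tally, region[g], local, wt[g], batch[g])
        if np.any(emit):
            ne = int(emit.sum())
            photon_bank.push(make_state(
                pos[g][emit], isotropic_directions(rng, ne),
                np.full(ne, e_ka), f_wt[emit], batch[g][emit]))


def _pair_events(sel, pos, dirs, E, wt, batch, rng, electron_bank):
    """Uniform kinetic-energy split; small-angle pair directions."""
    excess = E[sel] - PAIR_THRESHOLD
    T_minus = rng.random(sel.size) * excess
    T_plus = excess - T_minus
    phi = 2.0 * math.pi * rng.random(sel.size)
    for T, q, ph in ((T_minus, 0, phi), (T_plus, 1, phi + math.pi)):
        theta = M_E_C2 / (T + M_E_C2)
        d = rotate_direction(dirs[sel], np.cos(theta), ph)
        electron_bank.push(make_state(
            pos[sel], d, T, wt[sel], batch[sel],
            q=np.full(sel.size, q)))
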