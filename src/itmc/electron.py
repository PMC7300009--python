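"""Class-II condensed-history electron/positron transport.

Between catastrophic events (Moller collisions above E_M, bremsstrahlung
above E_B, both sampled from inverse-CDF tables) the electron takes
condensed steps: continuous energy loss from the restricted stopping power
evaluated at the mid-step equivalent energy, and one multiple-scattering
deflection per step drawn from the precompiled Goudsmit-Saunderson table.

Step-size limits: the global cap S_MAX, the fractional-energy-loss length
S_E = f_E T / L, the sampled distance to the next catastrophic event S_C
(with a fictitious-interaction majorant so the exponential stays exact
under the energy dependence of the cross sections), and the boundary
rules: far from a boundary (perpendicular distance above the skin depth of
N_k elastic mean free paths) the step is capped by the perpendicular
distance and a random hinge is applied — the deflection occurs at a
uniformly chosen point along the step, and since the total two-segment
path length never exceeds the perpendicular distance the step cannot leave
the region.  Within the skin depth the hinge is dropped: the electron
moves on a straight line (at most to the boundary, never farther than the
skin depth) and the deflection is applied at the end of the step.

Positrons are transported identically; at rest they annihilate into two
opposed 0.511 MeV photons (a strict mode deposits locally instead).
"""

from __future__ import annotations

import math

import numpy as np

from .constants import M_E_C2
from .kinematics import isotropic_directions, rotate_direction
from .mscatter import MsTables, T_RANGE
from .particles import make_state
from .tables import LOG_ELEC_GRID, TableSet, interp_stacked

_MAX_LOOPS = 1_000_000
_MIN_STEP = 1e-7          # cm; guards corner-case zero steps at boundaries
_EVENT_TOL = 1e-12
#: thickness of the exact single-scattering surface layer, elastic MFPs
_N_SINGLE = 3.0


def equivalent_energy(T, s, L_lookup):
    """Mid-step equivalent energy T~ = T - (s/2) L[T - L(T) s/2].

    ``L_lookup`` maps kinetic energy to restricted stopping power.  The
    result is floored at zero; callers shorten the step before it can go
    negative in practice.
    """
    T = np.asarray(T, dtype=float)
    s = np.asarray(s, dtype=float)
    half = np.clip(T - L_lookup(T) * s / 2.0, 1e-6, None)
    return np.clip(T - (s / 2.0) * L_lookup(half), 1e-6, None)


def moller_angles(T, T_out):
    """cos(theta) of an outgoing electron of energy T_out (incident T)."""
    return np.sqrt(np.clip(
        (T_out / T) * (T + 2.0 * M_E_C2) / (T_out + 2.0 * M_E_C2),
        0.0, 1.0))


def brems_photon_angle(T):
    """Mean emission polar angle m_e / (T + m_e), radians."""
    return M_E_C2 / (np.asarray(T, dtype=float) + M_E_C2)


def transport_electrons(state, medium, tset: TableSet, tally, rng,
                        photon_bank, diag, ms_tables: MsTables,
                        electron_bank=None, range_reject_fn=None) -> None:
    """Run an electron/positron population to extinction.

    ``range_reject_fn(pos, residual_mass_range)`` may return a kill mask
    for particles whose entire shower cannot reach the scoring region;
    exact only when radiative processes are off (Fano mode).
    """
    s = tset.settings
    n_mat = len(tset.materials)
    pos, dirs = state["pos"].copy(), state["dir"].copy()
    T, wt, batch = state["E"].copy(), state["wt"].copy(), \
        state["batch"].copy()
    q = state.get("q", np.zeros(T.size, np.int8)).copy()
    mfp = -np.log(1.0 - rng.random(T.size))
    steps = np.zeros(T.size, dtype=np.int32)

    def _finish(keep):
        nonlocal pos, dirs, T, wt, batch, q, mfp, steps
        pos, dirs, T, wt, batch, q, mfp, steps = (
            pos[keep], dirs[keep], T[keep], wt[keep], batch[keep],
            q[keep], mfp[keep], steps[keep])

    def _annihilate(sel_mask, region):
        """Stop positrons: two back-to-back 0.511 MeV photons."""
        p_sel = sel_mask & (q == 1)
        if not np.any(p_sel):
            return
        if s.strict_positron_stop:
            medium.deposit(tally, region[p_sel],
                           np.full(int(p_sel.sum()), 2.0 * M_E_C2),
                           wt[p_sel], batch[p_sel])
            return
        npp = int(p_sel.sum())
        d = isotropic_directions(rng, npp)
        for dd in (d, -d):
            photon_bank.push(make_state(
                pos[p_sel], dd, np.full(npp, M_E_C2), wt[p_sel],
                batch[p_sel]))

    for _ in range(_MAX_LOOPS):
        if T.size == 0:
            return
        region = medium.locate(pos, dirs)
        outside = region < 0
        if np.any(outside):
            rest = np.where(q[outside] == 1, 2.0 * M_E_C2, 0.0)
            tally.add_escaped(T[outside] + rest, wt[outside],
                              batch[outside])
            diag["electron_escaped"] = diag.get("electron_escaped", 0) \
                + int(outside.sum())
            _finish(~outside)
            if T.size == 0:
                return
            region = region[~outside]
        mat, rho_fac = medium.lookup(region)
        vac = mat < 0
        mc = np.clip(mat, 0, None)

        # cutoff: deposit residual energy locally
        done = (T <= s.electron_cutoff) & ~vac
        if np.any(done):
            medium.deposit(tally, region[done], T[done], wt[done],
                           batch[done])
            _annihilate(done, region)
            _finish(~done)
            if T.size == 0:
                return
            region, mat, rho_fac, vac, mc = (
                region[~done], mat[~done], rho_fac[~done], vac[~done],
                mc[~done])

        # exact-range rejection hook (Fano mode; radiative off)
        if range_reject_fn is not None:
            rres = interp_stacked(tset.mass_range, LOG_ELEC_GRID, mc, T)
            killm = range_reject_fn(pos, rres) & ~vac
            if np.any(killm):
                diag["range_rejected"] = diag.get("range_rejected", 0) \
                    + int(killm.sum())
                medium.deposit(tally, region[killm], T[killm], wt[killm],
                               batch[killm])
                _annihilate(killm, region)
                _finish(~killm)
                if T.size == 0:
                    return
                region, mat, rho_fac, vac, mc = (
                    region[~killm], mat[~killm], rho_fac[~killm],
                    vac[~killm], mc[~killm])

        n = T.size
        L0 = interp_stacked(tset.L, LOG_ELEC_GRID, mc, T) * rho_fac
        L0[vac] = 0.0
        maj = interp_stacked(tset.sigma_majorant, LOG_ELEC_GRID, mc, T) \
            * rho_fac
        maj[vac] = 0.0
        ssr = interp_stacked(tset.sigma_sr, LOG_ELEC_GRID, mc, T) \
            * rho_fac
        ssr[vac] = 0.0
        with np.errstate(divide="ignore"):
            S_E = np.where(L0 > 0, s.f_E * T / np.maximum(L0, 1e-300),
                           np.inf)
            s_C = np.where(maj > 0, mfp / np.maximum(maj, 1e-300), np.inf)
            S_k = np.where(ssr > 0, s.N_k / np.maximum(ssr, 1e-300),
                           np.inf)
        S_perp = medium.perp_distance(pos, region)
        # the hinge step's total displacement never exceeds S <= S_perp,
        # so hinge transport is safe down to a few elastic MFPs of a
        # boundary; inside that layer transport switches to straight
        # flight with exact single elastic scattering.  (Switching to
        # uncorrected straight steps at the full N_k skin depth instead
        # lumps deflections at interfaces and biases cavity-type doses
        # at the percent level.)
        with np.errstate(divide="ignore"):
            el_mfp0 = np.where(ssr > 0, 1.0 / np.maximum(ssr, 1e-300),
                               np.inf)
        hinge = S_perp > np.minimum(S_k, _N_SINGLE * el_mfp0)
        S = np.minimum(np.minimum(s.S_MAX, S_E),
                       np.minimum(s_C, np.where(hinge, S_perp, S_k)))
        t_seg = np.full(n, np.inf)
        S_el = np.full(n, np.inf)
        straight = ~hinge
        single = np.zeros(n, dtype=bool)
        if np.any(straight):
            t_seg[straight] = medium.boundary_distance(
                pos[straight], dirs[straight], region[straight])
            S[straight] = np.minimum(S[straight], t_seg[straight])
            # two-tier boundary crossing: in a thin layer a few elastic
            # mean free paths from a surface the condensed deflection is
            # replaced by exact single elastic scattering (straight
            # flight between collisions), so no deflection is ever
            # applied exactly at an interface — lumping the step's
            # deflection there biases re-entry into adjacent regions
            with np.errstate(divide="ignore"):
                el_mfp = np.where(ssr > 0, 1.0 / np.maximum(ssr, 1e-300),
                                  np.inf)
            layer = _N_SINGLE * el_mfp
            single = straight & (np.minimum(S_perp, t_seg) < layer) \
                & (ssr > 0)
            if np.any(single):
                S_el[single] = -np.log(
                    1.0 - rng.random(int(single.sum()))) * el_mfp[single]
                S[single] = np.minimum(S[single], S_el[single])
            # condensed straight steps stop short of the single-
            # scattering layer instead of at the boundary itself
            cond = straight & ~single
            if np.any(cond):
                stop = np.maximum(t_seg[cond] - layer[cond],
                                  np.minimum(t_seg[cond], layer[cond]))
                S[cond] = np.minimum(S[cond], stop)
        S = np.maximum(S, _MIN_STEP)

        # mid-step equivalent energy and continuous loss
        def L_of(TT, mm=mc, ff=rho_fac):
            out = interp_stacked(tset.L, LOG_ELEC_GRID, mm, TT) * ff
            return np.where(ff > 0, out, 0.0)

        T_til = equivalent_energy(T, S, L_of)
        L_til = L_of(T_til)
        L_til[vac] = 0.0
        dE = S * L_til
        ranging_out = (dE >= T - s.electron_cutoff) & ~vac
        if np.any(ranging_out):
            S = np.where(ranging_out,
                         np.maximum((T - s.electron_cutoff)
                                    / np.maximum(L_til, 1e-300),
                                    _MIN_STEP), S)
            dE = np.where(ranging_out, T - s.electron_cutoff, dE)
            T_til = np.where(ranging_out,
                             np.clip(0.5 * (T + s.electron_cutoff),
                                     1e-6, None), T_til)

        # multiple-scattering deflection parameters at T~
        ssr_til = interp_stacked(tset.sigma_sr, LOG_ELEC_GRID, mc, T_til) \
            * rho_fac
        eta_til = interp_stacked(tset.eta, LOG_ELEC_GRID, mc, T_til)
        t_ms = ssr_til * S
        t_ms[vac] = 0.0

        # single-scattering layer: deflect only at a real collision;
        # condensed steps (hinge or outer-skin straight) get the full
        # Goudsmit-Saunderson deflection for their path length
        collided = single & (S >= S_el - 1e-15)
        if s.multiple_scattering:
            mu_ms = np.ones(n)
            cm = ~single & ~vac
            if np.any(cm):
                mu_ms[cm] = _sample_ms(t_ms[cm], eta_til[cm], rng,
                                       ms_tables, diag)
            if np.any(collided):
                mu_ms[collided] = single_elastic_mu(
                    rng.random(int(collided.sum())), eta_til[collided])
                diag["single_elastic"] = diag.get("single_elastic", 0) \
                    + int(collided.sum())
        else:
            mu_ms = np.ones(n)
        phi_ms = 2.0 * math.pi * rng.random(n)

        at_boundary = straight & (S >= t_seg - 1e-12)
        zeta = rng.random(n)
        move1 = np.where(hinge, zeta * S, S)
        pos = pos + dirs * move1[:, None]
        dirs = rotate_direction(dirs, mu_ms, phi_ms)
        move2 = np.where(hinge, (1.0 - zeta) * S, 0.0)
        pos = pos + dirs * move2[:, None]
        # nudge boundary-crossers off the surface along the new direction
        pos[at_boundary] += dirs[at_boundary] * 1e-9

        medium.deposit(tally, region, dE, wt, batch)
        T = T - dE
        mfp = mfp - S * maj
        steps += 1
        diag["electron_path_cm"] = diag.get("electron_path_cm", 0.0) \
            + float(S.sum())

        # ranged-out particles stop here
        if np.any(ranging_out):
            medium.deposit(tally, region[ranging_out], T[ranging_out],
                           wt[ranging_out], batch[ranging_out])
            _annihilate(ranging_out, region)

        # catastrophic events where the majorant mfp ran out
        event = (mfp <= _EVENT_TOL) & ~ranging_out & ~vac
        if np.any(event):
            _catastrophic(event, pos, dirs, T, wt, batch, q, mc, rho_fac,
                          tset, rng, photon_bank, electron_bank, diag, s)
            mfp[event] = -np.log(1.0 - rng.random(int(event.sum())))

        over = steps > 20000
        if np.any(over):
            diag["electron_aborted"] = diag.get("electron_aborted", 0) \
                + int(over.sum())
            medium.deposit(tally, region[over], T[over], wt[over],
                           batch[over])
            _annihilate(over, region)
        _finish(~(ranging_out | over))
    raise RuntimeError("electron loop exceeded iteration cap")


def single_elastic_mu(xi, eta):
    """Analytic inverse CDF of the screened-Rutherford density.

    F^-1(xi) = 1 + 2 eta - 2 eta (1 + eta) / (xi + eta); xi=0 -> mu=-1,
    xi=1 -> mu=+1.
    """
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return 1.0 + 2.0 * eta - 2.0 * eta * (1.0 + eta) / (xi + eta)


def _poisson_inverse(t, u, kmax: int = 48):
    """Poisson counts by CDF inversion: one uniform per draw."""
    N = np.zeros(t.size, dtype=int)
    term = np.exp(-t)
    cum = term.copy()
    remaining = u >= cum
    k = 0
    while np.any(remaining) and k < kmax:
        k += 1
        term = term * t / k
        cum = cum + term
        N[remaining] = k
        remaining = u >= cum
    return N


def _small_t_net_mu(t, eta, rng):
    """Exact few-scatter sampling for steps below the table's t range.

    The Goudsmit-Saunderson distribution is the direction after a
    Poisson(t) number of single elastic scatterings, so for small t it is
    cheapest and exact to draw the count and compose the individual
    screened-Rutherford deflections; the net polar cosine is returned
    (the caller applies a fresh uniform azimuth, which is exact by
    symmetry)."""
    N = _poisson_inverse(t, rng.random(t.size))
    v = np.zeros((t.size, 3))
    v[:, 2] = 1.0
    nmax = int(N.max()) if N.size else 0
    for j in range(1, nmax + 1):
        m = N >= j
        k = int(m.sum())
        mu_j = single_elastic_mu(rng.random(k), eta[m])
        phi_j = 2.0 * math.pi * rng.random(k)
        v[m] = rotate_direction(v[m], mu_j, phi_j)
    return np.clip(v[:, 2], -1.0, 1.0)


def _sample_ms(t_ms, eta, rng, ms_tables: MsTables, diag):
    """Deflection cosine: inverse-CDF table for t in range, exact
    Poisson-composed single scattering below the table minimum."""
    n = t_ms.size
    mu = np.ones(n)
    xi = rng.random(n)
    t_lo = T_RANGE[0]
    big = t_ms >= t_lo
    if np.any(big):
        mu[big] = ms_tables.sample_mu(xi[big], t_ms[big], eta[big])
    small = (~big) & (t_ms > 0)
    if np.any(small):
        mu[small] = _small_t_net_mu(t_ms[small], eta[small], rng)
        diag["ms_small_t"] = diag.get("ms_small_t", 0) + int(small.sum())
    return np.clip(mu, -1.0, 1.0)


def _catastrophic(event, pos, dirs, T, wt, batch, q, mc, rho_fac, tset,
                  rng, photon_bank, electron_bank, diag, s):
    """Fictitious-interaction acceptance, then Moller or bremsstrahlung."""
    idx = np.nonzero(event)[0]
    sig_m = interp_stacked(tset.sigma_moller, LOG_ELEC_GRID, mc[idx],
                           T[idx]) * rho_fac[idx]
    sig_b = interp_stacked(tset.sigma_brems, LOG_ELEC_GRID, mc[idx],
                           T[idx]) * rho_fac[idx]
    maj = interp_stacked(tset.sigma_majorant, LOG_ELEC_GRID, mc[idx],
                         T[idx]) * rho_fac[idx]
    xi = rng.random(idx.size)
    p_real = np.clip((sig_m + sig_b) / np.maximum(maj, 1e-300), 0.0, 1.0)
    over = (sig_m + sig_b) > maj * (1.0 + 1e-9)
    if np.any(over):
        diag["majorant_exceeded"] = diag.get("majorant_exceeded", 0) \
            + int(over.sum())
    real = xi < p_real
    diag["null_events"] = diag.get("null_events", 0) \
        + int((~real).sum())
    if not np.any(real):
        return
    ridx = idx[real]
    # scaled residual of the same uniform picks the channel
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_m = sig_m[real] / np.maximum(sig_m[real] + sig_b[real],
                                          1e-300)
    is_moller = (xi[real] / np.maximum(p_real[real], 1e-300)) < frac_m
    for mi in np.unique(mc[ridx]):
        mtab = tset.per_mat[mi]
        mm = mc[ridx] == mi
        # ---- Moller ----
        sel = ridx[mm & is_moller]
        ok = sel[T[sel] > 2.0 * s.E_M]
        if ok.size:
            diag["moller"] = diag.get("moller", 0) + ok.size
            eps = mtab.moller_w.sample(rng.random(ok.size),
                                       np.log(T[ok]))
            W = np.clip(eps * T[ok], s.E_M, T[ok] / 2.0)
            T_prim = T[ok] - W
            phi = 2.0 * math.pi * rng.random(ok.size)
            mu1 = moller_angles(T[ok], T_prim)
            mu2 = moller_angles(T[ok], W)
            d2 = rotate_direction(dirs[ok], mu2, phi + math.pi)
            dirs[ok] = rotate_direction(dirs[ok], mu1, phi)
            T[ok] = T_prim
            electron_bank.push(make_state(pos[ok], d2, W, wt[ok],
                                          batch[ok], q=np.zeros(ok.size)))
        # ---- bremsstrahlung ----
        sel = ridx[mm & ~is_moller]
        ok = sel[T[sel] > s.E_B]
        if ok.size:
            diag["brems"] = diag.get("brems", 0) + ok.size
            k = mtab.brems_k.sample(rng.random(ok.size), np.log(T[ok]))
            k = np.clip(k, s.E_B / T[ok], 1.0)
            E_g = k * T[ok]
            theta = brems_photon_angle(T[ok])
            phi = 2.0 * math.pi * rng.random(ok.size)
            d_g = rotate_direction(dirs[ok], np.cos(theta), phi)
            photon_bank.push(make_state(pos[ok], d_g, E_g, wt[ok],
                                        batch[ok]))
            T[ok] = (1.0 - k) * T[ok]

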