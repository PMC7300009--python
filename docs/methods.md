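# Methods

This note documents the physics models, numerical choices and known
limitations of the `itmc` transport engine, at the level of detail a user
needs to judge what a given result does and does not demonstrate.

## Sampling discipline

Every stochastic quantity — free path, interaction channel, scattering
cosine, knock-on energy, radiated fraction, projected shell momentum,
multiple-scattering deflection — is drawn by inverse-transform sampling:
one uniform number ξ, a (multi)linear interpolation of a precompiled
inverse-CDF table, and a closed-form transformation where one exists.  No
transport path contains a rejection loop; the test suite audits the
one-uniform-per-variable property with a counting RNG wrapper, and every
sampler is checked against an independent acceptance–rejection draw of
the same density (two-sample KS at n = 10⁵).

Inverse tables store the quantile function on a 256-point cosine-spaced ξ
grid (denser near 0 and 1), except the coherent angular map which uses
1024 points because the form-factor quantile has sharp shoulders.  The
tabulated piecewise-linear density is inverted essentially exactly by
subdividing cells before integration.

## Photon physics

Per-element data are analytic fixture parameterizations (see
`itmc.elements`): Molière/Thomas–Fermi form factors, an
impulse-approximation incoherent scattering function built shell by shell
from hydrogen-like Compton profiles with the kinematic `p_z` limit at
scattered energy `E − E_binding`, a Born-type photoelectric cross section
with `n_i (E_i/E_K)^{3/2}` subshell shares, and Bethe–Heitler pair
production with complete-screening saturation.  These have the right
shapes, limits and orders of magnitude but are *not* evaluated-library
data; absolute photon attenuation is accurate to a few percent in the
Compton-dominated regime (e.g. water at 1.25 MeV: μ/ρ = 0.0631 vs 0.0632
cm²/g from standard tables) and fixture-grade (tens of percent) where
photoelectric absorption dominates.  Quantitative claims are therefore
made only for quantities the package's own desk-verifiable integrals
control (energy-transfer coefficients, moment identities, conservation),
not for kV-regime dosimetry.

The angular maps follow the published layout — deflection cosine versus
(ξ, log E) with 250 log-energy columns on log E ∈ [−6.91, 6.42] and a
100-point uniform μ backbone — but each column's CDF is integrated on a
momentum-transfer-adapted grid (points log-spaced in
`q = k α √(1−μ)`, `k = 29.1433 Å⁻¹`).  A uniform 100-point μ grid cannot
represent the coherent forward peak at MeV energies (the whole peak falls
inside the last cell, giving CDF errors up to 0.8); the adaptive column
integration reduces the sampled-CDF error below ~2×10⁻³ at all energies.
For the same reason the coherent map stores its quantiles as
`y = (1−μ)α²` (∝ q²), which is nearly energy-independent, so
interpolation between the published energy columns is benign; the sampler
converts back to μ with the query energy.

Compton events support three modes: free-electron Klein–Nishina (exact
kinematics), bound Compton (S(Z, q)-weighted angles), and Doppler
broadening — shell selected by occupancy among those energetically open,
`p_z` from the shell profile's inverse CDF, and the broadened scattered
energy from the quadratic relation between `p_z`, α and α′; kinematically
impossible draws retry once and then fall back to `p_z = 0` (counted in
diagnostics).  Energy balances exactly per event:
`E = E′ + T_e + E_binding`.

Atomic relaxation is reduced to K-shell fluorescence with yield `ω_K`
(Kα energy = K minus outermost-L binding); L-shell vacancies and
Auger/Coster–Kronig cascades deposit locally.  A biased mode emits one
fluorescence photon per absorption with weight `ω_K`, unbiased in
expectation.

## Electron physics

Class II condensed history.  Restricted collision stopping power uses the
Bethe–Møller form with the printed logarithm `ln[2(τ+2)T²/I²]` and F(τ);
in the unrestricted limit it reproduces standard water collision stopping
powers at 0.1/0.5/1/10 MeV within 3 % once the density effect is applied.
The density-effect correction is a Sternheimer-recipe fit computed per
material from (I, ρ, composition); Fano mode forces δ = 0.  Radiative
losses use the linear scaled-spectrum fit `f(k) = a(1 − b k)` per element
(complete-screening reference spectrum at 1 MeV), giving the closed-form
catastrophic cross section `Σ_B ∝ ln(1/k_B) − b(1 − k_B)`; this is known
to be crude in high-Z targets.

Catastrophic distances are sampled with a fictitious-interaction
(null-collision) majorant: the tabulated `Σ_M + Σ_B` maximized over the
energy window one step can span, with acceptance `Σ(T_site)/Σ̂` at the
tentative site.  A majorant-MFP countdown is carried across steps, so the
exponential law is exact under the energy dependence of the cross
sections; a fine-step oracle test verifies the realized event rate.

Multiple scattering: screened-Rutherford single scattering with Molière
screening `η = χ_a²/4` (with the `Z(Z+1)` electron-scattering factor and
`Z(Z+1)`-weighted mixing for compounds); Goudsmit–Saunderson distribution
precompiled as a 3-D inverse table of the flattening variable u over
(ξ: 256, log t: 32 points on [10, 10⁵], log η: 32 points on
[10⁻⁹, 10⁻³]), with the spreading parameter A(t, η) from the hard-coded
fit.  The Legendre series is summed in blocks with the asymptotic
`exp(−t)` tail subtracted and an explicit no-scatter atom at μ = 1;
convergence 10⁻⁷ per block, capped at 2.5×10⁵ terms (the smallest η
genuinely needs more than 10⁴ terms).  For steps whose t falls below the
table range, the deflection is drawn exactly as a Poisson(t) number of
single scatterings composed by rotation — the single-scatter CDF inverts
analytically, so this stays rejection-free.  Spin (Mott) corrections are
not modeled.

### Step selection and boundary crossing

Far from boundaries: `S = min{S_MAX, S_E, S_C, S_⊥}` with a random hinge
(deflect at ζS, ζ ~ U(0,1)).  Because the hinge path's total length is S
and `S ≤ S_⊥`, a hinge step can never leave its region, so every step
deposits into exactly one voxel/zone and continuous loss needs no
splitting.

Within a few elastic mean free paths of a surface the condensed
description itself breaks down, and lumping a step's full deflection at a
region interface measurably biases interface-sensitive quantities (in the
Fano cavity test, up to +2 % depending on the cavity density).  The
engine therefore uses hinge steps down to
`min(N_k, 3)` elastic MFPs from the nearest boundary and switches to
*exact single elastic scattering* inside that layer: straight flight
between collisions sampled at the local elastic cross section, one
analytic screened-Rutherford deflection per collision, at most to the
boundary (the `S_MAX, S_E, S_C, S_k, t_seg` caps all still apply).  This
is the package's own variant of a PRESTA-style boundary-crossing
algorithm; with it the Fano cavity response is flat in the cavity density
(ratios 1.001 ± 0.004 at density factors 10⁻³ and 10⁻²) where plain
straight steps with end-of-step deflection gave +1 % and +2 %.

Energy loss per step is `ΔE = S·L(T̃)` at the mid-step equivalent energy;
`Σ_SR` and η are evaluated at T̃.  Electrons below the kinetic cutoff
(default 0.189 MeV ≈ the EGSnrc-convention 0.7 MeV total energy; 1 keV in
Fano mode) deposit locally.  Positrons transport as electrons and
annihilate at rest into two opposed 0.511 MeV photons (a strict mode
deposits locally instead).

## Fano cavity harness

Idealizations, as the test requires: photons regenerate in place after
each (Compton-only, free-electron) interaction so the primary fluence is
uniform and unattenuated; bremsstrahlung off; δ = 0; photon/electron
cutoffs 10 keV / 1 keV; photon cross sections boosted ×100 with recoil
electrons carrying weight 1/boost.  The theoretical reference is
`E·μ_tr/ρ` from the free-electron Klein–Nishina energy-transfer integral
(graphite 5.353×10⁻¹², aluminum 5.163×10⁻¹² Gy cm² at 1.25 MeV).  Two
efficiency measures are exact under these idealizations: the beam is a
disk covering the cavity plus a margin larger than the maximum secondary
range (fluence normalization uses the actual beam area), and electrons
whose restricted-stopping-power range cannot reach the cavity are
deposited on the spot (valid only with radiative processes off, since no
photons then leave an electron shower).

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
each run in minutes on one core: the cavity simulation uses 5×10⁵ (tests)
to 10⁶ (acceptance) boosted histories for ~0.25–0.35 % statistical
precision; the step-size comparison uses paired 4×10⁴-history 15 MeV
electron-beam runs on a coarse (4×4×1 cm³ voxel) water phantom with the
depth dose averaged over the central 12×12 cm² columns; sampler KS checks
use 10⁵ draws.

## What the synthetic data do and do not show

The generator-defined study conditions (fixture cross sections, analytic
profiles, the idealized cavity geometry) exercise the *algorithms*:
inverse-CDF fidelity, conservation, condensed-history step and boundary
algorithms, and the engine's internal consistency against its own
theoretical integrals.  Passing tests do not certify absolute dosimetric
accuracy against evaluated nuclear data, measured beams, or kV-regime
applications; those require library-grade cross sections
(EPDL/ESTAR-class) outside this package's scope.

## Known limitations

* Fixture-grade photoelectric and pair cross sections (few-percent to
  tens-of-percent absolute error depending on regime); simplified
  relaxation (K fluorescence only).
* Linear bremsstrahlung spectrum fit; inaccurate for electron beams in
  high-Z media.
* No spin/Mott elastic correction; screened-Rutherford only.
* Compton recoil direction uses free-electron kinematics even for
  Doppler-broadened events.
* Pair production splits the excess energy uniformly and uses the
  small-angle mean emission angle; triplet production is folded into
  pair.
* The voxel phantom and quadric zones do not compose arbitrarily: a run
  uses either a voxel grid or a zone system as its medium.
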