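"""Test-side oracles: rejection sampling and physical-constant checks.

The transport engine itself never rejects; the classic acceptance-
rejection sampler here exists so the test suite can verify every
inverse-CDF sampler against an independent draw from the same density.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import (
    K_COH,
    M_E_C2,
    PAIR_THRESHOLD,
    R_E,
    SIGMA_THOMSON,
    momentum_transfer_constant,
)


def rejection_oracle(pdf, support, rng, n, envelope=None,
                     max_batches=10_000):
    """Acceptance-rejection samples of a bounded pdf on [a, b].

    ``envelope`` is an upper bound on the pdf (estimated from a fine scan
    when omitted).  Raises if the acceptance rate falls below 1e-4.
    """
    a, b = support
    if envelope is None:
        x = np.linspace(a, b, 4097)
        envelope = 1.2 * float(np.max(pdf(x)))
    if envelope <= 0:
        raise ValueError("pdf appears to be zero on the support")
    out = []
    got, tried = 0, 0
    while got < n:
        if tried > max_batches:
            raise RuntimeError("rejection oracle: too many batches")
        m = max(int((n - got) * 2.5), 1000)
        x = a + (b - a) * rng.random(m)
        keep = rng.random(m) * envelope < pdf(x)
        out.append(x[keep])
        got += int(keep.sum())
        tried += 1
        if tried >= 20 and got < tried * 1e-4 * m:
            raise RuntimeError("rejection oracle acceptance rate < 1e-4 "
                               "(bad envelope)")
    return np.concatenate(out)[:n]


def constants_check() -> dict:
    """Recompute the engine's key constants from first principles."""
    return {
        "momentum_transfer_constant_A_inv": momentum_transfer_constant(),
        "k_coh_in_use": K_COH,
        "pair_threshold_MeV": PAIR_THRESHOLD,
        "electron_rest_energy_MeV": M_E_C2,
        "classical_electron_radius_cm": R_E,
        "thomson_cross_section_barn": SIGMA_THOMSON / 1e-24,
        "thomson_from_integral_barn":
            (8.0 * math.pi / 3.0) * R_E**2 / 1e-24,
    }
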