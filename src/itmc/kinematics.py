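"""Direction rotations shared by the photon and electron loops."""

from __future__ import annotations

import numpy as np


def rotate_direction(dirs: np.ndarray, mu, phi) -> np.ndarray:
    """Rotate unit vectors by polar cosine mu and azimuth phi.

    The polar angle is measured from the current direction; the azimuth is
    measured in a plane perpendicular to it.  The result is renormalized
    to guard against drift over long rotation chains.
    """
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    sin_t = np.sqrt(np.clip(1.0 - mu**2, 0.0, None))
    # orthonormal frame (a, b, d); choose a stable seed axis per particle
    seed = np.zeros_like(d)
    smallest = np.argmin(np.abs(d), axis=1)
    seed[np.arange(d.shape[0]), smallest] = 1.0
    a = np.cross(d, seed)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = np.cross(d, a)
    out = (mu[:, None] * d
           + sin_t[:, None] * (np.cos(phi)[:, None] * a
                               + np.sin(phi)[:, None] * b))
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out if np.asarray(dirs).ndim > 1 else out[0]


def isotropic_directions(rng, n: int) -> np.ndarray:
    mu = rng.random(n) * 2.0 - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    s = np.sqrt(1.0 - mu**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])
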