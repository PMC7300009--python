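""".3ddose-format dose grid reader/writer.

Plain-text interchange format: first line the voxel counts ``nx ny nz``,
then the x, y and z boundary coordinate lists (n+1 values each), then the
dose values and finally the relative errors, both row-major with x
fastest.  Unix and Windows line endings are accepted.
"""

from __future__ import annotations

import numpy as np


def write_dose(path, dose: np.ndarray, rel_err: np.ndarray,
               bounds_x, bounds_y, bounds_z) -> None:
    dose = np.asarray(dose)
    nx, ny, nz = dose.shape
    if rel_err.shape != dose.shape:
        raise ValueError("dose and error grids must match")
    with open(path, "w") as fh:
        fh.write(f"{nx} {ny} {nz}\n")
        for b in (bounds_x, bounds_y, bounds_z):
            fh.write(" ".join(f"{v:.6f}" for v in b) + "\n")
        flat = dose.reshape(-1, order="F")
        fh.write(" ".join(f"{v:.6e}" for v in flat) + "\n")
        flat_e = np.asarray(rel_err).reshape(-1, order="F")
        fh.write(" ".join(f"{v:.6e}" for v in flat_e) + "\n")


def read_dose(path):
    """Returns (dose, rel_err, (bounds_x, bounds_y, bounds_z))."""
    with open(path, "r", newline=None) as fh:
        tokens = fh.read().split()
    pos = 0

    def take(n):
        nonlocal pos
        if pos + n > len(tokens):
            raise ValueError(
                f"malformed dose file: expected {n} more values "
                f"at token {pos}")
        out = tokens[pos:pos + n]
        pos += n
        return out

    try:
        nx, ny, nz = (int(v) for v in take(3))
    except ValueError as exc:
        raise ValueError(f"malformed dose file header: {exc}") from None
    bounds = tuple(np.array([float(v) for v in take(n + 1)])
                   for n in (nx, ny, nz))
    n_vox = nx * ny * nz
    dose = np.array([float(v) for v in take(n_vox)]).reshape(
        (nx, ny, nz), order="F")
    rel_err = np.array([float(v) for v in take(n_vox)]).reshape(
        (nx, ny, nz), order="F")
    return dose, rel_err, bounds
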