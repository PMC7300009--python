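"""3-D gamma-index comparison of dose distributions.

Low-style gamma: for each reference voxel the minimum over a search
volume of sqrt(dr^2/dta^2 + dD^2/(crit * D_norm)^2).  Global
normalization (D_norm = max of the reference) is the default; statistics
are restricted to significant voxels, those above a fraction of the
reference maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class GammaResult:
    gamma: np.ndarray           # per-voxel, NaN where not significant
    significant: np.ndarray     # bool mask
    pass_fraction: float
    mean_gamma: float
    max_gamma: float


def gamma_index_3d(ref: np.ndarray, ev: np.ndarray, spacing,
                   dose_crit: float = 0.02, dta: float = 0.2,
                   threshold: float = 0.2, search_factor: float = 3.0,
                   subsample: float = 0.25,
                   local: bool = False) -> GammaResult:
    """Gamma index of ``ev`` against ``ref`` on commensurate grids.

    ``spacing`` is the voxel size (cm, scalar or per-axis); ``dta`` in cm;
    ``dose_crit`` fractional (0.02 = 2%).  The search volume extends to
    ``search_factor * dta`` with trilinear interpolation of the evaluated
    distribution on a ``subsample * dta`` offset lattice.  ``local=True``
    normalizes the dose term to the local reference dose instead of the
    global maximum.
    """
    ref = np.asarray(ref, dtype=float)
    ev = np.asarray(ev, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("grids must have identical shape")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    d_max = ref.max()
    sig = ref > threshold * d_max
    if not np.any(sig):
        raise ValueError("no significant voxels above threshold")
    idx = np.array(np.nonzero(sig), dtype=float)     # (3, n)
    ref_vals = ref[sig]
    norm = ref_vals if local else d_max
    # offsets sorted by radius for early pruning
    step = subsample * dta
    n_off = int(np.floor(search_factor * dta / step))
    g1 = np.arange(-n_off, n_off + 1) * step
    ox, oy, oz = np.meshgrid(g1, g1, g1, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    r = np.linalg.norm(offs, axis=1)
    keep = r <= search_factor * dta
    offs, r = offs[keep], r[keep]
    order = np.argsort(r)
    offs, r = offs[order], r[order]

    best = np.full(ref_vals.size, np.inf)
    active = np.arange(ref_vals.size)
    for off, dist in zip(offs, r):
        # voxels whose current gamma can no longer improve at this radius
        active = active[best[active] > dist / dta]
        if active.size == 0:
            break
        coords = idx[:, active] + (off / spacing)[:, None]
        ev_i = map_coordinates(ev, coords, order=1, mode="nearest")
        dd = (ev_i - ref_vals[active]) / (
            dose_crit * (norm[active] if local else norm))
        g = np.sqrt((dist / dta) ** 2 + dd**2)
        best[active] = np.minimum(best[active], g)
    gamma = np.full(ref.shape, np.nan)
    gamma[sig] = best
    return GammaResult(
        gamma=gamma, significant=sig,
        pass_fraction=float(np.mean(best <= 1.0)),
        mean_gamma=float(best.mean()), max_gamma=float(best.max()))
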