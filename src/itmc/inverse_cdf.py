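"""Gridded inverse cumulative distribution tables.

Every stochastic quantity in the engine is drawn by inverse-transform
sampling: one uniform random number ``xi`` in [0, 1] plus multilinear
interpolation of a precompiled inverse-CDF table ``x = F^-1(xi)``.  No
sampler anywhere in the transport loops uses rejection.

A table stores the quantile function on a ``xi`` grid (optionally with one
or two parameter axes such as log-energy); ``sample`` interpolates
multilinearly.  Values are non-decreasing along the ``xi`` axis and the
endpoints map to the variable's domain endpoints by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def default_xi_grid(n: int = 256) -> np.ndarray:
    """Cosine-spaced xi grid on [0, 1], denser near both endpoints where
    quantile functions are steepest."""
    return 0.5 * (1.0 - np.cos(np.pi * np.linspace(0.0, 1.0, n)))


@dataclass
class InverseCdfTable:
    """Inverse CDF sampled on (xi, *params) with multilinear interpolation.

    ``axes[0]`` is the xi grid; further axes are parameter grids (stored on
    whatever scale the builder chose, e.g. log energy).  ``values`` has one
    dimension per axis.
    """

    axes: list[np.ndarray]
    values: np.ndarray
    valid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.ndim != len(self.axes):
            raise ValueError("values rank must match number of axes")
        diffs = np.diff(self.values, axis=0)
        if np.any(diffs < -1e-9 * (np.abs(self.values).max() + 1.0)):
            raise ValueError("inverse CDF must be non-decreasing in xi")

    def sample(self, xi, *params):
        """Evaluate F^-1 at ``xi`` for parameter values ``params``."""
        coords = [np.asarray(xi, dtype=float)]
        coords += [np.asarray(p, dtype=float) for p in params]
        if len(coords) != len(self.axes):
            raise ValueError(
                f"expected {len(self.axes) - 1} parameter(s), "
                f"got {len(coords) - 1}")
        coords = list(np.broadcast_arrays(*coords))
        idx, frac = [], []
        for ax, c in zip(self.axes, coords):
            c = np.clip(c, ax[0], ax[-1])
            i = np.clip(np.searchsorted(ax, c, side="right") - 1,
                        0, ax.size - 2)
            idx.append(i)
            frac.append((c - ax[i]) / (ax[i + 1] - ax[i]))
        out = np.zeros(np.broadcast(*coords).shape, dtype=float)
        ndim = len(self.axes)
        for corner in range(1 << ndim):
            w = 1.0
            sel = []
            for d in range(ndim):
                hi = (corner >> d) & 1
                w = w * (frac[d] if hi else (1.0 - frac[d]))
                sel.append(idx[d] + hi)
            out += w * self.values[tuple(sel)]
        return out


def build_inverse_cdf(pdf_values, x_grid, xi_grid=None,
                      refine: int = 1) -> InverseCdfTable:
    """Numerically invert a tabulated pdf into an InverseCdfTable.

    The pdf is integrated with the trapezoid rule, normalized to one, and
    the resulting CDF is inverted onto the xi grid.  ``refine`` subdivides
    each grid cell of the (piecewise-linear) pdf before integrating, which
    makes the inversion of the tabulated density essentially exact even
    when the tabulation grid is coarse relative to the xi grid.
    """
    pdf = np.asarray(pdf_values, dtype=float)
    x = np.asarray(x_grid, dtype=float)
    if np.any(pdf < 0.0):
        raise ValueError("pdf values must be nonnegative")
    if not np.any(pdf > 0.0):
        raise ValueError("pdf is identically zero")
    if refine > 1:
        fine = np.unique(np.concatenate(
            [np.linspace(x[i], x[i + 1], refine + 1)
             for i in range(x.size - 1)]))
        pdf = np.interp(fine, x, pdf)
        x = fine
    if xi_grid is None:
        xi_grid = default_xi_grid()
    cdf = np.concatenate(
        [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(x))])
    cdf /= cdf[-1]
    # break plateaus from zero-pdf stretches so the inversion is well posed
    cdf = cdf + np.linspace(0.0, 1e-12, cdf.size)
    cdf /= cdf[-1]
    inv = np.interp(xi_grid, cdf, x)
    inv[0], inv[-1] = x[0], x[-1]
    return InverseCdfTable(axes=[np.asarray(xi_grid)],
                           values=np.maximum.accumulate(inv))


def invert_cdf_columns(pdf_cols, x_grid, param_axis,
                       xi_grid=None, valid=None,
                       refine: int = 16) -> InverseCdfTable:
    """Invert a family of pdfs (columns over one parameter axis).

    ``pdf_cols`` has shape (n_param, n_x).  Returns a 2-D table over
    (xi, param).
    """
    pdf_cols = np.asarray(pdf_cols, dtype=float)
    if xi_grid is None:
        xi_grid = default_xi_grid()
    cols = []
    for j in range(pdf_cols.shape[0]):
        if valid is not None and not valid[j]:
            cols.append(np.full(xi_grid.size, x_grid[0]))
            continue
        t = build_inverse_cdf(pdf_cols[j], x_grid, xi_grid, refine=refine)
        cols.append(t.values)
    values = np.stack(cols, axis=1)
    return InverseCdfTable(
        axes=[np.asarray(xi_grid), np.asarray(param_axis)],
        values=values,
        valid=None if valid is None else np.asarray(valid))


class CountingRng:
    """Wrapper around a numpy Generator that counts uniform draws.

    Used by the test suite to audit the one-random-number-per-sample
    contract of inverse-transform sampling.
    """

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self.draws = 0

    def uniform(self, size=None):
        self.draws += int(np.prod(size)) if size is not None else 1
        return self._rng.random(size)

    def random(self, size=None):
        return self.uniform(size)
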