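"""Particle state arrays and secondary banks.

Transport is vectorized: a particle population is a dict of arrays with
keys ``pos`` (n, 3), ``dir`` (n, 3), ``E`` (n), ``wt`` (n), ``batch`` (n)
and, for charged particles, ``q`` (0 electron, 1 positron).  Secondary
particles are pushed onto banks (LIFO over chunks) and popped by the
driver until every history is exhausted.
"""

from __future__ import annotations

import numpy as np


def make_state(pos, dirs, E, wt, batch, q=None):
    state = {
        "pos": np.atleast_2d(np.asarray(pos, dtype=float)).copy(),
        "dir": np.atleast_2d(np.asarray(dirs, dtype=float)).copy(),
        "E": np.atleast_1d(np.asarray(E, dtype=float)).copy(),
        "wt": np.atleast_1d(np.asarray(wt, dtype=float)).copy(),
        "batch": np.atleast_1d(np.asarray(batch, dtype=int)).copy(),
    }
    if q is not None:
        state["q"] = np.atleast_1d(np.asarray(q, dtype=np.int8)).copy()
    norms = np.linalg.norm(state["dir"], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        state["dir"] /= norms[:, None]
    if np.any(state["E"] < 0) or np.any(state["wt"] <= 0):
        raise ValueError("particles need E >= 0 and weight > 0")
    return state


def select(state, mask_or_idx):
    return {k: v[mask_or_idx] for k, v in state.items()}


def concat(states):
    states = [s for s in states if s is not None and s["E"].size]
    if not states:
        return None
    keys = states[0].keys()
    return {k: np.concatenate([s[k] for s in states]) for k in keys}


class Bank:
    """LIFO bank of particle chunks."""

    def __init__(self):
        self._chunks: list[dict] = []
        self.pushed = 0
        self.popped = 0

    def push(self, state) -> None:
        if state is None or state["E"].size == 0:
            return
        self._chunks.append(state)
        self.pushed += state["E"].size

    def pop(self, max_particles: int | None = None):
        """Pop chunks (most recent first) up to max_particles total."""
        if not self._chunks:
            return None
        out = []
        n = 0
        while self._chunks and (max_particles is None
                                or n < max_particles):
            c = self._chunks.pop()
            out.append(c)
            n += c["E"].size
        got = concat(out)
        self.popped += got["E"].size
        return got

    def __len__(self):
        return sum(c["E"].size for c in self._chunks)

    @property
    def energy(self) -> float:
        """Weighted kinetic energy currently banked (MeV)."""
        return float(sum(np.sum(c["E"] * c["wt"]) for c in self._chunks))
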