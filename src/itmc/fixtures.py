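"""Fixture builder: element data library generation and export.

All per-element physics tables are generated deterministically from the
analytic parameterizations in :mod:`itmc.elements` (fixed
``FIXTURE_VERSION``); this module assembles them for a requested element
set and can export the library as a directory of CSV files with a JSON
manifest for inspection or external use.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .elements import FIXTURE_VERSION, SUPPORTED_ELEMENTS, Element, \
    build_element


def build_fixtures(symbols=None) -> dict[str, Element]:
    """Element library for the requested symbols (default: all)."""
    symbols = list(symbols) if symbols is not None \
        else list(SUPPORTED_ELEMENTS)
    bad = [s for s in symbols if s not in SUPPORTED_ELEMENTS]
    if bad:
        raise ValueError(
            f"unsupported element(s) {bad}; supported: "
            f"{', '.join(SUPPORTED_ELEMENTS)}")
    return {s: build_element(s) for s in symbols}


def save_fixture_library(path, symbols=None) -> Path:
    """Write the library as one CSV group per element plus a manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    lib = build_fixtures(symbols)
    manifest = {"version": FIXTURE_VERSION, "elements": {}}
    for sym, el in lib.items():
        d = root / sym
        d.mkdir(exist_ok=True)
        np.savetxt(d / "form_factor.csv",
                   np.column_stack([el.q_grid, el.form_factor]),
                   delimiter=",", header="q_A_inv,F0", comments="")
        np.savetxt(d / "incoherent_function.csv",
                   np.column_stack([el.q_grid, el.incoherent_function]),
                   delimiter=",", header="q_A_inv,S", comments="")
        np.savetxt(d / "photoelectric.csv",
                   np.column_stack([el.pe_energy_grid, el.pe_xs]),
                   delimiter=",", header="E_MeV,sigma_cm2", comments="")
        np.savetxt(d / "pair.csv",
                   np.column_stack([el.pe_energy_grid, el.pair_xs]),
                   delimiter=",", header="E_MeV,sigma_cm2", comments="")
        manifest["elements"][sym] = {
            "Z": el.Z, "A": el.A, "I_MeV": el.I,
            "fluorescence_yield_K": el.fluorescence_yield_K,
            "brems_fit": [el.brems_a, el.brems_b],
            "shells": [{"label": s.label,
                        "binding_MeV": s.binding_energy,
                        "occupancy": s.occupancy, "p0_au": s.p0}
                       for s in el.shells],
        }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return root
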