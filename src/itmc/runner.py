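"""Top-level run driver: config in, dose artifacts out."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from .config import RunConfig, dump_config
from .dosefile import write_dose
from .engine import slab_phantom_simulation
from .mscatter import MsTables
from .tally import extract_pdd


def run(cfg: RunConfig, ms_tables: MsTables | None = None) -> dict:
    """Execute a configured run; writes <output>.3ddose, <output>_pdd.csv
    and <output>.json and returns the report dict."""
    out = Path(cfg.output)
    out.parent.mkdir(parents=True, exist_ok=True)
    probe = out.with_suffix(".json")
    try:
        probe.write_text("{}")
    except OSError as exc:
        raise RuntimeError(f"output path not writable: {exc}") from None
    t0 = time.time()
    sim = slab_phantom_simulation(
        cfg.layers, cfg.beam, nxy=cfg.nxy, dxy=cfg.dxy, dz=cfg.dz,
        settings=cfg.settings, n_batches=cfg.batches,
        ms_tables=ms_tables)
    res = sim.run_beam(cfg.beam, cfg.histories, cfg.seed)
    grid = sim.tally.grid
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(res.dose > 0, res.sigma / res.dose, 0.0)
    bx = grid.origin[0] + np.arange(grid.shape[0] + 1) * grid.voxel_size[0]
    by = grid.origin[1] + np.arange(grid.shape[1] + 1) * grid.voxel_size[1]
    bz = grid.origin[2] + np.arange(grid.shape[2] + 1) * grid.voxel_size[2]
    write_dose(out.with_suffix(".3ddose"), res.dose, rel, bx, by, bz)
    pdd = extract_pdd(res.dose)
    z_mid = 0.5 * (bz[:-1] + bz[1:])
    csv_path = out.parent / (out.name + "_pdd.csv")
    with open(csv_path, "w") as fh:
        fh.write("depth_cm,dose_Gy_cm2,sigma\n")
        sig_pdd = extract_pdd(res.sigma)
        for z, d, sg in zip(z_mid, pdd, sig_pdd):
            fh.write(f"{z:.4f},{d:.6e},{sg:.6e}\n")
    report = {
        "config": dump_config(cfg),
        "n_histories": res.n_histories,
        "source_energy_MeV": res.source_energy,
        "energy_closure": res.energy_closure,
        "diagnostics": res.diag,
        "d_max_Gy_cm2": float(res.dose.max()),
        "wall_time_s": time.time() - t0,
        "outputs": {
            "dose": str(out.with_suffix(".3ddose")),
            "pdd": str(csv_path),
        },
    }
    probe.write_text(json.dumps(report, indent=1, default=str))
    return report
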