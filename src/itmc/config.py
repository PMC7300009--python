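"""Run configuration: YAML parsing, validation and defaults.

A run file has four blocks — ``source``, ``phantom``, ``physics``,
``electron`` and ``run`` — all optional except source and phantom.
Unknown keys are rejected by name so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .sources import BeamSpec
from .tables import TransportSettings

_TOP_KEYS = {"source", "phantom", "physics", "electron", "run"}
_SOURCE_KEYS = {"particle", "spectrum", "geometry", "direction", "ssd",
                "phase_space"}
_PHANTOM_KEYS = {"layers", "nxy", "dxy", "dz"}
_PHYSICS_KEYS = {"photon_cutoff", "electron_cutoff", "E_M", "E_B",
                 "doppler", "coherent", "biased_fluorescence",
                 "roulette_survival", "roulette_weight_floor"}
_ELECTRON_KEYS = {"S_MAX", "f_E", "N_k"}
_RUN_KEYS = {"histories", "batches", "seed", "output"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    beam: BeamSpec
    layers: list[tuple[str, float]]
    nxy: int
    dxy: float
    dz: float
    settings: TransportSettings
    histories: int
    batches: int
    seed: int
    output: str
    phase_space: str | None = None

    def validate(self) -> None:
        if self.histories < self.batches:
            raise ConfigError("histories must be >= batches")
        if self.phase_space and not Path(self.phase_space).exists():
            raise ConfigError(
                f"phase-space file not found: {self.phase_space}")


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {name!r}: {', '.join(sorted(unknown))}")


def _parse_source(block: dict) -> tuple[BeamSpec, str | None]:
    _check_keys(block, _SOURCE_KEYS, "source")
    particle = block.get("particle", "photon")
    spec = block.get("spectrum", {"mono": 1.0})
    if "mono" in spec:
        spectrum = ("mono", float(spec["mono"]))
    elif "lines" in spec:
        spectrum = ("lines", [(float(e), float(w))
                              for e, w in spec["lines"]])
    else:
        raise ConfigError("spectrum needs 'mono' or 'lines'")
    geo = block.get("geometry", {})
    if "parallel" in geo:
        g = geo["parallel"]
        geometry = ("parallel", float(g.get("width", 10.0)),
                    float(g.get("height", 10.0)), float(g.get("z", 0.0)))
    elif "disk" in geo:
        g = geo["disk"]
        geometry = ("disk", float(g["radius"]), float(g.get("z", 0.0)))
    elif "cylinder" in geo:
        g = geo["cylinder"]
        geometry = ("cylinder", float(g["radius"]),
                    float(g["half_height"]),
                    tuple(g.get("center", (0.0, 0.0, 0.0))))
    else:
        raise ConfigError("source geometry needs parallel/disk/cylinder")
    beam = BeamSpec(particle, spectrum, geometry,
                    direction=tuple(block.get("direction", (0, 0, 1))),
                    ssd=block.get("ssd"))
    return beam, block.get("phase_space")


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML run file, filling all defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    if "source" not in raw or "phantom" not in raw:
        raise ConfigError("config needs 'source' and 'phantom' blocks")
    beam, phsp = _parse_source(raw["source"])
    ph = raw["phantom"]
    _check_keys(ph, _PHANTOM_KEYS, "phantom")
    if "layers" not in ph:
        raise ConfigError("phantom needs 'layers'")
    layers = [(str(n), float(t)) for n, t in ph["layers"]]
    phys = raw.get("physics", {})
    _check_keys(phys, _PHYSICS_KEYS, "physics")
    elec = raw.get("electron", {})
    _check_keys(elec, _ELECTRON_KEYS, "electron")
    settings = TransportSettings(
        photon_cutoff=float(phys.get("photon_cutoff", 0.010)),
        electron_cutoff=float(phys.get("electron_cutoff", 0.189)),
        E_M=float(phys.get("E_M", 0.200)),
        E_B=float(phys.get("E_B", 0.010)),
        doppler=str(phys.get("doppler", "auto")),
        coherent_on=bool(phys.get("coherent", True)),
        pe_biased_fluorescence=bool(phys.get("biased_fluorescence",
                                             False)),
        roulette_survival=float(phys.get("roulette_survival", 1.0)),
        roulette_weight_floor=float(phys.get("roulette_weight_floor",
                                             0.0)),
        S_MAX=float(elec.get("S_MAX", 5.0)),
        f_E=float(elec.get("f_E", 0.25)),
        N_k=int(elec.get("N_k", 300)),
    )
    run = raw.get("run", {})
    _check_keys(run, _RUN_KEYS, "run")
    cfg = RunConfig(
        beam=beam, layers=layers,
        nxy=int(ph.get("nxy", 15)), dxy=float(ph.get("dxy", 2.0)),
        dz=float(ph.get("dz", 0.4)),
        settings=settings,
        histories=int(run.get("histories", 10_000)),
        batches=int(run.get("batches", 10)),
        seed=int(run.get("seed", 1)),
        output=str(run.get("output", "itmc_out")),
        phase_space=phsp,
    )
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig) -> dict:
    """Round-trippable dict representation of a config."""
    spec = {"mono": cfg.beam.spectrum[1]} \
        if cfg.beam.spectrum[0] == "mono" \
        else {"lines": [list(x) for x in cfg.beam.spectrum[1]]}
    g = cfg.beam.geometry
    if g[0] == "parallel":
        geo = {"parallel": {"width": g[1], "height": g[2], "z": g[3]}}
    elif g[0] == "disk":
        geo = {"disk": {"radius": g[1], "z": g[2]}}
    else:
        geo = {"cylinder": {"radius": g[1], "half_height": g[2],
                            "center": list(g[3])}}
    s = cfg.settings
    return {
        "source": {"particle": cfg.beam.particle, "spectrum": spec,
                   "geometry": geo,
                   "direction": list(cfg.beam.direction)},
        "phantom": {"layers": [[n, t] for n, t in cfg.layers],
                    "nxy": cfg.nxy, "dxy": cfg.dxy, "dz": cfg.dz},
        "physics": {"photon_cutoff": s.photon_cutoff,
                    "electron_cutoff": s.electron_cutoff,
                    "E_M": s.E_M, "E_B": s.E_B, "doppler": s.doppler},
        "electron": {"S_MAX": s.S_MAX, "f_E": s.f_E, "N_k": s.N_k},
        "run": {"histories": cfg.histories, "batches": cfg.batches,
                "seed": cfg.seed, "output": cfg.output},
    }
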