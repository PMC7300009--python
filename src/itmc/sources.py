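"""Primary-particle sources for the benchmark configurations.

Supported: parallel rectangular beams (field w x h defined at an entrance
plane, default direction +z), isotropic cylindrical volume sources (e.g. a
radioactive capsule), monoenergetic or discrete-line spectra, and a plain
text phase-space file with one particle per row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

PARTICLE_KINDS = ("photon", "electron", "positron")
KIND_CODE = {k: i for i, k in enumerate(PARTICLE_KINDS)}

PHSP_MAGIC = "#itmc-phsp-v1"
PHSP_COLUMNS = ["kind", "E", "x", "y", "z", "u", "v", "w", "weight"]


@dataclass
class BeamSpec:
    """Primary source description.

    ``spectrum`` is ``("mono", E)`` or ``("lines", [(E, w), ...])`` with
    weights summing to one.  ``geometry`` is
    ``("parallel", w, h, z0)`` (rectangular field centered on the z axis
    at plane z = z0, direction ``direction``) or
    ``("cylinder", radius, half_height, center)`` with isotropic emission.
    """

    particle: str
    spectrum: tuple
    geometry: tuple
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    ssd: float | None = None

    def __post_init__(self):
        if self.particle not in PARTICLE_KINDS:
            raise ValueError(f"unknown particle kind {self.particle!r}")
        if self.spectrum[0] == "lines":
            wsum = sum(w for _, w in self.spectrum[1])
            if abs(wsum - 1.0) > 1e-9:
                raise ValueError("line weights must sum to 1")
        if self.spectrum[0] not in ("mono", "lines"):
            raise ValueError(f"unknown spectrum {self.spectrum[0]!r}")
        if self.geometry[0] == "parallel":
            if self.geometry[1] <= 0 or self.geometry[2] <= 0:
                raise ValueError("field dimensions must be positive")

    @property
    def field_area(self) -> float:
        """Beam cross-sectional area (cm^2) for fluence normalization."""
        if self.geometry[0] == "parallel":
            return self.geometry[1] * self.geometry[2]
        if self.geometry[0] == "disk":
            return float(np.pi * self.geometry[1] ** 2)
        raise ValueError("fluence area undefined for volume sources")

    def mean_energy(self) -> float:
        if self.spectrum[0] == "mono":
            return float(self.spectrum[1])
        return float(sum(E * w for E, w in self.spectrum[1]))


def sample_energies(spec: BeamSpec, rng: np.random.Generator,
                    n: int) -> np.ndarray:
    if spec.spectrum[0] == "mono":
        return np.full(n, float(spec.spectrum[1]))
    lines = spec.spectrum[1]
    E = np.array([e for e, _ in lines])
    w = np.array([w for _, w in lines])
    # one uniform number against the line CDF (inverse-transform)
    cdf = np.cumsum(w)
    idx = np.searchsorted(cdf, rng.random(n) * cdf[-1])
    return E[np.clip(idx, 0, E.size - 1)]


def sample_primary(spec: BeamSpec, rng: np.random.Generator, n: int = 1):
    """Sample n primaries; returns dict of arrays (pos, dir, E, weight)."""
    E = sample_energies(spec, rng, n)
    if spec.geometry[0] == "parallel":
        _, w, h, z0 = spec.geometry
        x = (rng.random(n) - 0.5) * w
        y = (rng.random(n) - 0.5) * h
        pos = np.column_stack([x, y, np.full(n, float(z0))])
        d = np.asarray(spec.direction, dtype=float)
        d = d / np.linalg.norm(d)
        dirs = np.tile(d, (n, 1))
    elif spec.geometry[0] == "disk":
        _, radius, z0 = spec.geometry
        r = radius * np.sqrt(rng.random(n))
        a = 2.0 * np.pi * rng.random(n)
        pos = np.column_stack([r * np.cos(a), r * np.sin(a),
                               np.full(n, float(z0))])
        d = np.asarray(spec.direction, dtype=float)
        d = d / np.linalg.norm(d)
        dirs = np.tile(d, (n, 1))
    elif spec.geometry[0] == "cylinder":
        _, radius, half_h, center = spec.geometry
        r = radius * np.sqrt(rng.random(n))
        phi = 2.0 * np.pi * rng.random(n)
        z = (rng.random(n) * 2.0 - 1.0) * half_h
        pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z]) \
            + np.asarray(center, dtype=float)
        mu = rng.random(n) * 2.0 - 1.0
        phi_d = 2.0 * np.pi * rng.random(n)
        s = np.sqrt(1.0 - mu**2)
        dirs = np.column_stack([s * np.cos(phi_d), s * np.sin(phi_d), mu])
    else:
        raise ValueError(f"unknown source geometry {spec.geometry[0]!r}")
    return {"pos": pos, "dir": dirs, "E": E,
            "weight": np.ones(n), "kind": spec.particle}


# ---------------------------------------------------------------------------
# Phase-space file


def write_phase_space(path, kinds, E, pos, dirs, weights) -> None:
    """Write a plain-text phase-space file (one particle per row)."""
    n = len(E)
    rows = io.StringIO()
    for i in range(n):
        rows.write(
            f"{kinds[i]} {E[i]:.9e} "
            f"{pos[i][0]:.9e} {pos[i][1]:.9e} {pos[i][2]:.9e} "
            f"{dirs[i][0]:.15e} {dirs[i][1]:.15e} {dirs[i][2]:.15e} "
            f"{weights[i]:.9e}\n")
    checksum = float(np.sum(E))
    with open(path, "w") as fh:
        fh.write(PHSP_MAGIC + "\n")
        fh.write("#columns: " + " ".join(PHSP_COLUMNS) + "\n")
        fh.write(f"#count: {n}\n")
        fh.write(f"#checksum: {checksum:.9e}\n")
        fh.write(rows.getvalue())


@dataclass
class PhaseSpaceData:
    kinds: list[str]
    E: np.ndarray
    pos: np.ndarray
    dirs: np.ndarray
    weights: np.ndarray
    n_rejected: int = 0

    def __len__(self):
        return len(self.E)


def read_phase_space(path) -> PhaseSpaceData:
    """Read a phase-space file; malformed rows are skipped and counted.

    Directions with |norm - 1| < 1e-6 are renormalized; rows with a worse
    norm defect are rejected and counted.
    """
    kinds, E, pos, dirs, wts = [], [], [], [], []
    rejected = 0
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != PHSP_MAGIC:
            raise ValueError(f"not a phase-space file (magic {magic!r})")
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 9 or parts[0] not in PARTICLE_KINDS:
                rejected += 1
                continue
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError:
                rejected += 1
                continue
            d = np.array(vals[4:7])
            norm = np.linalg.norm(d)
            if abs(1.0 - norm) >= 1e-6:
                rejected += 1
                continue
            kinds.append(parts[0])
            E.append(vals[0])
            pos.append(vals[1:4])
            dirs.append(d / norm)
            wts.append(vals[7])
    if not kinds:
        raise ValueError("phase-space file contains no valid rows")
    return PhaseSpaceData(
        kinds=kinds, E=np.array(E), pos=np.array(pos),
        dirs=np.array(dirs), weights=np.array(wts), n_rejected=rejected)
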