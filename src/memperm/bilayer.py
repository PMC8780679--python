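"""Toy bilayer snapshots for structural-property analysis.

These snapshots are *synthetic* stand-ins for MD frames: enough geometry to
exercise density profiles, Voronoi area-per-lipid and deuterium order
parameters — per-lipid head-group triads in the membrane plane, a z
coordinate, per-carbon C-H orientation unit vectors, and masses.

Sign convention: the outer (extracellular) leaflet sits at z < 0, the inner
(cytoplasmic) leaflet at z > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["LipidRecord", "ToyBilayerSnapshot", "make_toy_bilayer",
           "COMPOSITIONS", "LIPID_MASSES"]

#: Molar masses, g/mol.
LIPID_MASSES = {"POPC": 760.08, "POPS": 783.99}
WATER_MASS = 18.015

#: Leaflet compositions {leaflet: {species: count}}.  "normal" has all PS in
#: the inner (cytoplasmic) leaflet; "cancer" exposes PS symmetrically.
COMPOSITIONS: Dict[str, Dict[str, Dict[str, int]]] = {
    "normal": {"outer": {"POPC": 36, "POPS": 0}, "inner": {"POPC": 12, "POPS": 24}},
    "cancer": {"outer": {"POPC": 24, "POPS": 12}, "inner": {"POPC": 24, "POPS": 12}},
}


@dataclass(frozen=True)
class LipidRecord:
    """One lipid: head-group triad in the xy plane plus chain orientations."""

    leaflet: str                  # "outer" (z<0) | "inner" (z>0)
    species: str
    triad_xy: np.ndarray          # (3, 2) nm, wrapped into the box
    z: float                      # nm
    orientations: np.ndarray      # (n_carbons, 3) C-H unit vectors
    mass: float                   # g/mol


@dataclass(frozen=True)
class ToyBilayerSnapshot:
    """A single toy frame: lipids plus optional bulk-water particles."""

    box: Tuple[float, float, float]     # (Lx, Ly, Lz) nm; z spans [-Lz/2, Lz/2]
    lipids: Tuple[LipidRecord, ...]
    particles: pd.DataFrame             # columns: leaflet, species, x, y, z, mass
    meta: dict = field(default_factory=dict)

    def leaflet_lipids(self, leaflet: str) -> List[LipidRecord]:
        if leaflet not in ("outer", "inner"):
            raise ValueError(f"unknown leaflet {leaflet!r}")
        return [l for l in self.lipids if l.leaflet == leaflet]

    @property
    def total_mass(self) -> float:
        return float(self.particles["mass"].sum())


def _draw_orientations(rng: np.random.Generator, n: int, spec) -> np.ndarray:
    """Unit C-H vectors with polar angle theta from ``spec``, uniform azimuth.

    spec: ("delta", theta_deg) | ("gaussian", mean_deg, sd_deg) | ("isotropic",)
    """
    kind = spec[0]
    if kind == "delta":
        theta = np.full(n, np.deg2rad(spec[1]))
        cos_t = np.cos(theta)
    elif kind == "gaussian":
        theta = np.deg2rad(rng.normal(spec[1], spec[2], size=n))
        cos_t = np.cos(theta)
    elif kind == "isotropic":
        cos_t = rng.uniform(-1.0, 1.0, size=n)
    else:
        raise ValueError(f"unknown tilt-angle distribution {kind!r}")
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, 1.0))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    v = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _leaflet_sites(rng: np.random.Generator, n: int, lx: float, ly: float,
                   placement: str) -> np.ndarray:
    if placement in ("grid", "jittered"):
        nx = int(np.ceil(np.sqrt(n)))
        ny = int(np.ceil(n / nx))
        xs = (np.arange(nx) + 0.5) * lx / nx
        ys = (np.arange(ny) + 0.5) * ly / ny
        pts = np.array([(x, y) for y in ys for x in xs])[:n]
        if placement == "jittered":
            amp = 0.3 * min(lx / nx, ly / ny)
            pts = pts + rng.uniform(-amp, amp, size=pts.shape)
    elif placement == "uniform":
        pts = np.column_stack([rng.uniform(0, lx, n), rng.uniform(0, ly, n)])
    else:
        raise ValueError(f"unknown placement {placement!r}")
    return np.column_stack([np.mod(pts[:, 0], lx), np.mod(pts[:, 1], ly)])


def make_toy_bilayer(n_outer: int = 36, n_inner: int = 36,
                     box: Tuple[float, float, float] = (6.0, 6.0, 8.0),
                     tilt_angle_dist=("gaussian", 25.0, 10.0),
                     seed: int = 0, *, placement: str = "jittered",
                     composition: str | Dict[str, Dict[str, int]] | None = None,
                     n_carbons: int = 16, n_water: int = 0,
                     leaflet_z: float = 1.5, z_jitter: float = 0.1,
                     bilayer_half: float = 2.2,
                     triad_radius: float = 0.15) -> ToyBilayerSnapshot:
    """Generate one toy bilayer frame.

    Parameters
    ----------
    n_outer, n_inner : int
        Lipids per leaflet (ignored when ``composition`` is given).
    box : (Lx, Ly, Lz)
        Periodic box, nm; z runs from -Lz/2 to +Lz/2.
    tilt_angle_dist
        C-H polar-angle distribution spec: ``("delta", theta_deg)``,
        ``("gaussian", mean_deg, sd_deg)`` or ``("isotropic",)``.
    placement : {"grid", "uniform", "jittered"}
        Point process for head-group triad sites in the leaflet plane.
    composition
        ``"normal"``/``"cancer"`` (see :data:`COMPOSITIONS`) or an explicit
        ``{leaflet: {species: count}}`` mapping; default all-POPC.
    n_water : int
        Bulk water particles split between the two slabs |z| > bilayer_half.
    """
    lx, ly, lz = box
    if lx <= 0 or ly <= 0 or lz <= 0:
        raise ValueError("box dimensions must be positive")
    if composition is None:
        comp = {"outer": {"POPC": n_outer}, "inner": {"POPC": n_inner}}
    elif isinstance(composition, str):
        try:
            comp = COMPOSITIONS[composition]
        except KeyError:
            raise ValueError(f"unknown composition preset {composition!r}") from None
    else:
        comp = composition
    counts = {leaf: sum(c for c in species.values() if c > 0)
              for leaf, species in comp.items()}
    if min(counts.values()) <= 0:
        raise ValueError("each leaflet needs at least one lipid")

    rng = np.random.default_rng(seed)
    lipids: List[LipidRecord] = []
    rows = []
    angles = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])
    triad_offsets = triad_radius * np.column_stack([np.cos(angles), np.sin(angles)])
    for leaflet, sign in (("outer", -1.0), ("inner", 1.0)):
        species_tags = [s for s, c in sorted(comp[leaflet].items()) for _ in range(c)]
        n = len(species_tags)
        sites = _leaflet_sites(rng, n, lx, ly, placement)
        rng.shuffle(species_tags)
        zs = sign * (leaflet_z + rng.uniform(-z_jitter, z_jitter, n))
        for i in range(n):
            triad = np.mod(sites[i] + triad_offsets, [lx, ly])
            orient = _draw_orientations(rng, n_carbons, tilt_angle_dist)
            sp = species_tags[i]
            lipids.append(LipidRecord(leaflet=leaflet, species=sp, triad_xy=triad,
                                      z=float(zs[i]), orientations=orient,
                                      mass=LIPID_MASSES[sp]))
            rows.append((leaflet, sp, sites[i, 0], sites[i, 1], float(zs[i]),
                         LIPID_MASSES[sp]))
    if n_water:
        half = lz / 2.0
        if bilayer_half >= half:
            raise ValueError("no room for water: bilayer_half >= Lz/2")
        zw = rng.uniform(bilayer_half, half, n_water)
        zw *= rng.choice([-1.0, 1.0], n_water)
        for j in range(n_water):
            rows.append(("water", "water", float(rng.uniform(0, lx)),
                         float(rng.uniform(0, ly)), float(zw[j]), WATER_MASS))
    particles = pd.DataFrame(rows, columns=["leaflet", "species", "x", "y", "z", "mass"])
    return ToyBilayerSnapshot(box=box, lipids=tuple(lipids), particles=particles,
                              meta={"seed": seed, "placement": placement,
                                    "tilt_angle_dist": tuple(tilt_angle_dist)})
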