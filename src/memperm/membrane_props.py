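"""Structural metrics of bilayer snapshots.

Three standard equilibration sanity checks for lipid bilayers:

- mass density profiles of system components along the bilayer normal,
- per-leaflet area per lipid from a periodic Voronoi tessellation of the
  projected head-group positions,
- deuterium order parameters S_CD = -1/2 <3 cos^2(theta) - 1> of the C-H
  bond angle theta to the bilayer normal, per carbon.

Operates on :class:`~memperm.bilayer.ToyBilayerSnapshot` frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, QhullError

from .bilayer import ToyBilayerSnapshot
from .constants import AMU_PER_NM3_TO_KG_PER_M3

__all__ = [
    "DensityProfile",
    "AreaPerLipidResult",
    "OrderParameterProfile",
    "density_profile",
    "area_per_lipid",
    "order_parameters",
]


@dataclass(frozen=True)
class DensityProfile:
    """Mass densities (kg/m^3) per component on z-slab midpoints."""

    z_mids: np.ndarray                    # nm
    densities: Dict[str, np.ndarray]      # label -> kg/m^3 per slab
    bin_width: float                      # nm
    box: Tuple[float, float, float]
    n_frames: int = 1

    def component(self, label: str) -> np.ndarray:
        return self.densities[label]


@dataclass(frozen=True)
class AreaPerLipidResult:
    """Voronoi polygon areas (nm^2) of one leaflet; a partition of the box."""

    leaflet: str
    areas: np.ndarray          # per-lipid polygon areas
    mean_area: float
    box_area: float


@dataclass(frozen=True)
class OrderParameterProfile:
    """S_CD per carbon, species and leaflet; -1 <= S_CD <= 0.5."""

    species: str
    table: pd.DataFrame        # columns: leaflet, carbon, s_cd, n_bonds

    def values(self, leaflet: str) -> np.ndarray:
        sub = self.table[self.table["leaflet"] == leaflet].sort_values("carbon")
        return sub["s_cd"].to_numpy()


def _as_frames(snapshots) -> List[ToyBilayerSnapshot]:
    if isinstance(snapshots, ToyBilayerSnapshot):
        return [snapshots]
    frames = list(snapshots)
    if not frames:
        raise ValueError("no snapshots supplied")
    return frames


def density_profile(snapshots, bin_width: float = 0.1,
                    grouping: Dict[str, Sequence[str] | None] | None = None) -> DensityProfile:
    """Mass histogram along z divided by slab volume Lx*Ly*bin_width.

    ``grouping`` maps component labels to lists of species tags (``None``
    selects everything); the default reports "system", "lipid", "water" and
    every species tag present.  Densities are averaged over frames.
    Convention: negative z is the outer (extracellular) leaflet.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    frames = _as_frames(snapshots)
    lx, ly, lz = frames[0].box
    n_bins = int(np.ceil(lz / bin_width - 1e-9))
    edges = -lz / 2.0 + bin_width * np.arange(n_bins + 1)
    if grouping is None:
        species = sorted(set(frames[0].particles["species"]))
        grouping = {"system": None,
                    "lipid": [s for s in species if s != "water"],
                    "water": ["water"]}
        grouping.update({s: [s] for s in species if s != "water"})
    if not grouping:
        raise ValueError("empty component grouping")

    slab_volume = lx * ly * bin_width      # nm^3
    acc = {label: np.zeros(n_bins) for label in grouping}
    for frame in frames:
        if frame.box != frames[0].box:
            raise ValueError("snapshots have inconsistent boxes")
        p = frame.particles
        for label, tags in grouping.items():
            sub = p if tags is None else p[p["species"].isin(tags)]
            hist, _ = np.histogram(sub["z"], bins=edges, weights=sub["mass"])
            acc[label] += hist
    dens = {label: h / len(frames) / slab_volume * AMU_PER_NM3_TO_KG_PER_M3
            for label, h in acc.items()}
    return DensityProfile(z_mids=0.5 * (edges[:-1] + edges[1:]), densities=dens,
                          bin_width=bin_width, box=frames[0].box,
                          n_frames=len(frames))


def _triad_centroid(triad_xy: np.ndarray, lx: float, ly: float) -> np.ndarray:
    """Centroid of three wrapped xy points under minimum image."""
    ref = triad_xy[0]
    d = triad_xy - ref
    d[:, 0] -= lx * np.round(d[:, 0] / lx)
    d[:, 1] -= ly * np.round(d[:, 1] / ly)
    c = ref + d.mean(axis=0)
    return np.array([np.mod(c[0], lx), np.mod(c[1], ly)])


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a convex polygon given unordered vertices."""
    c = vertices.mean(axis=0)
    ang = np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0])
    v = vertices[np.argsort(ang)]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def area_per_lipid(snapshot: ToyBilayerSnapshot, leaflet: str) -> AreaPerLipidResult:
    """Per-lipid areas by periodic Voronoi tessellation of one leaflet.

    Head-group sites (triad centroids projected on xy) are replicated on a
    3x3 grid of periodic images; the Voronoi cells of the central copies
    then tile the box exactly, and their areas are the per-lipid areas.
    """
    lipids = snapshot.leaflet_lipids(leaflet)
    if len(lipids) < 3:
        raise ValueError(f"need >= 3 lipids in leaflet {leaflet!r}, "
                         f"got {len(lipids)}")
    lx, ly, _ = snapshot.box
    sites = np.array([_triad_centroid(l.triad_xy, lx, ly) for l in lipids])
    shifts = np.array([(ix * lx, iy * ly) for ix in (-1, 0, 1) for iy in (-1, 0, 1)])
    tiled = (sites[None, :, :] + shifts[:, None, :]).reshape(-1, 2)
    central0 = np.flatnonzero((shifts == 0).all(axis=1))[0] * len(sites)
    try:
        vor = Voronoi(tiled)
    except QhullError as exc:
        raise ValueError(f"degenerate site set in leaflet {leaflet!r}: {exc}") from exc
    areas = np.empty(len(sites))
    for i in range(len(sites)):
        region = vor.regions[vor.point_region[central0 + i]]
        if -1 in region or len(region) < 3:
            raise ValueError("unbounded Voronoi cell; box replication too small")
        areas[i] = _polygon_area(vor.vertices[region])
    return AreaPerLipidResult(leaflet=leaflet, areas=areas,
                              mean_area=float(areas.mean()), box_area=lx * ly)


def order_parameters(snapshots, species: str) -> OrderParameterProfile:
    """Deuterium order parameter per carbon: S_CD = -1/2 <3 cos^2 theta - 1>.

    cos(theta) is the z-component of each C-H unit vector; the average runs
    over lipids of the species, bonds and frames, reported per leaflet.
    """
    frames = _as_frames(snapshots)
    sums: Dict[Tuple[str, int], List[float]] = {}
    for frame in frames:
        for lip in frame.lipids:
            if lip.species != species:
                continue
            cos_t = lip.orientations[:, 2]
            scd = -0.5 * (3.0 * cos_t ** 2 - 1.0)
            for carbon, val in enumerate(scd):
                sums.setdefault((lip.leaflet, carbon), []).append(float(val))
    if not sums:
        raise ValueError(f"no orientation vectors found for species {species!r}")
    rows = [(leaf, carbon, float(np.mean(vals)), len(vals))
            for (leaf, carbon), vals in sorted(sums.items())]
    table = pd.DataFrame(rows, columns=["leaflet", "carbon", "s_cd", "n_bonds"])
    return OrderParameterProfile(species=species, table=table)
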