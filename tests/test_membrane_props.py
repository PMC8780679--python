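"""Toy bilayer generation and structural metrics (density, APL, S_CD)."""

import numpy as np
import pytest

from memperm.bilayer import COMPOSITIONS, make_toy_bilayer
from memperm.constants import AMU_PER_NM3_TO_KG_PER_M3
from memperm.membrane_props import (area_per_lipid, density_profile,
                                    order_parameters)

# ------------------------------------------------------------------ bilayer


def test_delta_tilt_gives_vertical_vectors():
    snap = make_toy_bilayer(4, 4, box=(2.0, 2.0, 6.0),
                            tilt_angle_dist=("delta", 0.0), seed=1)
    for lip in snap.lipids:
        assert np.allclose(np.abs(lip.orientations[:, 2]), 1.0)
        assert np.allclose(lip.orientations[:, :2], 0.0, atol=1e-12)


def test_orientation_vectors_unit_norm_and_xy_wrapped():
    snap = make_toy_bilayer(20, 20, box=(5.0, 5.0, 8.0),
                            tilt_angle_dist=("isotropic",), seed=4)
    for lip in snap.lipids:
        norms = np.linalg.norm(lip.orientations, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-9
        assert np.all((lip.triad_xy[:, 0] >= 0) & (lip.triad_xy[:, 0] < 5.0))
        assert np.all((lip.triad_xy[:, 1] >= 0) & (lip.triad_xy[:, 1] < 5.0))


def test_leaflet_sign_convention():
    """Outer (extracellular) leaflet at z < 0, inner at z > 0."""
    snap = make_toy_bilayer(6, 6, box=(3.0, 3.0, 8.0), seed=2)
    for lip in snap.lipids:
        assert (lip.z < 0) == (lip.leaflet == "outer")


def test_grid_placement_lattice_spacing():
    snap = make_toy_bilayer(36, 36, box=(6.0, 6.0, 8.0), placement="grid",
                            tilt_angle_dist=("delta", 0.0), seed=0)
    sites = np.array([l.triad_xy.mean(axis=0) for l in snap.lipids
                      if l.leaflet == "outer"])
    # nearest-neighbor spacing on a 6x6 lattice in a 6 nm box is exactly 1 nm
    d = np.linalg.norm(sites[None] - sites[:, None], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert np.min(d) == pytest.approx(1.0, abs=1e-9)


def test_normal_composition_matches_leaflet_table():
    """Normal membrane: outer 36 POPC / 0 POPS, inner 12 POPC / 24 POPS."""
    snap = make_toy_bilayer(composition="normal", seed=3)
    outer = [l.species for l in snap.leaflet_lipids("outer")]
    inner = [l.species for l in snap.leaflet_lipids("inner")]
    assert outer.count("POPC") == 36 and outer.count("POPS") == 0
    assert inner.count("POPC") == 12 and inner.count("POPS") == 24
    cancer = COMPOSITIONS["cancer"]
    assert cancer["outer"] == {"POPC": 24, "POPS": 12}


def test_unknown_distribution_and_composition_rejected():
    with pytest.raises(ValueError, match="unknown tilt-angle"):
        make_toy_bilayer(4, 4, tilt_angle_dist=("cauchy", 1.0), seed=0)
    with pytest.raises(ValueError, match="unknown composition"):
        make_toy_bilayer(composition="tumourish", seed=0)
    with pytest.raises(ValueError, match="unknown placement"):
        make_toy_bilayer(4, 4, placement="poisson-disc", seed=0)


# ------------------------------------------------------------------ density

def test_density_conserves_total_mass():
    snap = make_toy_bilayer(16, 16, box=(4.0, 4.0, 8.0), seed=7, n_water=300)
    prof = density_profile(snap, bin_width=0.25)
    lx, ly, _ = snap.box
    integral = prof.densities["system"].sum() * prof.bin_width * lx * ly
    assert integral == pytest.approx(snap.total_mass * AMU_PER_NM3_TO_KG_PER_M3,
                                     rel=1e-9)


def test_density_doubling_mass_doubles_profile():
    snap = make_toy_bilayer(10, 10, box=(4.0, 4.0, 8.0), seed=9)
    prof = density_profile(snap, bin_width=0.5)
    heavy = snap.particles.copy()
    heavy["mass"] *= 2.0
    snap2 = type(snap)(box=snap.box, lipids=snap.lipids, particles=heavy)
    prof2 = density_profile(snap2, bin_width=0.5)
    assert np.allclose(prof2.densities["system"], 2.0 * prof.densities["system"])


def test_normal_membrane_has_no_pops_in_outer_leaflet():
    snap = make_toy_bilayer(composition="normal", seed=11)
    prof = density_profile(snap, bin_width=0.2)
    outer_bins = prof.z_mids < 0
    assert np.all(prof.densities["POPS"][outer_bins] == 0.0)
    assert prof.densities["POPS"][~outer_bins].sum() > 0


def test_mirrored_snapshot_reverses_profile():
    snap = make_toy_bilayer(12, 12, box=(4.0, 4.0, 8.0), seed=13, n_water=100)
    flipped = snap.particles.copy()
    flipped["z"] = -flipped["z"]
    snap2 = type(snap)(box=snap.box, lipids=snap.lipids, particles=flipped)
    a = density_profile(snap, bin_width=0.5).densities["system"]
    b = density_profile(snap2, bin_width=0.5).densities["system"]
    # interior bins mirror exactly (edge bins differ only by boundary ties)
    assert np.allclose(a[1:-1], b[::-1][1:-1])


# ---------------------------------------------------------- area per lipid

def test_square_lattice_areas_exact():
    snap = make_toy_bilayer(4, 4, box=(2.0, 2.0, 6.0), placement="grid",
                            tilt_angle_dist=("delta", 0.0), seed=0)
    res = area_per_lipid(snap, "outer")
    assert np.allclose(res.areas, 1.0, atol=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_voronoi_partition_conserves_box_area(seed):
    """Tessellation is a partition: polygon areas sum to Lx*Ly."""
    snap = make_toy_bilayer(25, 25, box=(5.0, 5.0, 8.0), placement="uniform",
                            seed=seed)
    for leaflet in ("outer", "inner"):
        res = area_per_lipid(snap, leaflet)
        assert res.areas.sum() == pytest.approx(res.box_area, rel=1e-9)
        assert res.mean_area == pytest.approx(res.box_area / len(res.areas),
                                              rel=1e-9)


def test_voronoi_partition_many_random_configurations():
    for seed in range(100):
        snap = make_toy_bilayer(9, 3, box=(3.0, 3.0, 8.0), placement="uniform",
                                seed=1000 + seed)
        res = area_per_lipid(snap, "outer")
        assert res.areas.sum() == pytest.approx(9.0, rel=1e-9)


def test_voronoi_areas_match_rasterization_oracle():
    """Polygon areas agree with brute-force nearest-site pixel counting."""
    from scipy.spatial import cKDTree
    snap = make_toy_bilayer(9, 3, box=(3.0, 3.0, 8.0), placement="jittered",
                            seed=42)
    res = area_per_lipid(snap, "outer")
    lx, ly, _ = snap.box
    from memperm.membrane_props import _triad_centroid
    sites = np.array([_triad_centroid(l.triad_xy, lx, ly)
                      for l in snap.leaflet_lipids("outer")])
    shifts = np.array([(i * lx, j * ly) for i in (-1, 0, 1) for j in (-1, 0, 1)])
    tiled = (sites[None] + shifts[:, None]).reshape(-1, 2)
    tree = cKDTree(tiled)
    h = 0.0015
    xs = np.arange(h / 2, lx, h)
    ys = np.arange(h / 2, ly, h)
    counts = np.zeros(len(sites))
    for x0 in xs:   # row-chunked to bound memory
        pts = np.column_stack([np.full(ys.size, x0), ys])
        _, idx = tree.query(pts)
        np.add.at(counts, idx % len(sites), 1.0)
    raster = counts * h * h
    assert np.max(np.abs(raster - res.areas) / res.areas) < 0.01


def test_too_few_lipids_rejected():
    snap = make_toy_bilayer(3, 2, box=(3.0, 3.0, 8.0), seed=0)
    with pytest.raises(ValueError, match=">= 3 lipids"):
        area_per_lipid(snap, "inner")


# ----------------------------------------------------------- order parameter

@pytest.mark.parametrize("theta,expected", [
    (0.0, -1.0),                                # bonds along the normal
    (90.0, 0.5),                                # bonds in the membrane plane
    (np.degrees(np.arccos(np.sqrt(1 / 3))), 0.0),   # magic angle
])
def test_scd_analytic_angles(theta, expected):
    snap = make_toy_bilayer(6, 6, box=(3.0, 3.0, 8.0),
                            tilt_angle_dist=("delta", theta), seed=5)
    prof = order_parameters(snap, "POPC")
    assert np.allclose(prof.values("outer"), expected, atol=1e-9)
    assert np.allclose(prof.values("inner"), expected, atol=1e-9)


def test_scd_isotropic_orientations_average_to_zero():
    snaps = [make_toy_bilayer(25, 25, box=(5.0, 5.0, 8.0),
                              tilt_angle_dist=("isotropic",), n_carbons=20,
                              seed=s) for s in range(5)]
    prof = order_parameters(snaps, "POPC")
    # 5 frames x 25 lipids x 20 carbons x 2 leaflets = 5000 draws
    mean_scd = prof.table["s_cd"].mean()
    assert abs(mean_scd) < 0.02
    assert ((prof.table["s_cd"] >= -1.0) & (prof.table["s_cd"] <= 0.5)).all()


def test_scd_invariant_under_azimuthal_rotation():
    snap = make_toy_bilayer(10, 10, box=(4.0, 4.0, 8.0),
                            tilt_angle_dist=("gaussian", 30.0, 10.0), seed=6)
    base = order_parameters(snap, "POPC").table["s_cd"].to_numpy()
    for ang in (0.3, 1.0, 2.0, 3.6, 5.1):
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        lipids = [type(l)(leaflet=l.leaflet, species=l.species,
                          triad_xy=l.triad_xy, z=l.z,
                          orientations=l.orientations @ rot.T, mass=l.mass)
                  for l in snap.lipids]
        snap2 = type(snap)(box=snap.box, lipids=tuple(lipids),
                           particles=snap.particles)
        rotated = order_parameters(snap2, "POPC").table["s_cd"].to_numpy()
        assert np.max(np.abs(rotated - base)) < 1e-12


def test_scd_missing_species_rejected():
    snap = make_toy_bilayer(4, 4, seed=0)
    with pytest.raises(ValueError, match="no orientation vectors"):
        order_parameters(snap, "DPPC")
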