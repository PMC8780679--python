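"""WHAM solver and PMF post-processing."""

import numpy as np
import pytest

import memperm as mp
from memperm import wham
from memperm.constants import rt
from memperm.langevin import WindowTrace

RT = rt(310.0)
BULK_BOTH = [(-2.2, -2.0), (2.0, 2.2)]


def _trace(positions, center=0.0, k=100.0, stride=0.1):
    positions = np.asarray(positions, dtype=float)
    return WindowTrace(center=center, force_constant=k,
                       times=stride * np.arange(positions.size),
                       positions=positions, seed=0)


@pytest.fixture(scope="module")
def pooled_flat_window():
    """One flat-landscape window with 2e5 equilibrium samples (pooled replicas)."""
    land, diff = mp.make_reference_landscape("flat", D0=0.04)

    def make(center, seed):
        proto = mp.UmbrellaProtocol(window_centers=(center,), n_steps=135_000,
                                    discard_fraction=0.074, save_stride=10,
                                    base_seed=seed)
        samples = mp.simulate_ensemble(land, diff, center, proto, 16).ravel()
        return _trace(samples, center=center)

    return make


# ------------------------------------------------------------ histogramming

def test_histogram_counts_single_bin():
    tr = _trace(np.full(50, 0.05))
    hist = wham.build_histograms([tr], bin_width=0.1, z_range=(0.0, 0.2))
    assert hist.counts.tolist() == [[50, 0]]
    assert hist.n_samples.tolist() == [50]


def test_histogram_rows_stay_per_window():
    h = wham.build_histograms([_trace(np.full(10, 0.05), center=0.0),
                               _trace(np.full(20, 0.15), center=0.1)],
                              bin_width=0.1, z_range=(0.0, 0.2))
    assert h.counts.shape == (2, 2)
    assert h.counts.tolist() == [[10, 0], [0, 20]]


def test_histogram_overflow_reported_and_blocks_solve():
    tr = _trace(np.concatenate([np.full(90, 0.05), np.full(10, 5.0)]))
    hist = wham.build_histograms([tr], bin_width=0.1, z_range=(0.0, 0.2))
    assert hist.n_overflow == 10
    assert hist.overflow_fraction == pytest.approx(0.1)
    with pytest.raises(ValueError, match="overflow"):
        wham.solve_wham(hist)
    with pytest.raises(ValueError, match="no traces"):
        wham.build_histograms([], 0.1, (0, 1))
    with pytest.raises(ValueError, match="zero-width"):
        wham.build_histograms([tr], 0.1, (0.2, 0.2))


def test_flat_protocol_modal_bins_track_centers(flat_traces):
    hist = wham.build_histograms(flat_traces, bin_width=0.02, z_range=(-2.2, 2.2))
    mids = hist.midpoints
    for row, center in zip(hist.counts, hist.centers):
        mode = mids[np.argmax(row)]
        assert abs(mode - center) <= 0.06 + 1e-9   # within a few bins


# ------------------------------------------------------------------- solver

def test_single_window_equals_direct_reweighting(pooled_flat_window):
    """WHAM with one window reduces to unbias-by-hand exactly.

    A biased histogram samples exp(-beta(dG + w)), so the direct estimate is
    dG = -RT ln(hist) - w(z) up to a constant.
    """
    tr = pooled_flat_window(0.0, seed=21)
    hist = wham.build_histograms([tr], bin_width=0.02, z_range=(-0.8, 0.8))
    pmf = wham.solve_wham(hist)
    mids = hist.midpoints
    counts = hist.counts[0].astype(float)
    valid = counts > 0
    direct = -RT * np.log(counts[valid]) - 50.0 * mids[valid] ** 2
    est = pmf.dG[valid]
    diff = (est - est.mean()) - (direct - direct.mean())
    assert np.max(np.abs(diff)) < 1e-9
    # unbiasing cancels the only bias: flat within sampling noise
    rich = valid & (counts >= 200)
    flat_part = pmf.dG[rich]
    assert np.sqrt(np.mean((flat_part - flat_part.mean()) ** 2)) < 0.2


def test_two_overlapping_windows_recover_flat(pooled_flat_window):
    traces = [pooled_flat_window(-0.1, seed=33), pooled_flat_window(0.1, seed=57)]
    hist = wham.build_histograms(traces, bin_width=0.02, z_range=(-0.9, 0.9))
    pmf = wham.solve_wham(hist)
    counts = hist.counts.sum(axis=0)
    rich = counts >= 400
    vals = pmf.dG[rich]
    assert np.sqrt(np.mean((vals - vals.mean()) ** 2)) < 0.2


def test_gauge_invariance_of_window_free_energies(gauss_traces):
    hist = wham.build_histograms(gauss_traces, bin_width=0.02, z_range=(-2.2, 2.2))
    a = wham.solve_wham(hist, tol=1e-8)
    b = wham.solve_wham(hist, tol=1e-8,
                        f_init=7.3 * np.ones(len(gauss_traces)))
    sel = a.valid & b.valid
    da = a.dG[sel] - a.dG[sel].mean()
    db = b.dG[sel] - b.dG[sel].mean()
    assert np.max(np.abs(da - db)) < 1e-5


def test_wham_recovers_gaussian_barrier_landscape(gauss_pair, gauss_traces):
    """Parameter recovery: truth reproduced to < 0.5 kJ/mol RMS over |z|<=2."""
    land, _ = gauss_pair
    hist = wham.build_histograms(gauss_traces, bin_width=0.02, z_range=(-2.2, 2.2))
    pmf = wham.reference_to_bulk(wham.solve_wham(hist), BULK_BOTH)
    truth = np.asarray(land.value(pmf.z_grid))
    sel = (np.abs(pmf.z_grid) <= 2.0) & pmf.valid
    rms = np.sqrt(np.mean((pmf.dG[sel] - truth[sel]) ** 2))
    assert rms < 0.5
    assert np.nanmax(pmf.dG) == pytest.approx(10.0, abs=0.5)
    # truth is zero in bulk water
    assert abs(pmf.dG[np.argmin(np.abs(pmf.z_grid - 2.19))]) < 0.3
    assert abs(pmf.dG[np.argmin(np.abs(pmf.z_grid + 2.19))]) < 0.3


def test_tightening_tolerance_refines_toward_fixed_point(gauss_pair,
                                                         gauss_traces):
    """Lower tol brings the iterate monotonically closer to the converged
    self-consistent solution, whose truth error meets the recovery bound."""
    land, _ = gauss_pair
    hist = wham.build_histograms(gauss_traces, bin_width=0.02, z_range=(-2.2, 2.2))
    fixed = wham.reference_to_bulk(wham.solve_wham(hist, tol=1e-10), BULK_BOTH)
    sel = np.abs(fixed.z_grid) <= 2.0
    dists = []
    for tol in (1e-1, 1e-3, 1e-5, 1e-7):
        pmf = wham.reference_to_bulk(wham.solve_wham(hist, tol=tol), BULK_BOTH)
        dists.append(np.sqrt(np.mean((pmf.dG[sel] - fixed.dG[sel]) ** 2)))
    assert all(b <= a + 1e-9 for a, b in zip(dists[:-1], dists[1:]))
    truth = np.asarray(land.value(fixed.z_grid))
    assert np.sqrt(np.mean((fixed.dG[sel] - truth[sel]) ** 2)) < 0.5


def test_non_convergence_raises_with_diagnostics(gauss_traces):
    hist = wham.build_histograms(gauss_traces, bin_width=0.02, z_range=(-2.2, 2.2))
    with pytest.raises(wham.WhamConvergenceError) as exc:
        wham.solve_wham(hist, tol=1e-12, max_iter=3)
    assert exc.value.iterations == 3
    assert exc.value.last_delta > 0


# -------------------------------------------------------------- referencing

def test_reference_subtracts_bulk_mean_and_is_idempotent():
    pmf = wham.PmfProfile(z_grid=np.array([0.0, 1.0, 2.0]),
                          dG=np.array([5.0, 5.0, 3.0]))
    ref = wham.reference_to_bulk(pmf, (-0.5, 1.5))
    assert np.allclose(ref.dG, [0.0, 0.0, -2.0])
    assert ref.reference == "bulk-zeroed"
    again = wham.reference_to_bulk(ref, (-0.5, 1.5))
    assert np.allclose(again.dG, ref.dG)
    with pytest.raises(ValueError, match="no valid overlap"):
        wham.reference_to_bulk(pmf, (10.0, 11.0))


# ---------------------------------------------------------------- smoothing

def test_smoothing_constant_profile_unchanged():
    z = np.arange(0, 1.0, 0.02)
    pmf = wham.PmfProfile(z_grid=z, dG=np.full(z.size, 3.3))
    sm = wham.smooth_pmf(pmf, span=0.05)
    assert sm.smoothed
    assert np.allclose(sm.dG, 3.3)


def test_smoothing_spreads_spike_over_three_bins():
    z = np.arange(0, 0.2, 0.02)
    dG = np.zeros(z.size)
    dG[5] = 9.0
    sm = wham.smooth_pmf(wham.PmfProfile(z_grid=z, dG=dG), span=0.05)
    assert sm.dG[5] == pytest.approx(3.0)       # spike height / 3
    assert sm.dG[4] == pytest.approx(3.0)
    assert sm.dG[2] == pytest.approx(0.0)


def test_smoothing_matches_brute_force_and_preserves_linear():
    rng = np.random.default_rng(5)
    z = np.arange(-1.0, 1.0, 0.02)
    dG = rng.normal(size=z.size)
    sm = wham.smooth_pmf(wham.PmfProfile(z_grid=z, dG=dG), span=0.05)
    brute = np.array([dG[np.abs(z - z[i]) <= 0.025 + 1e-12].mean()
                      for i in range(z.size)])
    assert np.allclose(sm.dG, brute, atol=1e-12)
    # interior of a linear profile is invariant under centered averaging
    lin = wham.smooth_pmf(wham.PmfProfile(z_grid=z, dG=2.0 * z + 1.0), span=0.05)
    assert np.allclose(lin.dG[1:-1], (2.0 * z + 1.0)[1:-1], atol=1e-12)
    with pytest.raises(ValueError, match="span"):
        wham.smooth_pmf(wham.PmfProfile(z_grid=z, dG=dG), span=0.001)


# ----------------------------------------------------------- leaflet assembly

def test_symmetrize_duplicates_leaflet():
    half = wham.PmfProfile(z_grid=np.array([-2.0, -1.0, 0.0]),
                           dG=np.array([0.0, 3.0, 10.0]), side="outer")
    full = wham.symmetrize_cancer(half)
    assert np.allclose(full.z_grid, [-2.0, -1.0, 0.0, 1.0, 2.0])
    assert np.allclose(full.dG, [0.0, 3.0, 10.0, 3.0, 0.0])
    assert np.allclose(full.dG, full.dG[::-1])      # exact mirror
    assert full.z_grid[np.argmax(full.dG)] == 0.0
    with pytest.raises(ValueError, match="core"):
        wham.symmetrize_cancer(wham.PmfProfile(z_grid=np.array([-2.0, -1.5]),
                                               dG=np.zeros(2)))


def test_symmetrized_recovery_matches_truth_on_mirror_side(gauss_pair,
                                                           gauss_half_traces):
    """Truth is symmetric, so the duplicated leaflet matches it on z > 0."""
    land, _ = gauss_pair
    hist = wham.build_histograms(gauss_half_traces["outer"], bin_width=0.02,
                                 z_range=(-2.2, 0.6))
    pmf = wham.reference_to_bulk(wham.solve_wham(hist, side="outer"),
                                 (-2.2, -2.0))
    full = wham.symmetrize_cancer(pmf)
    sel = (full.z_grid > 0) & (full.z_grid <= 2.0) & full.valid
    truth = np.asarray(land.value(full.z_grid[sel]))
    assert np.sqrt(np.mean((full.dG[sel] - truth) ** 2)) < 0.5


def test_join_identical_halves_is_seamless():
    z_out = np.array([-2.0, -1.0, 0.0])
    z_in = np.array([0.0, 1.0, 2.0])
    outer = wham.PmfProfile(z_grid=z_out, dG=np.array([0.0, 4.0, 9.0]),
                            reference="bulk-zeroed", side="outer")
    inner = wham.PmfProfile(z_grid=z_in, dG=np.array([9.0, 4.0, 0.0]),
                            reference="bulk-zeroed", side="inner")
    full = wham.join_normal_leaflets(outer, inner)
    assert full.meta["core_mismatch_kj_mol"] == pytest.approx(0.0)
    assert np.allclose(full.dG, full.dG[::-1])
    assert full.z_grid.size == 5                    # z = 0 not duplicated


def test_join_reports_core_mismatch_and_restores_continuity():
    outer = wham.PmfProfile(z_grid=np.array([-2.0, -1.0, 0.0]),
                            dG=np.array([0.0, 4.0, 9.0]),
                            reference="bulk-zeroed", side="outer")
    inner = wham.PmfProfile(z_grid=np.array([0.0, 1.0, 2.0]),
                            dG=np.array([10.0, 5.0, 1.0]),
                            reference="bulk-zeroed", side="inner")
    full = wham.join_normal_leaflets(outer, inner)
    assert full.meta["core_mismatch_kj_mol"] == pytest.approx(1.0)
    i0 = np.argmin(np.abs(full.z_grid))
    assert full.dG[i0] == pytest.approx(9.0)
    assert full.dG[i0 + 1] == pytest.approx(4.0)    # inner shifted down by 1
    with pytest.raises(ValueError, match="bulk-referenced"):
        wham.join_normal_leaflets(
            wham.PmfProfile(z_grid=np.array([-1.0, 0.0]), dG=np.zeros(2)),
            inner)


def test_join_asymmetric_truth_is_continuous_at_core():
    """Leaflets with different well depths still join without a jump."""
    z_out = np.arange(-2.2, 0.01, 0.02)
    z_in = np.arange(0.0, 2.21, 0.02)
    g_out = 10.0 * np.exp(-z_out ** 2 / 0.5) - 3.0 * np.exp(-(z_out + 1.3) ** 2 / 0.2)
    g_in = 10.0 * np.exp(-z_in ** 2 / 0.5) - 1.0 * np.exp(-(z_in - 1.3) ** 2 / 0.2)
    outer = wham.reference_to_bulk(
        wham.PmfProfile(z_grid=z_out, dG=g_out, side="outer"), (-2.2, -2.0))
    inner = wham.reference_to_bulk(
        wham.PmfProfile(z_grid=z_in, dG=g_in, side="inner"), (2.0, 2.2))
    full = wham.join_normal_leaflets(outer, inner)
    i0 = np.argmin(np.abs(full.z_grid))
    assert abs(full.dG[i0 + 1] - full.dG[i0]) < 0.5    # no seam jump
    assert np.all(np.diff(full.z_grid) > 0)


# -------------------------------------------------------------- convergence

def test_convergence_zero_delta_for_time_invariant_data():
    rng = np.random.default_rng(3)
    block = rng.normal(0.0, 0.15, 2000)
    positions = np.tile(block, 3)                  # identical thirds
    tr = _trace(positions)
    report = wham.check_convergence([tr], n_intervals=3, z_range=(-0.8, 0.8))
    assert report.max_deltas == pytest.approx((0.0, 0.0), abs=1e-12)
    assert report.converged


def test_convergence_flat_protocol_converges(flat_traces):
    report = wham.check_convergence(flat_traces, n_intervals=3,
                                    z_range=(-2.2, 2.2),
                                    bulk_region=BULK_BOTH)
    assert report.converged
    assert report.max_deltas[-1] < 1.0


def test_convergence_needs_two_intervals(flat_traces):
    with pytest.raises(ValueError, match="at least 2"):
        wham.check_convergence(flat_traces, n_intervals=1)
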