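"""Source grid, leadfield, LCMV beamforming, bootstrap threshold and D."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from megdbs.core import Recording
from megdbs.forward import dipole_field
from megdbs.phantom import make_sensor_array
from megdbs.source import (DResult, SourceMap, active_map,
                           bootstrap_threshold, build_grid,
                           compute_leadfield, data_covariance, lcmv_weights,
                           overlap_D, regularize_cov, source_power_at)

FS = 2400.0


@pytest.fixture(scope="module")
def sens():
    return make_sensor_array(128, 0.12, seed=1)


@pytest.fixture(scope="module")
def coarse_grid(sens):
    return build_grid(sens, spacing=0.01)


@pytest.fixture(scope="module")
def coarse_lf(coarse_grid, sens):
    return compute_leadfield(coarse_grid, sens)


class TestGrid:
    def test_all_points_strictly_inside(self, sens, coarse_grid):
        r = np.linalg.norm(coarse_grid.points - sens.sphere_center, axis=1)
        assert np.all(r < 0.95 * sens.sphere_radius)

    def test_count_matches_analytic_volume(self, sens):
        grid = build_grid(sens, spacing=5e-3)
        expect = 4.0 / 3.0 * np.pi * (0.95 * sens.sphere_radius) ** 3 / 5e-3 ** 3
        assert abs(grid.n_voxels - expect) / expect < 0.15

    def test_count_scales_inverse_cubically_with_spacing(self, sens):
        n1 = build_grid(sens, spacing=0.01).n_voxels
        n2 = build_grid(sens, spacing=0.005).n_voxels
        assert 6 < n2 / n1 < 10


class TestLeadfield:
    def test_columns_match_direct_forward_solution(self, sens, coarse_grid,
                                                   coarse_lf):
        v = coarse_grid.n_voxels // 2
        pos = coarse_grid.points[v]
        for ax, e in enumerate(np.eye(3)):
            direct = dipole_field(pos, e, sens)
            assert np.allclose(coarse_lf.matrix[:, 3 * v + ax], direct,
                               rtol=0, atol=1e-12 * np.abs(direct).max() + 1e-30)

    def test_linear_in_moment(self, sens, coarse_grid, coarse_lf):
        v = 10
        pos = coarse_grid.points[v]
        mom = np.array([1e-9, -2e-9, 0.5e-9])
        combo = coarse_lf.matrix[:, 3 * v:3 * v + 3] @ mom
        assert np.allclose(combo, dipole_field(pos, mom, sens), rtol=1e-10)

    def test_radial_moment_columns_are_silent(self, sens, coarse_grid,
                                              coarse_lf):
        v = coarse_grid.n_voxels // 3
        u = coarse_grid.points[v] - sens.sphere_center
        u /= np.linalg.norm(u)
        radial = coarse_lf.matrix[:, 3 * v:3 * v + 3] @ u
        block = coarse_lf.matrix[:, 3 * v:3 * v + 3]
        assert np.linalg.norm(radial) < 1e-3 * np.linalg.norm(block)


class TestRegularize:
    def test_identity_unchanged(self):
        assert np.allclose(regularize_cov(np.eye(5)), np.eye(5))

    def test_small_eigenvalues_raised_to_median(self):
        C = np.diag([4.0, 3.0, 2.0, 1.0])
        out = regularize_cov(C)
        assert np.allclose(np.sort(np.linalg.eigvalsh(out)),
                           [2.5, 2.5, 3.0, 4.0])

    def test_condition_bounded_by_max_over_median(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((20, 20))
        C = A @ A.T
        out = regularize_cov(C)
        w = np.linalg.eigvalsh(C)
        assert np.linalg.cond(out) <= w.max() / np.median(w) * (1 + 1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            regularize_cov(np.arange(9.0).reshape(3, 3))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_spectrum_floor_at_median(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((8, 8))
        C = A @ A.T
        w_in = np.linalg.eigvalsh(C)
        out = regularize_cov(C)
        w_out = np.linalg.eigvalsh(out)
        assert np.all(w_out >= np.median(w_in) - 1e-9 * w_in.max())
        assert np.allclose(out, out.T)


@pytest.fixture(scope="module")
def dipole_session(sens, coarse_lf):
    """Single-dipole recording with weak noise (conditions the covariance)."""
    rng = np.random.default_rng(3)
    t = np.arange(int(12 * FS)) / FS
    pos = np.array([0.045, 0.0, 0.0])
    topo = dipole_field(pos, np.array([0.0, 5e-8, 0.0]), sens)
    data = np.outer(topo, np.sin(2 * np.pi * 12 * t))
    noise = 1e-14 * rng.standard_normal(data.shape)
    rec = Recording(data=data + noise, fs=FS, sensors=sens)
    empty = Recording(data=1e-14 * rng.standard_normal(data.shape), fs=FS,
                      sensors=sens)
    data_cov = regularize_cov(data_covariance(rec))
    noise_cov = regularize_cov(data_covariance(empty))
    w = lcmv_weights(data_cov, noise_cov, coarse_lf)
    return rec, w, pos


class TestLcmv:
    def test_unit_gain_on_non_silent_subspace(self, coarse_lf, dipole_session):
        rec, w, _ = dipole_session
        v = coarse_lf.n_voxels // 2
        L = coarse_lf.matrix[:, 3 * v:3 * v + 3]
        G = w.weights[v] @ L          # 3x3, acts as identity on rank-2 space
        # G is a projector onto the non-silent moment subspace
        assert np.linalg.norm(G @ G - G) < 1e-8 * max(np.linalg.norm(G), 1)
        assert np.linalg.matrix_rank(G, tol=1e-6) >= 2
        # unit gain: a tangential moment passes through unchanged
        u = coarse_lf.grid.points[v] - rec.sensors.sphere_center
        u /= np.linalg.norm(u)
        tang = np.cross(u, [0.0, 0.0, 1.0])
        tang /= np.linalg.norm(tang)
        assert np.linalg.norm(G @ tang - tang) < 1e-6

    def test_localizes_simulated_dipole(self, dipole_session, coarse_lf):
        rec, w, pos = dipole_session
        smap = source_power_at(rec, w, 12.0)
        best = coarse_lf.grid.points[np.argmax(smap.power)]
        assert np.linalg.norm(best - pos) <= np.sqrt(3) * coarse_lf.grid.spacing + 1e-12

    def test_power_scales_quadratically_with_data(self, dipole_session):
        rec, w, _ = dipole_session
        smap1 = source_power_at(rec, w, 12.0)
        smap2 = source_power_at(rec.copy_with(2.0 * rec.data), w, 12.0)
        ok = smap1.power > 0
        assert np.allclose(smap2.power[ok] / smap1.power[ok], 4.0, rtol=1e-9)

    def test_zero_data_gives_zero_map(self, dipole_session):
        rec, w, _ = dipole_session
        smap = source_power_at(rec.copy_with(np.zeros_like(rec.data)), w, 12.0)
        assert np.all(smap.power == 0)

    def test_per_window_mean_equals_power(self, dipole_session):
        rec, w, _ = dipole_session
        smap = source_power_at(rec, w, 12.0)
        assert np.allclose(smap.per_window_power.mean(axis=1), smap.power)


def toy_map(P, valid=None):
    grid = build_grid(make_sensor_array(32, 0.12, seed=5), spacing=0.05)
    n = P.shape[0]
    pts = np.zeros((n, 3))
    g = type(grid)(points=pts, spacing=0.05, inside_mask=np.ones(n, bool))
    return SourceMap(power=P.mean(axis=1), frequency=12.0, grid=g,
                     per_window_power=P, valid=valid)


class TestBootstrap:
    def test_identical_windows_give_exact_threshold(self):
        P = np.tile(np.arange(1.0, 21.0)[:, None], (1, 10))
        thr = bootstrap_threshold(toy_map(P), n_iter=200, seed=0)
        assert np.isclose(thr, np.percentile(np.arange(1.0, 21.0), 95),
                          rtol=1e-9)

    def test_invariant_to_voxel_order(self):
        rng = np.random.default_rng(1)
        P = rng.gamma(2.0, 1.0, (30, 16))
        thr1 = bootstrap_threshold(toy_map(P), n_iter=500, seed=3)
        thr2 = bootstrap_threshold(toy_map(P[::-1]), n_iter=500, seed=3)
        assert np.isclose(thr1, thr2, rtol=1e-12)

    def test_matches_large_replicate_oracle(self):
        rng = np.random.default_rng(2)
        P = rng.gamma(2.0, 1.0, (40, 24))
        thr = bootstrap_threshold(toy_map(P), n_iter=20_000, seed=5)
        # independent oracle: direct index resampling, 1e5 replicates
        orng = np.random.default_rng(99)
        vals = []
        for _ in range(10):
            idx = orng.integers(0, 24, size=(10_000, 24))
            vals.append(P[:, idx].mean(axis=2).ravel())
        oracle = np.percentile(np.concatenate(vals), 95)
        assert abs(thr - oracle) / oracle < 0.02

    def test_threshold_monotone_in_percentile(self):
        rng = np.random.default_rng(3)
        P = rng.gamma(2.0, 1.0, (30, 16))
        t90 = bootstrap_threshold(toy_map(P), n_iter=1000, percentile=90, seed=1)
        t99 = bootstrap_threshold(toy_map(P), n_iter=1000, percentile=99, seed=1)
        assert t90 < t99

    def test_excluding_everything_rejected(self):
        P = np.ones((5, 10))
        with pytest.raises(ValueError, match="excluded"):
            bootstrap_threshold(toy_map(P), exclude=np.ones(5, bool))

    def test_too_few_windows_rejected(self):
        P = np.ones((5, 4))
        with pytest.raises(ValueError, match="8 windows"):
            bootstrap_threshold(toy_map(P))


class TestActiveAndD:
    def test_thresholding_matches_brute_force(self):
        rng = np.random.default_rng(4)
        P = rng.gamma(2.0, 1.0, (50, 12))
        smap = toy_map(P)
        am = active_map(smap, 2.0)
        assert np.array_equal(am.active, smap.power > 2.0)
        assert active_map(smap, np.inf).active.sum() == 0
        assert active_map(smap, -1.0).active.sum() == 50

    def test_d_identity_disjoint_and_half(self):
        P = np.ones((10, 10))
        a = active_map(toy_map(P), 0.5)
        a.active = np.zeros(10, bool)
        a.active[:2] = True
        b = active_map(toy_map(P), 0.5)
        b.active = np.zeros(10, bool)
        assert overlap_D(a, a).d == 1.0
        b.active[5:7] = True
        assert overlap_D(a, b).d == 0.0
        c = active_map(toy_map(P), 0.5)
        c.active = np.zeros(10, bool)
        c.active[:1] = True        # subset of a with |a|=2
        assert overlap_D(c, a).d == 0.5

    def test_both_empty_rejected(self):
        P = np.ones((10, 10))
        a = active_map(toy_map(P), np.inf)
        with pytest.raises(ValueError, match="undefined"):
            overlap_D(a, a)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_d_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        P = np.ones((20, 10))
        a = active_map(toy_map(P), 0.5)
        b = active_map(toy_map(P), 0.5)
        a.active = rng.random(20) < 0.4
        b.active = rng.random(20) < 0.4
        if not (a.active.any() or b.active.any()):
            a.active[0] = True
        ab = overlap_D(a, b)
        ba = overlap_D(b, a)
        assert ab.d == ba.d
        assert 0.0 <= ab.d <= 1.0
        assert ab.d == ab.n_intersection / ab.n_union
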