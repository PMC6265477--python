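"""FES reconstruction, basin finding, minimax paths, mechanism reports."""

import numpy as np
import pytest
from scipy import ndimage

from usb1mech.fes import (
    FESGrid,
    convergence_check,
    default_axes,
    find_basins,
    mechanism_order,
    minimax_path,
    reconstruct_fes,
    slice_fes_2d,
)
from usb1mech.metad import Hill, HillsLog
from usb1mech.surfaces import make_mechanism_surface


def _log_1d(entries, name="x"):
    log = HillsLog([name])
    for i, (c, w, h) in enumerate(entries):
        log.append(Hill(0.1 * (i + 1), np.array([c]), np.array([w]), h))
    return log


def bruteforce_bottleneck(values, start, goal):
    """Independent oracle: binary search over thresholds + connectivity."""
    levels = np.unique(values)
    lo, hi = 0, len(levels) - 1
    struct = np.ones((3,) * values.ndim, dtype=bool)

    def connected(t):
        mask = values <= t
        if not (mask[start] and mask[goal]):
            return False
        lab, _ = ndimage.label(mask, structure=struct)
        return lab[start] == lab[goal]

    while lo < hi:
        mid = (lo + hi) // 2
        if connected(levels[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(levels[lo])


class TestReconstruct:
    def test_single_hill_profile(self):
        log = _log_1d([(0.0, 0.1, 0.1)])
        grid = reconstruct_fes(log, [("x", -1.0, 1.0, 2001)])
        i0 = grid.nearest_node([0.0])
        isig = grid.nearest_node([0.1])
        ifar = grid.nearest_node([0.9])
        assert grid.values[i0] == pytest.approx(0.0, abs=1e-12)
        assert grid.values[isig] == pytest.approx(0.1 - 0.1 * np.exp(-0.5),
                                                  abs=1e-6)
        assert grid.values[ifar] == pytest.approx(0.1, abs=1e-6)

    def test_two_identical_distant_hills_make_equal_wells(self):
        log = _log_1d([(-2.0, 0.1, 0.1), (2.0, 0.1, 0.1)])
        grid = reconstruct_fes(log, [("x", -3.0, 3.0, 601)])
        a = grid.values[grid.nearest_node([-2.0])]
        b = grid.values[grid.nearest_node([2.0])]
        assert abs(a - b) < 1e-9

    def test_empty_log_gives_flat_zero(self):
        grid = reconstruct_fes(HillsLog(["x"]), [("x", 0.0, 1.0, 11)])
        assert np.all(grid.values == 0.0)

    def test_linearity_in_the_log(self, rng):
        axes = [("x", -2.0, 2.0, 201)]
        ha = [(rng.uniform(-1, 1), 0.1, 0.1) for _ in range(10)]
        hb = [(rng.uniform(-1, 1), 0.1, 0.1) for _ in range(7)]
        fa = reconstruct_fes(_log_1d(ha), axes).values
        fb = reconstruct_fes(_log_1d(hb), axes).values
        fab = reconstruct_fes(_log_1d(ha + hb), axes).values
        combined = fa + fb
        assert np.allclose(fab - fab.min(), combined - combined.min(),
                           atol=1e-9)

    def test_hills_outside_axes_warn(self):
        log = _log_1d([(10.0, 0.1, 0.1), (0.0, 0.1, 0.1)])
        with pytest.warns(UserWarning, match="outside"):
            reconstruct_fes(log, [("x", -1.0, 1.0, 21)])

    def test_default_axes_pad_the_hills(self):
        log = _log_1d([(0.0, 0.1, 0.1), (1.0, 0.1, 0.1)])
        (name, lo, hi, n), = default_axes(log, resolution=0.02)
        assert name == "x"
        assert lo == pytest.approx(-0.3)
        assert hi == pytest.approx(1.3)
        assert n >= 80


class TestSliceFes:
    @staticmethod
    def _separable_grid():
        x = np.linspace(-1, 1, 21)
        f = x**2
        g = np.abs(np.linspace(-1, 1, 19))
        h = np.cos(np.linspace(0, 3, 17))
        vals = f[:, None, None] + g[None, :, None] + h[None, None, :]
        vals -= vals.min()
        axes = [("x", -1.0, 1.0, 21), ("y", -1.0, 1.0, 19), ("z", 0.0, 3.0, 17)]
        return FESGrid(axes, vals), f, g, h

    def test_separable_slice_shape(self):
        grid, f, g, h = self._separable_grid()
        sl, offset = slice_fes_2d(grid, "z", 1.5)
        expected = f[:, None] + g[None, :]
        expected -= expected.min()
        assert np.allclose(sl.values, expected, atol=1e-12)
        assert offset >= 0

    def test_unknown_axis_lists_known(self):
        grid, *_ = self._separable_grid()
        with pytest.raises(ValueError, match="known axes"):
            slice_fes_2d(grid, "w", 0.0)

    def test_requires_3d(self):
        grid = FESGrid([("x", 0, 1, 5), ("y", 0, 1, 5)], np.zeros((5, 5)))
        with pytest.raises(ValueError):
            slice_fes_2d(grid, "x", 0.5)


class TestFindBasins:
    def test_double_well_grid_has_two_basins(self):
        x = np.linspace(-1.5, 1.5, 151)
        vals = 5.0 * ((x / 1.0) ** 2 - 1) ** 2
        grid = FESGrid([("x", -1.5, 1.5, 151)], vals - vals.min())
        basins = find_basins(grid)
        assert len(basins) == 2
        xs = sorted(grid.node_coords(b[0])[0] for b in basins)
        assert xs[0] == pytest.approx(-1.0, abs=0.02)
        assert xs[1] == pytest.approx(1.0, abs=0.02)

    def test_flat_surface_warns_and_returns_empty(self):
        grid = FESGrid([("x", 0.0, 1.0, 11)], np.zeros(11))
        with pytest.warns(UserWarning, match="flat"):
            assert find_basins(grid) == []

    def test_single_hill_reconstruction_minima_on_normalization_set(self):
        log = _log_1d([(0.0, 0.1, 0.1)])
        grid = reconstruct_fes(log, [("x", -1.0, 1.0, 201)])
        basins = find_basins(grid)
        assert len(basins) == 1
        assert basins[0][1] == 0.0

    def test_mechanism_surface_basins_near_known_features(self):
        surf = make_mechanism_surface(6.0, 21.6, 0.0)
        axes = [(n, lo, hi, 47) for n, (lo, hi)
                in zip(surf.cv_names, surf.domain_box)]
        pts = np.stack(np.meshgrid(
            *[np.linspace(lo, hi, n) for _, lo, hi, n in axes],
            indexing="ij"), axis=-1)
        vals = surf.energy(pts)
        grid = FESGrid(axes, vals - vals.min())
        basins = find_basins(grid)
        step = (axes[0][2] - axes[0][1]) / (axes[0][3] - 1)
        for label in ("reactant", "product"):
            target, _ = surf.feature(label)
            hit = min(np.linalg.norm(grid.node_coords(b[0]) - target)
                      for b in basins)
            assert hit <= step * np.sqrt(3) + 1e-9, label


class TestMinimaxPath:
    def test_3x3_descending_example(self):
        vals = np.array([[0.0, 9.0, 0.0], [1.0, 9.0, 1.0], [2.0, 3.0, 2.0]])
        grid = FESGrid([("a", 0, 2, 3), ("b", 0, 2, 3)], vals)
        res = minimax_path(grid, (0, 0), (0, 2))
        assert res.barrier == pytest.approx(3.0)
        assert res.free_energies.max() == pytest.approx(3.0)
        # oracle: exhaustive over thresholds
        assert bruteforce_bottleneck(vals, (0, 0), (0, 2)) == 3.0

    def test_symmetric_surface_forward_equals_reverse(self):
        x = np.linspace(-1.5, 1.5, 151)
        vals = 5.0 * (x**2 - 1) ** 2
        grid = FESGrid([("x", -1.5, 1.5, 151)], vals - vals.min())
        r, p = grid.nearest_node([-1.0]), grid.nearest_node([1.0])
        fwd = minimax_path(grid, r, p)
        rev = minimax_path(grid, p, r)
        assert fwd.barrier == pytest.approx(rev.barrier, abs=1e-12)

    def test_barrier_invariant_to_constant_offset(self, rng):
        vals = rng.uniform(0, 5, size=(6, 6))
        vals -= vals.min()
        a = FESGrid([("a", 0, 5, 6), ("b", 0, 5, 6)], vals)
        res_a = minimax_path(a, (0, 0), (5, 5))
        # PathResult.barrier is referenced to the reactant-basin minimum,
        # so adding a constant before normalization changes nothing
        b = FESGrid([("a", 0, 5, 6), ("b", 0, 5, 6)], (vals + 3.7) - 3.7)
        res_b = minimax_path(b, (0, 0), (5, 5))
        assert res_a.barrier == pytest.approx(res_b.barrier)

    def test_nan_blocked_region_raises(self):
        vals = np.zeros((5, 5))
        vals[:, 2] = np.nan
        grid = FESGrid([("a", 0, 4, 5), ("b", 0, 4, 5)], vals)
        with pytest.raises(ValueError, match="blocked|NaN"):
            minimax_path(grid, (0, 0), (0, 4))

    def test_random_grids_match_bruteforce(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            vals = rng.uniform(0, 10, size=(6, 6))
            vals -= vals.min()
            grid = FESGrid([("a", 0, 5, 6), ("b", 0, 5, 6)], vals)
            res = minimax_path(grid, (0, 0), (5, 5))
            want = bruteforce_bottleneck(vals, (0, 0), (5, 5))
            assert res.free_energies.max() == pytest.approx(want, abs=0)


class TestMechanismOrder:
    @staticmethod
    def _exact_grid(surf, n=47):
        axes = [(name, lo, hi, n) for name, (lo, hi)
                in zip(surf.cv_names, surf.domain_box)]
        pts = np.stack(np.meshgrid(
            *[np.linspace(lo, hi, nn) for _, lo, hi, nn in axes],
            indexing="ij"), axis=-1)
        vals = surf.energy(pts)
        return FESGrid(axes, vals - vals.min())

    def test_deprotonation_precedes_concerted_transfer(self, mechanism_surface):
        grid = self._exact_grid(mechanism_surface)
        r = grid.nearest_node(mechanism_surface.feature("reactant")[0])
        p = grid.nearest_node(mechanism_surface.feature("product")[0])
        path = minimax_path(grid, r, p)
        rep = mechanism_order(grid, path)
        assert rep.progress["Nucleophile Deprotonation"] >= 0.9
        assert 0.2 < rep.progress["Phosphoryl Transfer"] < 0.8
        assert 0.2 < rep.progress["Leaving Group Protonation"] < 0.8
        assert rep.ordering.startswith("Nucleophile Deprotonation")
        assert rep.tightness == "tight"

    def test_ts_plane_slice_contains_the_path_ts(self, mechanism_surface):
        grid = self._exact_grid(mechanism_surface)
        r = grid.nearest_node(mechanism_surface.feature("reactant")[0])
        p = grid.nearest_node(mechanism_surface.feature("product")[0])
        path = minimax_path(grid, r, p)
        ts_node = path.nodes[path.ts_index]
        ts_coords = grid.node_coords(ts_node)
        k = grid.cv_names.index("Phosphoryl Transfer")
        sl, offset = slice_fes_2d(grid, "Phosphoryl Transfer", ts_coords[k])
        # the slice is the plane through the TS's transfer coordinate, so
        # the TS projects onto it at its remaining two indices
        reduced = tuple(i for j, i in enumerate(ts_node) if j != k)
        assert sl.values[reduced] + offset == pytest.approx(
            grid.values[ts_node], abs=1e-12)

    def test_ts_at_product_node_gives_full_progress(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        grid = FESGrid([("x", 0.0, 4.0, 5)], vals)
        path = minimax_path(grid, (0,), (4,))
        rep = mechanism_order(grid, path)
        assert rep.progress["x"] == pytest.approx(1.0)

    def test_1d_surface_single_cv_report(self):
        x = np.linspace(-1.2, 1.2, 121)
        vals = 5.0 * (x**2 - 1) ** 2
        grid = FESGrid([("x", -1.2, 1.2, 121)], vals - vals.min())
        path = minimax_path(grid, grid.nearest_node([-1.0]),
                            grid.nearest_node([1.0]))
        rep = mechanism_order(grid, path)
        assert set(rep.progress) == {"x"}
        assert rep.tightness == "indeterminate"

    def test_zero_displacement_cv_reported_not_failed(self):
        vals = np.zeros((5, 5))
        vals[2, :] = 1.0
        grid = FESGrid([("a", 0, 4, 5), ("b", 0, 4, 5)], vals)
        path = minimax_path(grid, (0, 2), (4, 2))
        rep = mechanism_order(grid, path)
        assert np.isnan(rep.progress["b"])


class TestConvergenceCheck:
    def test_identical_halves_give_zero(self):
        entries = [(0.1 * i, 0.1, 0.1) for i in range(10)]
        log = HillsLog(["x"])
        for i, (c, w, h) in enumerate(entries + entries):
            log.append(Hill(float(i), np.array([c]), np.array([w]), h))
        axes = [("x", -1.0, 2.0, 61)]
        assert convergence_check(log, axes, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_ten_hill_boundary_is_allowed(self):
        log = _log_1d([(0.05 * i, 0.1, 0.1) for i in range(10)])
        out = convergence_check(log, [("x", -1.0, 1.0, 41)], 0.5)
        assert np.isfinite(out)

    def test_too_few_hills_rejected(self):
        log = _log_1d([(0.0, 0.1, 0.1)] * 9)
        with pytest.raises(ValueError):
            convergence_check(log, [("x", -1.0, 1.0, 41)], 0.5)

    def test_bad_split_rejected(self):
        log = _log_1d([(0.0, 0.1, 0.1)] * 12)
        with pytest.raises(ValueError):
            convergence_check(log, [("x", -1.0, 1.0, 41)], 1.5)
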