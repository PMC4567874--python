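"""Landscape availability: line rasterisation, moving-window density,
masking, patches, distributions, ownership shares."""

import numpy as np
import pytest

from npmrocc import (
    GridConfig,
    Raster,
    mask_by_suitability,
    moving_window_density,
    ownership_shares,
    patch_statistics,
    rasterize_line_length,
    value_density_distribution,
)


GRID = GridConfig(origin=(0.0, 0.0), shape=(20, 20), cell_size=1.0,
                  window_radius=5.0)


def subsampling_oracle(lines, grid, pts_per_line=100_000):
    """Independent rasteriser: scatter many points along each line and
    bin their share of the line's length."""
    nrows, ncols = grid.shape
    out = np.zeros((nrows, ncols))
    for line in lines:
        coords = np.asarray(line, dtype=float)
        seg = np.diff(coords, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        total = seg_len.sum()
        if total == 0:
            continue
        cum = np.concatenate([[0], np.cumsum(seg_len)])
        s = (np.arange(pts_per_line) + 0.5) / pts_per_line * total
        idx = np.searchsorted(cum, s, side="right") - 1
        idx = np.clip(idx, 0, len(seg) - 1)
        frac = (s - cum[idx]) / seg_len[idx]
        pts = coords[idx] + frac[:, None] * seg[idx]
        c = ((pts[:, 0] - grid.origin[0]) // grid.cell_size).astype(int)
        r = ((pts[:, 1] - grid.origin[1]) // grid.cell_size).astype(int)
        ok = (r >= 0) & (r < nrows) & (c >= 0) & (c < ncols)
        np.add.at(out, (r[ok], c[ok]), total / pts_per_line)
    return out


def flood_fill_patch_count(mask):
    """Independent 8-neighbour connected-component counter (BFS)."""
    seen = np.zeros_like(mask, dtype=bool)
    nrows, ncols = mask.shape
    count = 0
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nrows and 0 <= cc < ncols and \
                                mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


class TestRasterizeLineLength:
    def test_segment_inside_one_cell(self):
        lines = [np.array([[2.2, 3.5], [3.2, 3.5]])]  # 1 km inside cell (3, 2..3)?
        out = rasterize_line_length(lines, GRID)
        # crosses x=3 boundary: 0.8 in cell (3,2), 0.2 in (3,3)
        assert out.values[3, 2] == pytest.approx(0.8)
        assert out.values[3, 3] == pytest.approx(0.2)
        lines = [np.array([[2.2, 3.5], [2.9, 3.5]])]
        out = rasterize_line_length(lines, GRID)
        assert out.values[3, 2] == pytest.approx(0.7)
        assert out.values.sum() == pytest.approx(0.7)

    def test_midpoint_crossing_split_evenly(self):
        lines = [np.array([[4.5, 0.5], [5.5, 0.5]])]
        out = rasterize_line_length(lines, GRID)
        assert out.values[0, 4] == pytest.approx(0.5)
        assert out.values[0, 5] == pytest.approx(0.5)

    def test_total_length_conserved(self, rng):
        lines = [rng.uniform(1, 19, size=(int(rng.integers(2, 6)), 2))
                 for _ in range(20)]
        total = sum(np.hypot(*np.diff(l, axis=0).T).sum() for l in lines)
        out = rasterize_line_length(lines, GRID)
        assert out.values.sum() == pytest.approx(total, rel=1e-9)

    def test_matches_subsampling_oracle(self, rng):
        lines = [rng.uniform(0.5, 19.5, size=(3, 2)) for _ in range(20)]
        exact = rasterize_line_length(lines, GRID).values
        approx = subsampling_oracle(lines, GRID)
        assert np.abs(exact - approx).max() < 1e-3

    def test_translation_invariance(self, rng):
        lines = [rng.uniform(2, 18, size=(4, 2)) for _ in range(5)]
        out1 = rasterize_line_length(lines, GRID)
        shift = np.array([100.0, -40.0])
        grid2 = GridConfig(origin=(shift[0], shift[1]), shape=GRID.shape,
                           cell_size=1.0, window_radius=5.0)
        out2 = rasterize_line_length([l + shift for l in lines], grid2)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-9)


class TestMovingWindowDensity:
    def test_uniform_field_limit(self):
        d = 0.7  # km of line per km^2, uniformly, at the working resolution
        grid = GridConfig(shape=(160, 160), cell_size=0.27, window_radius=5.0)
        lengths = Raster(grid, np.full(grid.shape, d * grid.cell_area))
        dens = moving_window_density(lengths)
        k = int(np.ceil(5.0 / 0.27)) + 1
        interior = dens.values[k:-k, k:-k]
        assert np.allclose(interior, d, rtol=0.02)

    def test_empty_raster_stays_zero(self):
        dens = moving_window_density(Raster(GRID, np.zeros(GRID.shape)))
        assert (dens.values == 0).all()

    def test_point_source_closed_form(self):
        grid = GridConfig(shape=(41, 41), cell_size=1.0, window_radius=5.0)
        L = 3.0
        lengths = np.zeros((41, 41))
        lengths[20, 20] = L
        dens = moving_window_density(Raster(grid, lengths))
        assert dens.values[20, 20] == pytest.approx(L / (np.pi * 25.0))

    def test_masking_never_increases_density(self, rng):
        vals = rng.uniform(0, 1, size=GRID.shape)
        dens = moving_window_density(Raster(GRID, vals))
        suit = Raster(GRID, rng.uniform(0, 1, size=GRID.shape))
        masked = mask_by_suitability(dens, suit, threshold=0.5)
        ok = np.isfinite(masked.values)
        assert (masked.values[ok] == dens.values[ok]).all()


class TestMaskBySuitability:
    def test_zero_threshold_is_identity(self, rng):
        dens = Raster(GRID, rng.uniform(0, 2, size=GRID.shape))
        suit = Raster(GRID, rng.uniform(0, 1, size=GRID.shape))
        out = mask_by_suitability(dens, suit, threshold=0.0)
        np.testing.assert_array_equal(out.values, dens.values)

    def test_impossible_threshold_masks_everything(self, rng):
        dens = Raster(GRID, rng.uniform(0, 2, size=GRID.shape))
        suit = Raster(GRID, rng.uniform(0, 1, size=GRID.shape))
        assert np.isnan(mask_by_suitability(dens, suit, 1.01).values).all()

    def test_checkerboard_masks_exactly_half(self):
        suit = np.indices(GRID.shape).sum(axis=0) % 2 * 0.8 + 0.1
        out = mask_by_suitability(Raster(GRID, np.ones(GRID.shape)),
                                  Raster(GRID, suit), threshold=0.20)
        assert np.isnan(out.values).sum() == out.values.size // 2

    def test_misaligned_grids_rejected(self):
        other = GridConfig(shape=(10, 10), cell_size=1.0, window_radius=5.0)
        with pytest.raises(ValueError):
            mask_by_suitability(Raster(GRID, np.ones(GRID.shape)),
                                Raster(other, np.ones((10, 10))))


class TestPatchStatistics:
    def test_solid_block_single_patch(self):
        vals = np.full(GRID.shape, np.nan)
        vals[5:15, 5:15] = 1.0
        pt = patch_statistics(Raster(GRID, vals))
        assert pt.n_patches == 1
        assert pt.patches["area_ha"].iloc[0] == pytest.approx(100 * 100.0)

    def test_diagonal_touch_merges_under_8_adjacency(self):
        vals = np.full(GRID.shape, np.nan)
        vals[2:4, 2:4] = 1.0
        vals[4:6, 4:6] = 1.0  # touches only at the corner (3,3)-(4,4)
        assert patch_statistics(Raster(GRID, vals)).n_patches == 1

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            mask = rng.uniform(size=(25, 25)) < 0.35
            vals = np.where(mask, 1.0, np.nan)
            grid = GridConfig(shape=(25, 25), cell_size=1.0, window_radius=5.0)
            got = patch_statistics(Raster(grid, vals)).n_patches
            assert got == flood_fill_patch_count(mask)

    def test_occupancy_flag_and_monotone_shares(self, rng):
        vals = np.where(rng.uniform(size=GRID.shape) < 0.4, 1.0, np.nan)
        obs = rng.uniform(0, 20, size=(15, 2))
        pt = patch_statistics(Raster(GRID, vals), observations=obs,
                              top_k=(1, 5, 14))
        assert 0 <= pt.n_occupied <= pt.n_patches
        s = pt.top_shares
        assert s[1] <= s[5] <= s[14] <= 1.0 + 1e-12


class TestValueDensityDistribution:
    def test_degenerate_spike_flagged(self):
        curve = value_density_distribution(np.full(50, 2.5))
        assert curve.degenerate
        assert curve.mean == 2.5 and curve.se == 0.0

    def test_standard_normal_density_at_zero(self, rng):
        vals = rng.normal(size=10_000)
        curve = value_density_distribution(vals)
        at0 = np.interp(0.0, curve.x, curve.density)
        assert at0 == pytest.approx(0.3989, rel=0.05)

    def test_curve_integrates_to_one(self, rng):
        vals = rng.lognormal(0, 0.5, size=400)
        curve = value_density_distribution(vals)
        assert np.trapezoid(curve.density, curve.x) == pytest.approx(1.0,
                                                                     abs=1e-3)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            value_density_distribution(np.array([1.0]))

    def test_use_points_in_empty_cells_sit_below_availability_mean(self, rng):
        vals = rng.uniform(0.5, 2.0, size=GRID.shape)
        vals[0:5, 0:5] = 0.0
        raster = Raster(GRID, vals)
        pts = rng.uniform(0, 5, size=(30, 2))  # only in the zero block
        avail = value_density_distribution(raster)
        use = value_density_distribution(raster, points=pts)
        assert use.mean < avail.mean


class TestOwnershipShares:
    def test_single_owner(self):
        mask = Raster(GRID, np.ones(GRID.shape))
        owner = Raster(GRID, np.zeros(GRID.shape))
        assert ownership_shares(mask, owner) == {0: 1.0}

    def test_constructed_split(self):
        mask = Raster(GRID, np.ones(GRID.shape))
        vals = np.zeros(GRID.shape)
        vals[:12, :] = 1.0  # 12 of 20 rows -> 60%
        shares = ownership_shares(mask, Raster(GRID, vals))
        assert shares[1] == pytest.approx(0.6)
        assert shares[0] == pytest.approx(0.4)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_counting(self, rng):
        mvals = np.where(rng.uniform(size=GRID.shape) < 0.5, 1.0, np.nan)
        ovals = rng.integers(0, 3, size=GRID.shape).astype(float)
        shares = ownership_shares(Raster(GRID, mvals), Raster(GRID, ovals))
        avail = np.isfinite(mvals)
        for k in range(3):
            want = ((ovals == k) & avail).sum() / avail.sum()
            assert shares.get(k, 0.0) == pytest.approx(want)
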