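"""Unit and property tests for box counting, window selection and FD fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracdem.fractal import (
    EmptyMaskError,
    FDResult,
    ScaleSeries,
    ScalingWindow,
    VoxelMask,
    box_count_curve,
    compute_fd,
    count_boxes,
    default_scales,
    fit_fd,
    hemispheric_average,
    load_mask,
    save_mask,
    select_scaling_window,
)
from fracdem.phantoms import PhantomSpec, make_phantom


def oracle_count(coords, s, offset):
    """Independent brute-force oracle: hash per-voxel cell indices."""
    cells = set()
    for v in coords:
        cells.add(tuple(math.floor((v[k] - offset[k]) / s) for k in range(3)))
    return len(cells)


def oracle_window(scales, counts, decimals=2):
    """Independent exhaustive window-selection oracle using scipy."""
    from scipy.stats import linregress

    log_s, log_n = np.log(scales), np.log(counts)
    best = None
    n = len(scales)
    for i in range(n):
        for j in range(i + 2, n):
            x, y = log_s[i : j + 1], log_n[i : j + 1]
            if np.ptp(y) == 0:
                r2 = 1.0
            else:
                r2 = linregress(x, y).rvalue ** 2
            k = j - i + 1
            adj = 1 - (1 - r2) * (k - 1) / (k - 2)
            cand = (round(adj, decimals), k, -i)
            if best is None or cand > best[0]:
                best = (cand, (i, j))
    return best[1]


def solid_cube(n=8):
    return VoxelMask(np.ones((n, n, n), dtype=bool))


class TestCountBoxes:
    def test_aligned_cube(self):
        assert count_boxes(solid_cube(8), 2, (0, 0, 0)) == 64

    def test_single_box_encloses_all(self):
        assert count_boxes(solid_cube(8), 8, (0, 0, 0)) == 1

    def test_offset_cube_derived(self):
        # brute-force enumeration gives 5 x 4 x 4 occupied cells
        mask = solid_cube(8)
        assert count_boxes(mask, 2, (1, 0, 0)) == 80
        assert oracle_count(mask.coordinates(), 2, (1, 0, 0)) == 80

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            count_boxes(VoxelMask(np.zeros((4, 4, 4), dtype=bool)), 2, (0, 0, 0))

    def test_small_scale_raises(self):
        with pytest.raises(ValueError):
            count_boxes(solid_cube(8), 0.5, (0, 0, 0))

    def test_zero_offset_matches_oracle_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            occ = rng.random((16, 16, 16)) < rng.uniform(0.02, 0.5)
            if not occ.any():
                occ[0, 0, 0] = True
            mask = VoxelMask(occ)
            coords = mask.coordinates()
            for s in (1, 2, 4, 8):
                assert count_boxes(mask, s, (0, 0, 0)) == oracle_count(coords, s, (0, 0, 0))

    @given(seed=st.integers(0, 10_000), s=st.sampled_from([1, 2, 3, 4, 8]))
    @settings(max_examples=25, deadline=None)
    def test_random_offsets_match_oracle(self, seed, s):
        rng = np.random.default_rng(seed)
        occ = rng.random((12, 12, 12)) < 0.2
        occ[0, 0, 0] = True
        mask = VoxelMask(occ)
        off = rng.uniform(0, s, size=3)
        assert count_boxes(mask, s, off) == oracle_count(mask.coordinates(), s, off)

    def test_nested_grids_non_increasing(self):
        rng = np.random.default_rng(3)
        for _ in range(10)[:10]:
            occ = rng.random((32, 32, 32)) < 0.1
            occ[0, 0, 0] = True
            mask = VoxelMask(occ)
            counts = [count_boxes(mask, s, (0, 0, 0)) for s in (1, 2, 4, 8, 16)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBoxCountCurve:
    def test_single_voxel_always_one(self):
        occ = np.zeros((16, 16, 16), dtype=bool)
        occ[5, 7, 3] = True
        series = box_count_curve(VoxelMask(occ), [1, 2, 4], seed=0)
        assert np.all(series.counts == 1.0)

    @pytest.mark.parametrize("agg", ["min", "mean"])
    def test_cube_overhang_bound(self, agg):
        mask = solid_cube(64)
        scales = [1, 2, 4, 8, 16, 32]
        series = box_count_curve(mask, scales, n_offsets=20, seed=1, agg=agg)
        for s, n in zip(series.scales, series.counts):
            assert (64 / s) ** 3 <= n <= (64 / s + 1) ** 3

    def test_seed_determinism(self):
        mask = solid_cube(16)
        a = box_count_curve(mask, [1, 2, 4, 8], n_offsets=10, seed=42, agg="mean")
        b = box_count_curve(mask, [1, 2, 4, 8], n_offsets=10, seed=42, agg="mean")
        assert np.array_equal(a.counts, b.counts)

    def test_counts_bounded_by_foreground(self):
        rng = np.random.default_rng(11)
        occ = rng.random((16, 16, 16)) < 0.1
        occ[0, 0, 0] = True
        mask = VoxelMask(occ)
        series = box_count_curve(mask, [1, 2, 4], seed=0)
        assert np.all(series.counts >= 1)
        assert np.all(series.counts <= mask.n_foreground)

    def test_rejects_bad_agg(self):
        with pytest.raises(ValueError):
            box_count_curve(solid_cube(8), [1, 2, 4], agg="median")

    def test_too_few_scales(self):
        with pytest.raises(ValueError):
            box_count_curve(solid_cube(8), [1, 2])


class TestDefaultScales:
    def test_cube_64(self):
        assert default_scales(solid_cube(64)).tolist() == [1, 2, 4, 8, 16, 32]

    def test_cube_8(self):
        assert default_scales(solid_cube(8)).tolist() == [1, 2, 4]

    def test_too_small(self):
        with pytest.raises(ValueError, match="explicit scales"):
            default_scales(VoxelMask(np.ones((2, 2, 2), dtype=bool)))

    def test_menger_grid_uses_triadic_divisors(self):
        mask = make_phantom(PhantomSpec(kind="menger", iterations=4))
        assert default_scales(mask).tolist() == [1, 3, 9, 27]

    def test_prime_edge_falls_back_to_powers_of_two(self):
        occ = np.zeros((37, 8, 8), dtype=bool)
        occ[:37, :4, :4] = True
        assert default_scales(VoxelMask(occ)).tolist() == [1, 2, 4, 8, 16]


class TestSelectScalingWindow:
    def test_exact_power_law_full_window(self):
        scales = np.array([1, 2, 4, 8, 16, 32], dtype=float)
        series = ScaleSeries(scales, 1.0e6 * scales**-2.0, n_offsets=1, seed=0)
        window = select_scaling_window(series)
        assert (window.start_index, window.end_index) == (0, len(scales) - 1)
        assert window.radj2_rounded == 1.0

    def test_broken_power_law_confined(self):
        scales = np.array([1, 2, 4, 8, 16, 32, 64], dtype=float)
        counts = np.where(scales <= 8, 1e6 * scales**-3.0, 1e6 * 8.0**-3.0)
        series = ScaleSeries(scales, counts, n_offsets=1, seed=0)
        window = select_scaling_window(series)
        assert (window.start_index, window.end_index) == oracle_window(scales, counts)
        assert scales[window.end_index] <= 8  # confined to the power-law part

    def test_three_point_series(self):
        series = ScaleSeries([1, 2, 4], [100, 40, 10], n_offsets=1, seed=0)
        window = select_scaling_window(series)
        assert (window.start_index, window.end_index) == (0, 2)

    def test_matches_oracle_on_synthetic_curves(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(4, 9)
            scales = 2.0 ** np.arange(n)
            kind = rng.integers(3)
            if kind == 0:  # pure power law
                counts = 10.0**6 * scales ** -rng.uniform(0.5, 3)
            elif kind == 1:  # broken power law
                knee = scales[rng.integers(1, n - 1)]
                d1, d2 = rng.uniform(0.5, 3, size=2)
                counts = np.where(
                    scales <= knee,
                    1e6 * scales**-d1,
                    1e6 * knee ** (d2 - d1) * scales**-d2,
                )
            else:  # noisy power law
                counts = 1e6 * scales ** -rng.uniform(0.5, 3)
                counts *= np.exp(rng.normal(0, 0.1, size=n))
            series = ScaleSeries(scales, counts, n_offsets=1, seed=0)
            window = select_scaling_window(series)
            assert (window.start_index, window.end_index) == oracle_window(scales, counts)


class TestFitFD:
    def test_exact_slope(self):
        scales = np.array([1, 2, 4, 8], dtype=float)
        counts = 1.0e5 * scales**-2.5
        series = ScaleSeries(scales, counts, n_offsets=1, seed=0)
        result = fit_fd(series, select_scaling_window(series))
        assert result.fd == pytest.approx(2.5, abs=1e-12)

    def test_flat_series_fd_zero(self):
        series = ScaleSeries([1, 2, 4, 8], [1, 1, 1, 1], n_offsets=1, seed=0)
        result = fit_fd(series, select_scaling_window(series))
        assert result.fd == 0.0

    def test_zero_offset_cube_counts(self):
        scales = np.array([1, 2, 4, 8, 16, 32], dtype=float)
        counts = (64.0 / scales) ** 3  # exact aligned counts
        series = ScaleSeries(scales, counts, n_offsets=1, seed=0)
        result = fit_fd(series, select_scaling_window(series))
        assert result.fd == pytest.approx(3.0, abs=0.05)

    def test_window_must_fit(self):
        series = ScaleSeries([1, 2, 4], [10, 5, 2], n_offsets=1, seed=0)
        with pytest.raises(ValueError):
            fit_fd(series, ScalingWindow(0, 3, 1.0))


class TestComputeFD:
    def test_small_cube(self):
        result = compute_fd(solid_cube(32), seed=0)
        assert result.fd == pytest.approx(3.0, abs=0.05)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        occ = rng.random((24, 24, 24)) < 0.3
        occ[0, 0, 0] = occ[23, 23, 23] = True
        base = np.zeros((40, 40, 40), dtype=bool)
        base[:24, :24, :24] = occ
        shifted = np.zeros((40, 40, 40), dtype=bool)
        shifted[10 : 10 + 24, 5 : 5 + 24, 16 : 16 + 24] = occ
        fd0 = compute_fd(VoxelMask(base), seed=123).fd
        fd1 = compute_fd(VoxelMask(shifted), seed=123).fd
        assert fd1 == pytest.approx(fd0, abs=0.02)

    def test_dimension_ordering(self):
        fd_cube = compute_fd(make_phantom(PhantomSpec("cube", size=64)), seed=0).fd
        fd_slab = compute_fd(make_phantom(PhantomSpec("slab", size=64)), seed=0).fd
        fd_line = compute_fd(make_phantom(PhantomSpec("line", size=64)), seed=0).fd
        assert fd_cube >= fd_slab >= fd_line

    def test_fd_in_valid_range(self):
        rng = np.random.default_rng(21)
        occ = rng.random((16, 16, 16)) < 0.2
        occ[0, 0, 0] = True
        result = compute_fd(VoxelMask(occ), seed=0)
        assert 0.0 <= result.fd <= 3.0


class TestHemisphericAverage:
    def test_identical(self):
        assert hemispheric_average(2.34, 2.34) == 2.34

    def test_mean(self):
        assert hemispheric_average(2.30, 2.38) == pytest.approx(2.34)

    def test_extremes(self):
        assert hemispheric_average(0.0, 3.0) == 1.5

    def test_accepts_results(self):
        series = ScaleSeries([1, 2, 4], [64, 16, 4], n_offsets=1, seed=0)
        res = fit_fd(series, select_scaling_window(series))
        assert hemispheric_average(res, res) == pytest.approx(res.fd)


class TestNifti:
    def test_roundtrip(self, tmp_path):
        mask = make_phantom(PhantomSpec("menger", iterations=2))
        path = str(tmp_path / "sponge.nii.gz")
        save_mask(mask, path)
        loaded = load_mask(path)
        assert np.array_equal(loaded.occupancy, mask.occupancy)

    def test_anisotropic_rejected(self, tmp_path):
        import nibabel as nib

        data = np.ones((8, 8, 8), dtype=np.uint8)
        img = nib.Nifti1Image(data, np.diag([1.0, 1.0, 1.5, 1.0]))
        path = str(tmp_path / "aniso.nii.gz")
        nib.save(img, path)
        with pytest.raises(ValueError, match="anisotropic"):
            load_mask(path)
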