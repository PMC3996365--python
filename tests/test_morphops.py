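import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from hepaq3d.core import BinaryMask, IntensityVolume, KernelSpec
from hepaq3d.morphops import (
    CavityFillParams,
    ThresholdSpec,
    VotingParams,
    apply_threshold,
    cavity_fill,
    drop_small_objects,
    open_close,
    otsu_adaptive,
    otsu_global,
    vote_fill,
)


def otsu_scan_oracle(data):
    """Exhaustive 0-255 between-class variance scan (classes [<t] / [>=t]).

    The variance is flat over empty histogram gaps; ties resolve to the
    middle of the maximizing plateau.
    """
    vals = data.ravel().astype(float)
    scores = np.full(256, -1.0)
    for t in range(1, 256):
        lo, hi = vals[vals < t], vals[vals >= t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        scores[t] = w0 * w1 * (lo.mean() - hi.mean()) ** 2
    best = scores.max()
    ties = np.nonzero(scores >= best - 1e-12 * max(best, 1.0))[0]
    return int(round(ties.mean()))


class TestOtsu:
    def test_bimodal_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        data = np.clip(
            np.concatenate(
                [rng.normal(40, 5, 4000), rng.normal(200, 5, 4000)]
            ).round(),
            0,
            255,
        ).astype(np.uint8)
        data = data.reshape(20, 20, 20)
        t = otsu_global(data)
        assert t == otsu_scan_oracle(data)
        assert 60 < t < 180

    def test_two_value_volume_separates_exactly(self):
        data = np.zeros((4, 4, 4), dtype=np.uint8)
        data[2:] = 255
        t = otsu_global(data)
        assert 0 < t <= 255
        assert np.array_equal(data >= t, data == 255)

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_global(np.full((4, 4, 4), 9, dtype=np.uint8))


class TestOtsuAdaptive:
    def test_whole_volume_region_reduces_to_global(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 256, (16, 24, 24), dtype=np.uint8)
        vol = IntensityVolume(data)
        spec = ThresholdSpec("adaptive_otsu", region_size=(24, 24, 16), n_samples=1)
        field = otsu_adaptive(vol, spec)
        assert np.all(field == otsu_global(data))

    def test_left_right_halves_get_local_thresholds(self):
        rng = np.random.default_rng(2)
        left = np.clip(
            np.where(
                rng.uniform(size=(16, 32, 32)) < 0.5,
                rng.normal(30, 4, (16, 32, 32)),
                rng.normal(90, 4, (16, 32, 32)),
            ).round(),
            0,
            255,
        )
        right = np.clip(
            np.where(
                rng.uniform(size=(16, 32, 32)) < 0.5,
                rng.normal(140, 4, (16, 32, 32)),
                rng.normal(230, 4, (16, 32, 32)),
            ).round(),
            0,
            255,
        )
        data = np.concatenate([left, right], axis=2).astype(np.uint8)
        vol = IntensityVolume(data)
        spec = ThresholdSpec("adaptive_otsu", region_size=(30, 32, 16), n_samples=2)
        field = otsu_adaptive(vol, spec)
        t_left = field[8, 16, 4]
        t_right = field[8, 16, 60]
        assert 34 < t_left < 86  # within the left half's mode gap
        assert 144 < t_right < 226
        # each side agrees with that half's own global Otsu to interpolation slack
        assert abs(t_left - otsu_global(data[:, :, :32])) < 10
        assert abs(t_right - otsu_global(data[:, :, 32:])) < 10

    def test_same_seed_same_field(self):
        rng = np.random.default_rng(3)
        vol = IntensityVolume(rng.integers(0, 256, (12, 20, 20), dtype=np.uint8))
        spec = ThresholdSpec("adaptive_otsu", region_size=(10, 10, 6), n_samples=4, seed=11)
        assert np.array_equal(otsu_adaptive(vol, spec), otsu_adaptive(vol, spec))

    def test_oversized_region_rejected(self):
        vol = IntensityVolume(np.zeros((4, 8, 8), dtype=np.uint8))
        spec = ThresholdSpec("adaptive_otsu", region_size=(9, 8, 4), n_samples=1)
        with pytest.raises(ValueError, match="larger"):
            otsu_adaptive(vol, spec)

    def test_manual_threshold_application(self):
        data = np.arange(64, dtype=np.uint8).reshape(4, 4, 4)
        mask = apply_threshold(IntensityVolume(data), ThresholdSpec("manual", 32))
        assert np.array_equal(mask.data, data >= 32)


class TestVoteFill:
    def test_isolated_salt_voxel_removed(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[3, 3, 3] = True
        out = vote_fill(BinaryMask(m), VotingParams((1, 1, 1), 0), inverse=True)
        assert not out.data.any()

    def test_cube_interior_survives_inverse(self):
        m = np.zeros((14, 14, 14), dtype=bool)
        m[2:12, 2:12, 2:12] = True
        for majority in (2, 5, 10):
            out = vote_fill(BinaryMask(m), VotingParams((1, 1, 1), majority), inverse=True)
            assert out.data[3:11, 3:11, 3:11].all()

    def test_interior_neighbour_counts_match_oracle(self):
        # the voting rule uses exact neighbour counts: cross-check via convolve
        rng = np.random.default_rng(4)
        m = rng.uniform(size=(9, 9, 9)) > 0.5
        out = vote_fill(BinaryMask(m), VotingParams((1, 1, 1), 3), inverse=True)
        kernel = np.ones((3, 3, 3))
        counts = ndimage.convolve(m.astype(int), kernel, mode="constant") - m
        expected = m & ~((26 - counts) >= 13 + 3)
        assert np.array_equal(out.data, expected)

    def test_pepper_hole_filled_direct(self):
        m = np.ones((7, 7, 7), dtype=bool)
        m[3, 3, 3] = False
        out = vote_fill(BinaryMask(m), VotingParams((1, 1, 1), 0))
        assert out.data.all()

    def test_direct_never_removes_inverse_never_adds(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(size=(8, 8, 8)) > 0.4
        direct = vote_fill(BinaryMask(m), VotingParams((1, 1, 1), 1))
        inverse = vote_fill(BinaryMask(m), VotingParams((1, 1, 1), 1), inverse=True)
        assert (direct.data | m).sum() == direct.data.sum()  # superset
        assert (inverse.data & m).sum() == inverse.data.sum()  # subset

    def test_majority_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0-10|0..10"):
            VotingParams((1, 1, 1), 11)

    def test_large_radius_needs_force(self):
        m = BinaryMask(np.zeros((9, 9, 9), dtype=bool))
        with pytest.raises(ValueError, match="exceed 3"):
            vote_fill(m, VotingParams((4, 4, 1), 2))
        vote_fill(m, VotingParams((4, 4, 1), 2), force=True)  # no raise


class TestCavityFill:
    def test_enclosed_core_fills_at_high_fraction(self):
        zz, yy, xx = np.mgrid[:40, :40, :40]
        d = np.sqrt((xx - 20) ** 2 + (yy - 20) ** 2 + (zz - 20) ** 2)
        shell = (d >= 6) & (d <= 9)
        out = cavity_fill(BinaryMask(shell), CavityFillParams((7, 7, 7), 0.9))
        assert out.data[d < 6].all()
        assert not out.data[d > 9.5].any()

    def test_precise_variant_fills_with_adequate_radius(self):
        zz, yy, xx = np.mgrid[:40, :40, :40]
        d = np.sqrt((xx - 20) ** 2 + (yy - 20) ** 2 + (zz - 20) ** 2)
        shell = (d >= 6) & (d <= 9)
        out = cavity_fill(
            BinaryMask(shell), CavityFillParams((9, 9, 9), 0.9, accelerated=False)
        )
        assert out.data[d < 6].all()
        assert not out.data[d > 9.5].any()

    def test_open_hole_needs_lower_fraction(self):
        zz, yy, xx = np.mgrid[:40, :40, :40]
        d = np.sqrt((xx - 20) ** 2 + (yy - 20) ** 2 + (zz - 20) ** 2)
        shell = (d >= 6) & (d <= 9) & (zz <= 22)  # top cut away
        core = d < 6
        high = cavity_fill(BinaryMask(shell), CavityFillParams((7, 7, 7), 0.9))
        low = cavity_fill(BinaryMask(shell), CavityFillParams((7, 7, 7), 0.6))
        assert high.data[core].sum() < 0.3 * core.sum()
        assert low.data[core].sum() > 0.6 * core.sum()

    def test_empty_mask_unchanged(self):
        out = cavity_fill(BinaryMask(np.zeros((6, 6, 6), bool)), CavityFillParams((2, 2, 2), 0.5))
        assert not out.data.any()

    def test_fraction_one_only_fully_surrounded(self):
        solid = np.ones((9, 9, 9), dtype=bool)
        solid[4, 4, 4] = False  # fully surrounded pepper hole
        solid[0, 4, 4] = False  # face voxel: open towards the border
        out = cavity_fill(BinaryMask(solid), CavityFillParams((2, 2, 2), 1.0))
        assert out.data[4, 4, 4]
        assert not out.data[0, 4, 4]

    def test_never_removes_foreground(self):
        rng = np.random.default_rng(6)
        m = rng.uniform(size=(10, 10, 10)) > 0.5
        out = cavity_fill(BinaryMask(m), CavityFillParams((2, 2, 2), 0.7))
        assert (out.data & m).sum() == m.sum()


class TestOpenClose:
    def test_radius_zero_identity(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(size=(8, 8, 8)) > 0.5
        out = open_close(BinaryMask(m), KernelSpec((0, 0, 0)), "open")
        assert np.array_equal(out.data, m)

    def test_thin_rod_removed_by_opening(self):
        m = np.zeros((20, 20, 20), dtype=bool)
        m[9:12, 9:12, 2:18] = True  # 3-voxel-thick rod along x
        out = open_close(BinaryMask(m, (1, 1, 1)), KernelSpec((2, 2, 2)), "open")
        # erosion-dilation oracle: erosion by a radius-2 ball empties the rod
        ero = ndimage.binary_erosion(m, KernelSpec((2, 2, 2)).footprint(), border_value=1)
        assert not ero.any()
        assert not out.data.any()

    def test_closing_idempotent(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(size=(12, 12, 12)) > 0.6
        once = open_close(BinaryMask(m), KernelSpec((1, 1, 1)), "close")
        twice = open_close(once, KernelSpec((1, 1, 1)), "close")
        assert np.array_equal(once.data, twice.data)

    def test_erode_dilate_composition(self):
        rng = np.random.default_rng(9)
        m = BinaryMask(rng.uniform(size=(10, 10, 10)) > 0.5)
        k = KernelSpec((1, 1, 1))
        opened = open_close(m, k, "open")
        manual = open_close(open_close(m, k, "erode"), k, "dilate")
        assert np.array_equal(opened.data, manual.data)


class TestDropSmall:
    def test_small_component_removed(self):
        m = np.zeros((20, 20, 20), dtype=bool)
        m[1:11, 1:11, 1:11] = True  # 1000 voxels
        m[15:16, 15:16, 15:26 - 16] = True  # 10 voxels
        out = drop_small_objects(BinaryMask(m), 100)
        assert out.data.sum() == 1000

    def test_threshold_zero_identity(self):
        rng = np.random.default_rng(10)
        m = rng.uniform(size=(8, 8, 8)) > 0.7
        out = drop_small_objects(BinaryMask(m), 0)
        assert np.array_equal(out.data, m)

    def test_component_count_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(size=(15, 15, 15)) > 0.7
        thr = 5
        out = drop_small_objects(BinaryMask(m), thr)
        labels, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
        expect = sum(
            1 for i in range(1, n + 1) if (labels == i).sum() >= thr
        )
        _, n_out = ndimage.label(out.data, structure=np.ones((3, 3, 3)))
        assert n_out == expect

    def test_um3_units_use_spacing(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[2:4, 2:4, 2:4] = True  # 8 voxels
        mask = BinaryMask(m, (0.5, 0.5, 1.0))  # voxel volume 0.25 um^3 -> 2 um^3
        assert drop_small_objects(mask, 1.9, "um3").data.sum() == 8
        assert drop_small_objects(mask, 2.1, "um3").data.sum() == 0


@settings(max_examples=30, deadline=None)
@given(
    arrays(bool, (6, 6, 6), elements=st.booleans()),
    st.integers(0, 10),
)
def test_vote_fill_monotone_contracts(m, majority):
    """Inverse voting only removes, direct voting only adds, any majority."""
    mask = BinaryMask(m)
    p = VotingParams((1, 1, 1), majority)
    assert not (vote_fill(mask, p, inverse=True).data & ~m).any()
    assert not (~vote_fill(mask, p, inverse=False).data & m).any()


@settings(max_examples=20, deadline=None)
@given(arrays(bool, (6, 6, 6), elements=st.booleans()))
def test_cavity_and_drop_contracts(m):
    """Cavity filling never removes; object dropping never adds."""
    mask = BinaryMask(m)
    filled = cavity_fill(mask, CavityFillParams((2, 2, 2), 0.6))
    assert not (~filled.data & m).any()
    dropped = drop_small_objects(mask, 3)
    assert not (dropped.data & ~m).any()
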