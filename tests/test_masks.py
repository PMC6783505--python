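"""Morphology: structuring elements, dilate/erode vs brute-force oracles,
the safe-WM mask composition, and WMH penumbra expansion."""

import numpy as np
import pytest

from fwsafe.io_core import BinaryMask, ImageGrid
from fwsafe.masks import (
    TissueMaps,
    build_wm_safe,
    dilate,
    erode,
    expand_wmh,
    make_ball,
    subtract,
)


from morph_oracles import oracle_dilate, oracle_erode


def _mask(values):
    return BinaryMask(ImageGrid.isotropic(values.shape), np.asarray(values, bool))


class TestMakeBall:
    @pytest.mark.parametrize("radius,count", [(0, 1), (1, 7), (2, 33)])
    def test_euclidean_ball_cardinality(self, radius, count):
        # counts verified by brute enumeration of ||v||_2 <= r on the
        # (2r+1)^3 cube
        se = make_ball(radius)
        assert len(se) == count

    def test_matches_enumeration(self):
        se = make_ball(2)
        expect = {(x, y, z)
                  for x in range(-2, 3) for y in range(-2, 3)
                  for z in range(-2, 3) if x * x + y * y + z * z <= 4}
        assert set(se.offsets) == expect

    def test_cube_variant(self):
        assert len(make_ball(1, "cube")) == 27

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            make_ball(-1)


class TestDilateErode:
    def test_single_voxel_dilation(self):
        v = np.zeros((5, 5, 5), bool)
        v[2, 2, 2] = True
        out = dilate(_mask(v), make_ball(1))
        assert out.n_true == 7

    def test_empty_mask_stays_empty(self):
        v = np.zeros((5, 5, 5), bool)
        assert dilate(_mask(v), make_ball(2)).n_true == 0
        assert erode(_mask(v), make_ball(2)).n_true == 0

    def test_full_cube_erosion_border_rule(self):
        # outside-grid counts as background, so a full 10^3 cube erodes
        # to its 8^3 interior under the radius-1 ball
        v = np.ones((10, 10, 10), bool)
        out = erode(_mask(v), make_ball(1))
        assert out.n_true == 8 ** 3
        assert out.values[1:-1, 1:-1, 1:-1].all()

    def test_single_voxel_erodes_away(self):
        v = np.zeros((5, 5, 5), bool)
        v[2, 2, 2] = True
        assert erode(_mask(v), make_ball(1)).n_true == 0

    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_oracle_on_random_masks(self, radius, rng):
        se = make_ball(radius)
        for _ in range(20):
            v = rng.random((12, 12, 12)) < 0.3
            m = _mask(v)
            assert np.array_equal(dilate(m, se).values, oracle_dilate(v, se))
            assert np.array_equal(erode(m, se).values, oracle_erode(v, se))

    def test_duality(self, rng):
        # erosion is the complement of dilating the complement, given the
        # border rule (pad the complement with True)
        se = make_ball(1)
        for _ in range(10):
            v = rng.random((10, 10, 10)) < 0.5
            pad = np.pad(~v, 1, constant_values=True)
            dil = oracle_dilate(pad, se)[1:-1, 1:-1, 1:-1]
            assert np.array_equal(erode(_mask(v), se).values, ~dil)

    def test_extensive_antiextensive_monotone(self, rng):
        se = make_ball(1)
        a = rng.random((10, 10, 10)) < 0.4
        b = a | (rng.random((10, 10, 10)) < 0.2)  # a subset of b
        assert (dilate(_mask(a), se).values >= a).all()
        assert (erode(_mask(a), se).values <= a).all()
        assert (dilate(_mask(a), se).values <= dilate(_mask(b), se).values).all()
        assert (erode(_mask(a), se).values <= erode(_mask(b), se).values).all()


def _random_tissues(rng, shape=(20, 20, 20)):
    grid = ImageGrid.isotropic(shape)
    labels = rng.integers(0, 4, size=shape)  # 0 bg, 1 wm, 2 gm, 3 csf
    brain = rng.random(shape) < 0.9
    wmh = (labels == 1) & (rng.random(shape) < 0.1)
    return TissueMaps(
        wm=BinaryMask(grid, labels == 1), gm=BinaryMask(grid, labels == 2),
        csf=BinaryMask(grid, labels == 3), brain=BinaryMask(grid, brain),
        wmh=BinaryMask(grid, wmh))


class TestWMSafe:
    def test_wm_voxel_touching_gm_excluded(self):
        grid = ImageGrid.isotropic((7, 7, 7))
        wm = np.zeros((7, 7, 7), bool)
        gm = np.zeros_like(wm)
        wm[3, 3, 3] = True
        gm[3, 3, 4] = True  # face neighbour
        t = TissueMaps(wm=BinaryMask(grid, wm), gm=BinaryMask(grid, gm),
                       csf=BinaryMask(grid, np.zeros_like(wm)),
                       brain=BinaryMask(grid, np.ones_like(wm)),
                       wmh=BinaryMask(grid, np.zeros_like(wm)))
        out = build_wm_safe(t, r_small=1, r_brain=0)
        assert not out.values[3, 3, 3]

    def test_interior_wm_voxel_included(self):
        grid = ImageGrid.isotropic((9, 9, 9))
        wm = np.ones((9, 9, 9), bool)
        zero = np.zeros_like(wm)
        t = TissueMaps(wm=BinaryMask(grid, wm), gm=BinaryMask(grid, zero),
                       csf=BinaryMask(grid, zero),
                       brain=BinaryMask(grid, wm), wmh=BinaryMask(grid, zero))
        out = build_wm_safe(t, r_small=1, r_brain=2)
        assert out.values[4, 4, 4]
        assert out.n_true < wm.sum()  # brain-edge erosion removed the rim

    def test_matches_term_by_term_oracle(self, rng):
        r_small, r_brain = 1, 3
        se_s, se_b = make_ball(r_small), make_ball(r_brain)
        for _ in range(5):
            t = _random_tissues(rng)
            got = build_wm_safe(t, r_small=r_small, r_brain=r_brain)
            expect = (t.wm.values
                      & ~oracle_dilate(t.gm.values, se_s)
                      & ~oracle_dilate(t.csf.values, se_s)
                      & oracle_erode(t.brain.values, se_b))
            assert np.array_equal(got.values, expect)

    def test_postconditions(self, rng):
        # the defining equation restated: no safe voxel within r_small of
        # GM or CSF, all inside the eroded brain mask, all inside WM
        t = _random_tissues(rng)
        safe = build_wm_safe(t, r_small=1, r_brain=3)
        se = make_ball(1)
        assert not (safe.values & dilate(t.gm, se).values).any()
        assert not (safe.values & dilate(t.csf, se).values).any()
        assert (safe.values <= erode(t.brain, make_ball(3)).values).all()
        assert (safe.values <= t.wm.values).all()

    def test_empty_wm_warns(self, rng):
        t = _random_tissues(rng)
        t.wm.values[:] = False
        with pytest.warns(UserWarning, match="empty WM"):
            out = build_wm_safe(t, r_small=1, r_brain=3)
        assert out.n_true == 0


class TestExpandWMH:
    def test_empty_stays_empty(self):
        v = np.zeros((9, 9, 9), bool)
        assert expand_wmh(_mask(v)).n_true == 0

    def test_single_voxel_becomes_radius2_ball(self):
        v = np.zeros((9, 9, 9), bool)
        v[4, 4, 4] = True
        assert expand_wmh(_mask(v)).n_true == 33

    def test_not_idempotent(self):
        # dilation grows: expanding twice strictly contains expanding once
        v = np.zeros((15, 15, 15), bool)
        v[7, 7, 7] = True
        once = expand_wmh(_mask(v))
        twice = expand_wmh(once)
        assert (once.values <= twice.values).all()
        assert twice.n_true > once.n_true


class TestSubtract:
    def test_self_subtraction_empty(self, rng):
        v = rng.random((8, 8, 8)) < 0.5
        assert subtract(_mask(v), _mask(v)).n_true == 0

    def test_subtract_empty_is_identity(self, rng):
        v = rng.random((8, 8, 8)) < 0.5
        out = subtract(_mask(v), _mask(np.zeros((8, 8, 8), bool)))
        assert np.array_equal(out.values, v)

    def test_elementwise_oracle(self, rng):
        a = rng.random((8, 8, 8)) < 0.5
        b = rng.random((8, 8, 8)) < 0.5
        out = subtract(_mask(a), _mask(b))
        assert np.array_equal(out.values, a & ~b)


class TestTissueMaps:
    def test_overlap_warns_and_counts(self):
        grid = ImageGrid.isotropic((5, 5, 5))
        wm = np.zeros((5, 5, 5), bool)
        gm = np.zeros_like(wm)
        wm[2, 2, 2] = gm[2, 2, 2] = True  # overlapping label
        with pytest.warns(UserWarning, match="overlap"):
            t = TissueMaps(wm=BinaryMask(grid, wm), gm=BinaryMask(grid, gm),
                           csf=BinaryMask(grid, np.zeros_like(wm)),
                           brain=BinaryMask(grid, np.ones_like(wm)),
                           wmh=BinaryMask(grid, np.zeros_like(wm)))
        assert t.overlap_count == 1
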