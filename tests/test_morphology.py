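"""Morphology checked bit-exactly against a brute-force set-translation oracle.

The oracle evaluates the set definitions literally: erosion keeps the points
whose translated SE offsets all land on foreground pixels, dilation the
points where some reflected offset does.  It shares no code with the
shift-based implementation.
"""

import numpy as np
import pytest

from holomorph import (
    InvalidParameterError,
    StructuringElement,
    binary_close,
    binary_open,
    close_open,
    dilate,
    disk_se,
    erode,
    open_close,
    square_se,
)


def oracle_erode(mask, se):
    rows, cols = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    offsets = se.offsets
    for r in range(rows):
        for c in range(cols):
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def oracle_dilate(mask, se):
    rows, cols = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for dr, dc in -se.offsets:  # reflection about the origin
        for r in range(rows):
            for c in range(cols):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                    out[r, c] = True
    return out


def oracle_open(mask, se):
    return oracle_dilate(oracle_erode(mask, se), se)


def oracle_close(mask, se):
    return oracle_erode(oracle_dilate(mask, se), se)


SES = [disk_se(1), square_se(2)]


class TestStructuringElements:
    def test_disk_radius_1_is_plus_shape(self):
        se = disk_se(1)
        assert se.footprint.shape == (3, 3)
        assert se.footprint.sum() == 5
        assert not se.footprint[0, 0] and not se.footprint[2, 2]
        assert se.origin == (1, 1)

    def test_disk_radius_0_single_cell(self):
        se = disk_se(0)
        assert se.footprint.shape == (1, 1) and se.footprint.all()

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_disk_matches_membership_rule(self, radius):
        se = disk_se(radius)
        rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        np.testing.assert_array_equal(se.footprint, rr**2 + cc**2 <= radius**2)

    def test_disk_radius_2_has_13_cells(self):
        assert disk_se(2).footprint.sum() == 13

    def test_square_origins(self):
        assert square_se(2).origin == (0, 0)
        assert square_se(3).origin == (1, 1)
        assert square_se(2).footprint.all()

    def test_square_1_is_identity_element(self, rng):
        mask = rng.random((16, 16)) > 0.5
        se = square_se(1)
        np.testing.assert_array_equal(erode(mask, se), mask)
        np.testing.assert_array_equal(dilate(mask, se), mask)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            disk_se(-1)
        with pytest.raises(InvalidParameterError):
            square_se(0)
        with pytest.raises(InvalidParameterError):
            StructuringElement(np.zeros((3, 3), dtype=bool), (1, 1))
        with pytest.raises(InvalidParameterError):
            StructuringElement(np.ones((3, 3), dtype=bool), (3, 0))


class TestPrimitivesAgainstOracle:
    def test_isolated_pixel_erodes_away(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not erode(mask, disk_se(1)).any()

    def test_all_true_unchanged_by_identity_se(self):
        mask = np.ones((8, 8), dtype=bool)
        np.testing.assert_array_equal(erode(mask, square_se(1)), mask)

    def test_block_erosion_by_square2(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        out = erode(mask, square_se(2))
        expected = oracle_erode(mask, square_se(2))
        np.testing.assert_array_equal(out, expected)
        assert out.sum() == 4  # 2x2 surviving block

    def test_single_pixel_dilates_to_plus(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        out = dilate(mask, disk_se(1))
        assert out.sum() == 5
        np.testing.assert_array_equal(out, oracle_dilate(mask, disk_se(1)))

    def test_dilate_empty_is_empty(self):
        mask = np.zeros((6, 6), dtype=bool)
        assert not dilate(mask, disk_se(1)).any()

    @pytest.mark.parametrize("se", SES, ids=["disk1", "square2"])
    def test_exact_agreement_with_oracle_on_random_masks(self, se):
        """200 random 32x32 masks, all six operations bit-identical."""
        rng = np.random.default_rng(1234)
        g1, g2 = disk_se(1), square_se(2)
        for trial in range(200):
            mask = rng.random((32, 32)) > rng.uniform(0.3, 0.7)
            np.testing.assert_array_equal(erode(mask, se), oracle_erode(mask, se))
            np.testing.assert_array_equal(dilate(mask, se), oracle_dilate(mask, se))
            if trial % 20 == 0:  # composites are implied, spot-check them
                np.testing.assert_array_equal(
                    binary_open(mask, se), oracle_open(mask, se)
                )
                np.testing.assert_array_equal(
                    binary_close(mask, se), oracle_close(mask, se)
                )
                np.testing.assert_array_equal(
                    open_close(mask, g1, g2),
                    oracle_close(oracle_open(mask, g1), g2),
                )
                np.testing.assert_array_equal(
                    close_open(mask, g1, g2),
                    oracle_open(oracle_close(mask, g1), g2),
                )

    def test_asymmetric_se_reflection_matters(self):
        """Dilation must use the reflected SE: checked on an L-shaped SE."""
        fp = np.array([[1, 1], [1, 0]], dtype=bool)
        se = StructuringElement(fp, (0, 0))
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 3] = True
        np.testing.assert_array_equal(dilate(mask, se), oracle_dilate(mask, se))
        rand = np.random.default_rng(5).random((8, 8)) > 0.4
        np.testing.assert_array_equal(erode(rand, se), oracle_erode(rand, se))
        np.testing.assert_array_equal(dilate(rand, se), oracle_dilate(rand, se))


@pytest.fixture(scope="module")
def masks():
    rng = np.random.default_rng(99)
    return [rng.random((32, 32)) > 0.5 for _ in range(20)]


class TestAlgebraicProperties:
    @pytest.mark.parametrize("se", SES, ids=["disk1", "square2"])
    def test_duality_away_from_frame(self, masks, se):
        """dilate(F, G) == ~erode(~F, G-reflected) in the image interior.

        With the outside-is-background convention the identity cannot hold
        on the frame itself (the complement is implicitly True there), so
        it is asserted on the interior, where the embedding is faithful.
        """
        refl = se.reflected()
        inner = (slice(2, -2), slice(2, -2))
        for mask in masks:
            np.testing.assert_array_equal(
                dilate(mask, se)[inner], (~erode(~mask, refl))[inner]
            )

    @pytest.mark.parametrize("se", SES, ids=["disk1", "square2"])
    def test_open_anti_extensive_close_extensive(self, masks, se):
        """open(F) <= F everywhere; F <= close(F) for sets off the frame."""
        for mask in masks:
            assert np.all(binary_open(mask, se) <= mask)
            interior = mask.copy()
            interior[:3] = interior[-3:] = False
            interior[:, :3] = interior[:, -3:] = False
            assert np.all(interior <= binary_close(interior, se))

    @pytest.mark.parametrize("se", SES, ids=["disk1", "square2"])
    def test_idempotence(self, masks, se):
        for mask in masks:
            opened = binary_open(mask, se)
            closed = binary_close(mask, se)
            np.testing.assert_array_equal(binary_open(opened, se), opened)
            np.testing.assert_array_equal(binary_close(closed, se), closed)

    @pytest.mark.parametrize("se", SES, ids=["disk1", "square2"])
    def test_monotonicity(self, masks, se):
        rng = np.random.default_rng(7)
        for mask in masks:
            smaller = mask & (rng.random(mask.shape) > 0.3)
            assert np.all(erode(smaller, se) <= erode(mask, se))
            assert np.all(dilate(smaller, se) <= dilate(mask, se))

    def test_cascades_on_smooth_block(self):
        """A large solid block passes the cascades essentially unchanged.

        CO preserves a square block exactly; OC's plus-shaped opening
        clips the four convex corner pixels (the square is not open with
        respect to the disk SE), which the oracle confirms.
        """
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        g1, g2 = disk_se(1), square_se(2)
        np.testing.assert_array_equal(close_open(mask, g1, g2), mask)
        oc = open_close(mask, g1, g2)
        np.testing.assert_array_equal(
            oc, oracle_close(oracle_open(mask, g1), g2)
        )
        corners = np.zeros_like(mask)
        corners[[5, 5, 14, 14], [5, 14, 5, 14]] = True
        np.testing.assert_array_equal(oc, mask & ~corners)

    def test_cascade_output_is_stable(self):
        """Re-running a cascade on its own output changes nothing further."""
        rng = np.random.default_rng(21)
        g1, g2 = disk_se(1), square_se(2)
        for _ in range(5):
            mask = rng.random((24, 24)) > 0.45
            once = close_open(mask, g1, g2)
            np.testing.assert_array_equal(close_open(once, g1, g2), once)

    def test_cascade_removes_speckle(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        speckled = mask.copy()
        for r, c in [(1, 1), (2, 17), (17, 2)]:
            speckled[r, c] = True
        out = open_close(speckled, disk_se(1), square_se(2))
        assert not out[1, 1] and not out[2, 17] and not out[17, 2]
        np.testing.assert_array_equal(
            out, oracle_close(oracle_open(speckled, disk_se(1)), square_se(2))
        )
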