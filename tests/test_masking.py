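"""Blind-spot perturbation: index cycling, neighbour means, masked loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proj2proj.exceptions import InvalidInputError
from proj2proj.masking import (
    PerturbationGrid,
    masked_projection_loss,
    perturb_sinogram,
    select_pixel_index,
)

GRID = PerturbationGrid(4, 4)


class TestSelectPixelIndex:
    @pytest.mark.parametrize(
        "iteration,expected", [(17, 1), (0, 0), (16, 0), (15, 15), (33, 1)]
    )
    def test_modulo_cycling(self, iteration, expected):
        assert select_pixel_index(iteration, GRID) == expected

    def test_negative_iteration_rejected(self):
        with pytest.raises(InvalidInputError):
            select_pixel_index(-1, GRID)

    def test_single_pixel_cell_rejected(self):
        with pytest.raises(InvalidInputError):
            PerturbationGrid(1, 1)


class TestPerturbSinogram:
    def test_constant_sinogram_unchanged_density_one_sixteenth(self):
        sino = np.full((16, 32), 5.0)
        out, mask = perturb_sinogram(sino, 3, GRID)
        assert np.array_equal(out, sino)  # neighbour mean of a constant
        assert mask.sum() == sino.size / 16

    def test_hand_computed_four_neighbour_mean(self):
        # index 5 is cell position (row 1, col 1): value 6 -> mean(2, 5, 7, 10)
        sino = np.arange(1.0, 17.0).reshape(4, 4)
        out, mask = perturb_sinogram(sino, 5, GRID)
        assert out[1, 1] == pytest.approx((2 + 5 + 7 + 10) / 4)
        assert mask.sum() == 1 and mask[1, 1]
        assert np.array_equal(out[~mask], sino[~mask])

    def test_exactly_one_pixel_per_cell_changes(self):
        rng = np.random.default_rng(0)
        sino = rng.random((8, 8))
        out, mask = perturb_sinogram(sino, 2, GRID)
        assert (out != sino).sum() == 4  # 4 complete cells
        assert np.array_equal(out != sino, mask)

    def test_unmasked_pixels_bit_identical(self):
        rng = np.random.default_rng(1)
        sino = rng.random((12, 20))
        out, mask = perturb_sinogram(sino, 9, GRID)
        assert np.array_equal(out[~mask], sino[~mask])

    def test_sixteen_iterations_cover_every_pixel_exactly_once(self):
        sino = np.zeros((8, 12))
        total = np.zeros(sino.shape, dtype=int)
        for t in range(16):
            _, mask = perturb_sinogram(sino, t, GRID)
            total += mask
        assert np.all(total == 1)

    def test_edge_pixels_use_available_neighbours(self):
        sino = np.arange(16.0).reshape(4, 4)
        out, mask = perturb_sinogram(sino, 0, GRID)  # corner (0, 0)
        assert mask[0, 0]
        assert out[0, 0] == pytest.approx((sino[0, 1] + sino[1, 0]) / 2)

    def test_incomplete_cells_perturbed_when_position_exists(self):
        sino = np.random.default_rng(2).random((6, 6))  # cells cut at edges
        _, mask = perturb_sinogram(sino, 5, GRID)  # position (1, 1)
        assert mask[1, 1] and mask[5, 5] and mask[1, 5] and mask[5, 1]

    def test_too_small_sinogram_rejected(self):
        with pytest.raises(InvalidInputError):
            perturb_sinogram(np.zeros((3, 4)), 0, GRID)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 200), st.integers(4, 11), st.integers(4, 11))
    def test_neighbour_means_from_unperturbed_input(self, t, h, w):
        # no cascading: every replaced value is the neighbour mean of the
        # ORIGINAL sinogram, never of an already-perturbed one
        rng = np.random.default_rng(t * 1000 + h * 10 + w)
        sino = rng.random((h, w))
        out, mask = perturb_sinogram(sino, t, GRID)
        for r, c in zip(*np.nonzero(mask)):
            nbrs = []
            if r > 0:
                nbrs.append(sino[r - 1, c])
            if r < h - 1:
                nbrs.append(sino[r + 1, c])
            if c > 0:
                nbrs.append(sino[r, c - 1])
            if c < w - 1:
                nbrs.append(sino[r, c + 1])
            assert out[r, c] == pytest.approx(np.mean(nbrs))


class TestMaskedLoss:
    def test_zero_when_equal(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[::4, ::4] = True
        x = np.random.default_rng(0).random((8, 8))
        assert masked_projection_loss(x, x, mask) == 0.0

    def test_uniform_offset_gives_squared_offset(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1::4, 1::4] = True
        x = np.random.default_rng(1).random((8, 8))
        assert masked_projection_loss(x + 1.0, x, mask) == pytest.approx(1.0)

    def test_blind_outside_mask(self):
        x = np.random.default_rng(2).random((8, 8))
        y = x.copy()
        _, mask = perturb_sinogram(x, 4, GRID)
        r, c = np.argwhere(~mask)[0]
        y[r, c] += 100.0  # huge change on an unmasked pixel
        assert masked_projection_loss(y, x, mask) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            masked_projection_loss(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            masked_projection_loss(np.ones((4, 4)), np.ones((4, 5)), np.ones((4, 4), bool))

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a, b = rng.random((8, 8)), rng.random((8, 8))
            _, mask = perturb_sinogram(a, int(rng.integers(0, 16)), GRID)
            assert masked_projection_loss(a, b, mask) >= 0
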