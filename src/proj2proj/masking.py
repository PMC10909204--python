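"""Blind-spot perturbation of sinograms and the masked projection loss.

The self-supervised scheme tiles the sinogram with a small grid of cells
(default 4x4).  At training iteration ``t`` the cell-internal position
``t mod (rows*cols)`` (row-major within the cell) is selected in *every*
cell, and each selected pixel is replaced by the mean of its 4-connected
neighbours in the original sinogram.  The training loss is then evaluated
only on the selected pixels, against the *unperturbed* sinogram, so the
network never sees the value it is asked to predict — the blind-spot
property that prevents collapse to the identity mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "PerturbationGrid",
    "select_pixel_index",
    "perturb_sinogram",
    "masked_projection_loss",
]


@dataclass(frozen=True)
class PerturbationGrid:
    """Cell shape of the perturbation tiling (default 4x4 → density 1/16)."""

    cell_rows: int = 4
    cell_cols: int = 4

    def __post_init__(self) -> None:
        if self.cell_rows < 1 or self.cell_cols < 1:
            raise InvalidInputError("cell dimensions must be >= 1")
        if self.cell_rows * self.cell_cols < 2:
            raise InvalidInputError(
                "a 1-pixel cell would perturb every pixel and force identity"
            )

    @property
    def n_pixels(self) -> int:
        return self.cell_rows * self.cell_cols


def select_pixel_index(iteration: int, grid: PerturbationGrid) -> int:
    """Cell-internal pixel index for this iteration: ``iteration mod n_pixels``.

    E.g. iteration 17 with a 4x4 grid selects index 17 mod 16 = 1, i.e.
    position (row 0, col 1) of every cell.
    """
    if iteration < 0:
        raise InvalidInputError(f"iteration must be >= 0, got {iteration}")
    return iteration % grid.n_pixels


def _neighbor_mean(values: np.ndarray) -> np.ndarray:
    """Mean of the available 4-connected neighbours of every pixel.

    Edge pixels average over their 2 or 3 in-bounds neighbours.
    """
    total = np.zeros_like(values, dtype=np.float64)
    count = np.zeros(values.shape, dtype=np.int64)
    total[1:, :] += values[:-1, :]
    count[1:, :] += 1
    total[:-1, :] += values[1:, :]
    count[:-1, :] += 1
    total[:, 1:] += values[:, :-1]
    count[:, 1:] += 1
    total[:, :-1] += values[:, 1:]
    count[:, :-1] += 1
    return total / count


def perturb_sinogram(
    sino: np.ndarray, iteration: int, grid: PerturbationGrid = PerturbationGrid()
) -> tuple[np.ndarray, np.ndarray]:
    """Replace one pixel per grid cell by its 4-neighbour mean.

    Neighbour means are computed from the unperturbed input (no cascading),
    all other pixels are returned bit-identical, and the boolean mask marks
    exactly the replaced pixels.  Cells cut off at the sinogram edge are
    perturbed only if the selected position exists inside the array.
    """
    sino = np.asarray(sino, dtype=np.float64)
    if sino.ndim != 2:
        raise InvalidInputError(f"sinogram must be 2D, got shape {sino.shape}")
    if sino.shape[0] < grid.cell_rows or sino.shape[1] < grid.cell_cols:
        raise InvalidInputError(
            f"sinogram {sino.shape} smaller than one {grid.cell_rows}x"
            f"{grid.cell_cols} cell"
        )
    idx = select_pixel_index(iteration, grid)
    pr, pc = divmod(idx, grid.cell_cols)
    rows = np.arange(sino.shape[0]) % grid.cell_rows == pr
    cols = np.arange(sino.shape[1]) % grid.cell_cols == pc
    mask = np.logical_and.outer(rows, cols)
    perturbed = np.where(mask, _neighbor_mean(sino), sino)
    return perturbed, mask


def masked_projection_loss(
    pred_sino: np.ndarray, target_sino: np.ndarray, mask: np.ndarray
) -> float:
    """Mean squared difference restricted to the masked entries."""
    pred_sino = np.asarray(pred_sino)
    target_sino = np.asarray(target_sino)
    mask = np.asarray(mask, dtype=bool)
    if pred_sino.shape != target_sino.shape or pred_sino.shape != mask.shape:
        raise InvalidInputError(
            f"shape mismatch: pred {pred_sino.shape}, target {target_sino.shape}, "
            f"mask {mask.shape}"
        )
    if not mask.any():
        raise InvalidInputError("mask selects no pixels")
    diff = pred_sino[mask] - target_sino[mask]
    return float(np.mean(diff**2))
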