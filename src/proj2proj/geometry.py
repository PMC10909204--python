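"""Parallel-beam projection geometry, discrete Radon transform, and FBP.

The forward operator is assembled as a sparse matrix so that one object serves
three roles at once: the simulator of low-dose projections, the data-fidelity
operator inside the self-supervised training loss (whose gradient is the exact
matrix transpose), and the system matrix for algebraic reconstruction.  A
mismatch between the operator used for simulation and the one used in the
training loss would leak systematic error into the loss, so every consumer in
this package goes through the same :class:`RadonTransform`.

Discretisation
--------------
Pixel-driven, bilinear:  for a view at angle ``theta`` the image is sampled on
a grid rotated by ``theta`` (unit step in both the detector direction ``s``
and the ray direction ``t``) and summed along ``t``.  Each sample point
spreads onto its four neighbouring pixels with bilinear weights, which makes
the matrix rows exactly the rotate-and-sum operation used by common
inverse-Radon stacks.  Angle 0 sends rays parallel to the image columns, i.e.
the first sinogram row is (up to interpolation) the per-column sum of the
image.  Detectors are centred on the image centre with spacing equal to one
image pixel by default.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.fft import fft, ifft

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "ProjectionGeometry",
    "RadonTransform",
    "radon_forward",
    "back_project",
    "fbp_reconstruct",
]

# Matrices above this nnz estimate are never cached; they are built and
# applied one block of views at a time (dense-view FBP consistency checks).
_CACHE_NNZ_LIMIT = 120_000_000
# Total nnz kept in the process-wide LRU operator cache.
_CACHE_TOTAL_NNZ = 180_000_000
_VIEW_CHUNK = 8


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam acquisition geometry for square images.

    Parameters
    ----------
    image_size:
        Pixels per side of the (square) image.
    n_views:
        Number of projection angles, uniformly spaced over ``[0, pi)``
        (half-open: 180 degrees is the same line integral as 0).
    n_detectors:
        Detector bins per view.
    detector_spacing:
        Detector pitch in units of the image pixel width.
    """

    image_size: int
    n_views: int
    n_detectors: int
    detector_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.image_size < 1 or self.n_views < 1 or self.n_detectors < 1:
            raise InvalidInputError(
                "image_size, n_views and n_detectors must all be >= 1, got "
                f"{self.image_size}, {self.n_views}, {self.n_detectors}"
            )
        if not (self.detector_spacing > 0):
            raise InvalidInputError("detector_spacing must be positive")

    @property
    def angles(self) -> np.ndarray:
        """Projection angles in radians, strictly increasing in ``[0, pi)``."""
        return np.linspace(0.0, np.pi, self.n_views, endpoint=False)

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_views, self.n_detectors)

    def check_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.shape != (self.image_size, self.image_size):
            raise InvalidInputError(
                f"image shape {image.shape} does not match geometry "
                f"({self.image_size}, {self.image_size})"
            )
        return image

    def check_sinogram(self, sino: np.ndarray) -> np.ndarray:
        sino = np.asarray(sino)
        if sino.shape != self.sinogram_shape:
            raise InvalidInputError(
                f"sinogram shape {sino.shape} does not match geometry "
                f"{self.sinogram_shape}"
            )
        return sino


def default_geometry() -> ProjectionGeometry:
    """The sparse-view setting used throughout: 512x512 image, 64 views, 512 bins."""
    return ProjectionGeometry(image_size=512, n_views=64, n_detectors=512)


# ---------------------------------------------------------------------------
# Sparse system-matrix assembly
# ---------------------------------------------------------------------------

def _view_block_matrix(geom: ProjectionGeometry, view_indices: np.ndarray) -> sp.csr_matrix:
    """Rows of the system matrix for a block of views, shape (len(block)*n_det, n*n)."""
    n = geom.image_size
    n_det = geom.n_detectors
    c = (n - 1) / 2.0
    # Ray-direction samples cover the full image diagonal at unit step.
    n_samp = int(math.ceil(n * math.sqrt(2.0))) + 1
    t = np.arange(n_samp, dtype=np.float64) - (n_samp - 1) / 2.0
    s = (np.arange(n_det, dtype=np.float64) - (n_det - 1) / 2.0) * geom.detector_spacing
    angles = geom.angles[view_indices]

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    for k, theta in enumerate(angles):
        ct, st = math.cos(theta), math.sin(theta)
        # sample point (row, col) = center + s * u_perp + t * u_dir
        r = c - s[:, None] * st + t[None, :] * ct
        q = c + s[:, None] * ct + t[None, :] * st
        inb = (r > -1.0) & (r < n) & (q > -1.0) & (q < n)
        det_idx = np.broadcast_to(np.arange(n_det)[:, None], r.shape)[inb]
        r = r[inb]
        q = q[inb]
        r0 = np.floor(r)
        q0 = np.floor(q)
        fr = r - r0
        fq = q - q0
        r0 = r0.astype(np.int64)
        q0 = q0.astype(np.int64)
        for dr_, dq_, w in (
            (0, 0, (1 - fr) * (1 - fq)),
            (0, 1, (1 - fr) * fq),
            (1, 0, fr * (1 - fq)),
            (1, 1, fr * fq),
        ):
            rr = r0 + dr_
            qq = q0 + dq_
            ok = (rr >= 0) & (rr < n) & (qq >= 0) & (qq < n) & (w > 0)
            rows_out.append(k * n_det + det_idx[ok])
            cols_out.append(rr[ok] * n + qq[ok])
            vals_out.append(w[ok])
    rows = np.concatenate(rows_out)
    cols = np.concatenate(cols_out).astype(np.int32)
    vals = np.concatenate(vals_out).astype(np.float32)
    m = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(view_indices) * n_det, n * n), dtype=np.float32
    )
    return m.tocsr()


def _estimated_nnz(geom: ProjectionGeometry) -> int:
    # ~4 bilinear corners per in-bounds unit-cell sample, ~image_size^2 samples/view
    return 4 * geom.image_size**2 * geom.n_views


class RadonTransform:
    """The discrete parallel-beam forward operator A and its exact adjoint.

    ``forward`` computes line integrals (sinogram); ``adjoint`` applies the
    matrix transpose, which back-smears sinogram values along rays.  The
    adjoint carries no angular normalisation: summed over views, each image
    pixel receives a total weight of about ``n_views`` per unit sinogram.
    """

    def __init__(self, geom: ProjectionGeometry):
        self.geom = geom
        self._matrix: sp.csr_matrix | None = None
        nnz = _estimated_nnz(geom)
        self._streaming = nnz > _CACHE_NNZ_LIMIT
        if not self._streaming:
            self._matrix = _cached_matrix(geom)

    # -- application ------------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        image = self.geom.check_image(image)
        if not np.all(np.isfinite(image)):
            raise InvalidInputError("image contains non-finite values")
        x = np.ascontiguousarray(image, dtype=np.float32).ravel()
        if self._matrix is not None:
            y = self._matrix @ x
        else:
            y = np.empty(self.geom.n_views * self.geom.n_detectors, dtype=np.float32)
            for block, rows in self._iter_blocks():
                y[rows] = block @ x
        return y.reshape(self.geom.sinogram_shape).astype(np.float64)

    def adjoint(self, sino: np.ndarray) -> np.ndarray:
        sino = self.geom.check_sinogram(sino)
        if not np.all(np.isfinite(sino)):
            raise InvalidInputError("sinogram contains non-finite values")
        y = np.ascontiguousarray(sino, dtype=np.float32).ravel()
        if self._matrix is not None:
            x = self._matrix.T @ y
        else:
            n = self.geom.image_size
            x = np.zeros(n * n, dtype=np.float32)
            for block, rows in self._iter_blocks():
                x += block.T @ y[rows]
        return x.reshape(self.geom.image_size, self.geom.image_size).astype(np.float64)

    def _iter_blocks(self):
        n_det = self.geom.n_detectors
        for start in range(0, self.geom.n_views, _VIEW_CHUNK):
            idx = np.arange(start, min(start + _VIEW_CHUNK, self.geom.n_views))
            rows = slice(start * n_det, (start + len(idx)) * n_det)
            yield _view_block_matrix(self.geom, idx), rows

    # -- SART support -----------------------------------------------------
    def row_sums(self) -> np.ndarray:
        """A @ 1 — per-ray intersection weight (approximate ray length in pixels)."""
        return self.forward(np.ones((self.geom.image_size,) * 2)).ravel()

    def col_sums(self) -> np.ndarray:
        """A^T @ 1 — per-pixel total weight over all views."""
        return self.adjoint(np.ones(self.geom.sinogram_shape)).ravel()


_matrix_cache: OrderedDict[tuple, sp.csr_matrix] = OrderedDict()


def _cached_matrix(geom: ProjectionGeometry) -> sp.csr_matrix:
    key = (geom.image_size, geom.n_views, geom.n_detectors, geom.detector_spacing)
    if key in _matrix_cache:
        _matrix_cache.move_to_end(key)
        return _matrix_cache[key]
    blocks = [
        _view_block_matrix(geom, np.arange(s, min(s + _VIEW_CHUNK, geom.n_views)))
        for s in range(0, geom.n_views, _VIEW_CHUNK)
    ]
    mat = blocks[0] if len(blocks) == 1 else sp.vstack(blocks, format="csr")
    _matrix_cache[key] = mat
    total = sum(m.nnz for m in _matrix_cache.values())
    while total > _CACHE_TOTAL_NNZ and len(_matrix_cache) > 1:
        _, evicted = _matrix_cache.popitem(last=False)
        total -= evicted.nnz
    return mat


def clear_operator_cache() -> None:
    """Drop all cached system matrices (frees memory between large experiments)."""
    _matrix_cache.clear()


# ---------------------------------------------------------------------------
# Public functional surface
# ---------------------------------------------------------------------------

def radon_forward(image: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    """Line integrals of ``image`` at every (angle, detector) pair of ``geom``."""
    return RadonTransform(geom).forward(image)


def back_project(sino: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    """Adjoint (transpose) of :func:`radon_forward`; unfiltered, unnormalised."""
    return RadonTransform(geom).adjoint(sino)


def _ramp_filter(padded_size: int) -> np.ndarray:
    """Frequency response of the discrete ramp, from its space-domain kernel.

    Built Fourier-transforming the band-limited real-space ramp kernel
    (f[0] = 1/4, f[odd n] = -1/(pi n)^2) rather than as |f| directly, which
    avoids the DC bias of the naive ramp.
    """
    n = np.concatenate(
        (
            np.arange(1, padded_size / 2 + 1, 2, dtype=int),
            np.arange(padded_size / 2 - 1, 0, -2, dtype=int),
        )
    )
    f = np.zeros(padded_size)
    f[0] = 0.25
    f[1::2] = -1.0 / (np.pi * n) ** 2
    return 2.0 * np.real(fft(f))


_FILTERS = ("ramp",)


def fbp_reconstruct(
    sino: np.ndarray, geom: ProjectionGeometry, filter_name: str = "ramp"
) -> np.ndarray:
    """Filtered back projection with a ramp filter.

    Each view is ramp-filtered along the detector axis (zero-padded FFT),
    back-projected with the adjoint operator, and scaled by
    ``pi / (2 * n_views)``.  The output is *not* clipped to [0, 1]; value-range
    policy belongs to the metrics layer.
    """
    if filter_name not in _FILTERS:
        raise ConfigurationError(
            f"unknown filter {filter_name!r}; available: {_FILTERS}"
        )
    sino = geom.check_sinogram(sino)
    n_det = geom.n_detectors
    padded = max(64, int(2 ** math.ceil(math.log2(2 * n_det))))
    filt = _ramp_filter(padded)
    proj = fft(sino, padded, axis=1) * filt[None, :]
    filtered = np.real(ifft(proj, axis=1))[:, :n_det]
    recon = RadonTransform(geom).adjoint(filtered)
    recon *= np.pi / (2.0 * geom.n_views)
    return recon
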