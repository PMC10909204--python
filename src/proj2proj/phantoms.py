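"""Synthetic ground-truth generators: Shepp–Logan and random-ellipse images.

Both generators rasterize analytic ellipses with sub-pixel supersampling
(area-weighted anti-aliasing), which keeps rasterization consistent under
grid refinement.  All images are attenuation maps in [0, 1].
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "EllipseSpec",
    "DatasetSplit",
    "shepp_logan",
    "random_ellipses_image",
    "generate_dataset",
    "load_image_folder",
]


@dataclass(frozen=True)
class EllipseSpec:
    """One additive ellipse in normalized [-1, 1]^2 coordinates.

    ``center`` is (x, y) with x rightwards and y upwards; ``semi_axes`` (a, b)
    are the semi-axis lengths along the (pre-rotation) x and y directions;
    ``rotation`` is counter-clockwise in radians; ``intensity`` is added to
    every covered pixel.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    intensity: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise InvalidInputError(f"semi_axes must be positive, got {self.semi_axes}")


# Standard ("modified"/Toft) Shepp–Logan head phantom:
# (intensity, a, b, x0, y0, rotation_degrees)
_SHEPP_LOGAN_TABLE: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
)


def rasterize_ellipses(
    specs: list[EllipseSpec] | tuple[EllipseSpec, ...],
    size: int,
    supersample: int = 2,
) -> np.ndarray:
    """Sum of ellipse indicators on a ``size`` x ``size`` grid (not clipped).

    Evaluated on a ``supersample``-times finer grid and block-averaged, so
    boundary pixels carry fractional (area-weighted) intensity.
    """
    if size < 16:
        raise InvalidInputError(f"size must be >= 16, got {size}")
    n = size * supersample
    # pixel centres in normalized coordinates; row 0 is y = +1 side
    coords = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    x = coords[None, :]
    y = -coords[:, None]
    img = np.zeros((n, n))
    for e in specs:
        cx, cy = e.center
        a, b = e.semi_axes
        ct, st = np.cos(e.rotation), np.sin(e.rotation)
        xr = (x - cx) * ct + (y - cy) * st
        yr = -(x - cx) * st + (y - cy) * ct
        img += e.intensity * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    if supersample > 1:
        img = img.reshape(size, supersample, size, supersample).mean(axis=(1, 3))
    return img


def shepp_logan(size: int) -> np.ndarray:
    """Standard 10-ellipse Shepp–Logan head phantom, values in [0, 1]."""
    specs = [
        EllipseSpec((x0, y0), (a, b), np.deg2rad(rot), v)
        for v, a, b, x0, y0, rot in _SHEPP_LOGAN_TABLE
    ]
    return np.clip(rasterize_ellipses(specs, size, supersample=4), 0.0, 1.0)


def fov_mask(size: int) -> np.ndarray:
    """Boolean mask of the inscribed field-of-view disk (the scanner FOV)."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - c) ** 2 + (xx - c) ** 2) <= (size / 2.0) ** 2


def random_ellipses_image(
    size: int,
    n_ellipses_range: tuple[int, int] | None = None,
    rng_seed: int | np.random.Generator = 0,
    fov_circle: bool = True,
) -> np.ndarray:
    """One random-ellipse image: a clipped sum of randomly sampled ellipses.

    The default distribution emulates the artificial-ellipses benchmark
    datasets used for sparse-view CT: the ellipse count is Poisson with mean
    40, capped at 70; intensities are uniform in [-0.4, 1.0] (negative values
    carve darker structures out of overlaps); semi-axes are 0.2 times a unit
    exponential (capped at 1); centres uniform in [-0.9, 0.9]^2; rotations
    uniform in [0, 2 pi).  The sum is clipped to [0, 1] and, by default,
    confined to the inscribed field-of-view disk (CT scanners measure inside
    a circular FOV; content outside it would not be consistently sampled by
    the projections).  Passing ``n_ellipses_range`` replaces the Poisson
    count with a uniform count over the inclusive range.  Deterministic
    given the seed.
    """
    if size < 16:
        raise InvalidInputError(f"size must be >= 16, got {size}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if n_ellipses_range is None:
        n_ell = int(min(rng.poisson(40), 70))
    else:
        lo, hi = n_ellipses_range
        if lo > hi or lo < 0:
            raise InvalidInputError(f"invalid n_ellipses_range {n_ellipses_range}")
        n_ell = int(rng.integers(lo, hi + 1))
    specs = [
        EllipseSpec(
            center=tuple(rng.uniform(-0.9, 0.9, size=2)),
            semi_axes=tuple(np.clip(0.2 * rng.exponential(1.0, size=2), 1e-3, 1.0)),
            rotation=float(rng.uniform(0.0, 2.0 * np.pi)),
            intensity=float(rng.uniform(-0.4, 1.0)),
        )
        for _ in range(n_ell)
    ]
    if not specs:
        return np.zeros((size, size))
    img = np.clip(rasterize_ellipses(specs, size), 0.0, 1.0)
    if fov_circle:
        img *= fov_mask(size)
    return img


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test image collections plus the seed used."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        for part in (self.train, self.validation, self.test):
            if part.ndim != 3:
                raise InvalidInputError("split parts must be stacks of 2D images")


def generate_dataset(
    n_total: int,
    fractions: tuple[float, float, float],
    size: int,
    rng_seed: int = 0,
    n_ellipses_range: tuple[int, int] = (3, 10),
) -> DatasetSplit:
    """Generate ``n_total`` random-ellipse images and split them.

    Split sizes are ``floor(n_total * fraction)`` for validation and test,
    with the remainder assigned to training, so ``(10, (0.6, 0.2, 0.2))``
    yields 6/2/2.  Content is disjoint by construction (sequential slices of
    one seeded stream).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ConfigurationError(f"fractions must be nonnegative, got {fractions}")
    rng = np.random.default_rng(rng_seed)
    images = np.stack(
        [random_ellipses_image(size, n_ellipses_range, rng) for _ in range(n_total)]
    )
    n_val = int(n_total * fractions[1])
    n_test = int(n_total * fractions[2])
    n_train = n_total - n_val - n_test
    return DatasetSplit(
        train=images[:n_train],
        validation=images[n_train : n_train + n_val],
        test=images[n_train + n_val :],
        seed=rng_seed,
    )


def load_image_folder(path: str | pathlib.Path, sort: bool = True) -> np.ndarray:
    """Read a folder of grayscale TIFF/PNG slices, normalized to [0, 1].

    Integer images are scaled by their dtype maximum; float images are
    clipped to [0, 1].  RGB inputs are averaged to one channel.  Lets real
    CT slices stand in for the synthetic generators.
    """
    import imageio.v3 as iio

    p = pathlib.Path(path)
    files = [f for f in p.iterdir() if f.suffix.lower() in (".tif", ".tiff", ".png")]
    if sort:
        files.sort()
    if not files:
        raise InvalidInputError(f"no TIFF/PNG images found in {p}")
    out = []
    for f in files:
        raw = np.asarray(iio.imread(f))
        arr = raw.astype(np.float64)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        if np.issubdtype(raw.dtype, np.integer):
            arr = arr / np.iinfo(raw.dtype).max
        out.append(np.clip(arr, 0.0, 1.0))
    shapes = {a.shape for a in out}
    if len(shapes) != 1:
        raise InvalidInputError(f"images in {p} have mixed shapes: {shapes}")
    return np.stack(out)
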