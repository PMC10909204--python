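"""Dataset and image persistence: HDF5 containers and 32-bit TIFF slices.

A dataset file holds ``/images`` (ground truth) and optionally ``/sinograms``
(one per image), with the acquisition geometry, noise level, seed and config
hash stored as root attributes so every artifact records what produced it.
"""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import tifffile

from .exceptions import InvalidInputError
from .geometry import ProjectionGeometry

__all__ = ["save_dataset", "load_dataset", "save_tiff", "load_tiff"]


def save_dataset(
    path: str | pathlib.Path,
    images: np.ndarray,
    sinograms: np.ndarray | None = None,
    geometry: ProjectionGeometry | None = None,
    snr_db: float | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write images (and optionally sinograms plus geometry) to one HDF5 file."""
    images = np.asarray(images)
    if images.ndim != 3:
        raise InvalidInputError(f"images must be (n, h, w), got {images.shape}")
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=images.astype(np.float32))
        if sinograms is not None:
            sinograms = np.asarray(sinograms)
            if sinograms.shape[0] != images.shape[0]:
                raise InvalidInputError("images and sinograms counts differ")
            f.create_dataset("sinograms", data=sinograms.astype(np.float32))
        if geometry is not None:
            f.attrs["image_size"] = geometry.image_size
            f.attrs["n_views"] = geometry.n_views
            f.attrs["n_detectors"] = geometry.n_detectors
            f.attrs["detector_spacing"] = geometry.detector_spacing
        if snr_db is not None:
            f.attrs["snr_db"] = snr_db
        if seed is not None:
            f.attrs["seed"] = seed
        if config_hash is not None:
            f.attrs["config_hash"] = config_hash


def load_dataset(path: str | pathlib.Path):
    """Read a dataset file; returns (images, sinograms_or_None, geometry_or_None, attrs)."""
    with h5py.File(path, "r") as f:
        images = f["images"][:].astype(np.float64)
        sinograms = f["sinograms"][:].astype(np.float64) if "sinograms" in f else None
        geom = None
        if "image_size" in f.attrs:
            geom = ProjectionGeometry(
                image_size=int(f.attrs["image_size"]),
                n_views=int(f.attrs["n_views"]),
                n_detectors=int(f.attrs["n_detectors"]),
                detector_spacing=float(f.attrs.get("detector_spacing", 1.0)),
            )
        attrs = {k: f.attrs[k] for k in f.attrs}
    return images, sinograms, geom, attrs


def save_tiff(path: str | pathlib.Path, image: np.ndarray) -> None:
    """Write a single slice as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def load_tiff(path: str | pathlib.Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float64)
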