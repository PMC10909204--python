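"""Image-quality metrics (PSNR, SSIM) and 1-D line profiles.

Reconstructions are compared against references on a fixed data range of 1.0
(attenuation images live in [0, 1]); the evaluation helpers clip
reconstruction outputs into [0, 1] before computing metrics, a policy noted
in every report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .exceptions import InvalidInputError

__all__ = [
    "psnr",
    "ssim",
    "lpips_available",
    "lpips_distance",
    "line_profile",
    "EvaluationReport",
    "evaluate_reconstructions",
]


def _check_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise InvalidInputError(
            f"shape mismatch: reference {reference.shape} vs test {test.shape}"
        )
    return reference, test


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, ``10 log10(data_range^2 / MSE)`` in dB.

    Returns ``inf`` for identical images.
    """
    reference, test = _check_pair(reference, test)
    if not (data_range > 0):
        raise InvalidInputError("data_range must be > 0")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity with the standard 11x11 Gaussian window.

    sigma = 1.5, K1 = 0.01, K2 = 0.03, population covariance — the constants
    of the original SSIM definition.
    """
    reference, test = _check_pair(reference, test)
    return float(
        structural_similarity(
            reference,
            test,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def lpips_available() -> bool:
    """Whether the optional learned-perceptual-metric dependency is installed."""
    try:
        import lpips  # type: ignore[import-not-found]  # noqa: F401

        return True
    except ImportError:
        return False


def lpips_distance(reference: np.ndarray, test: np.ndarray) -> float:
    """Learned perceptual distance via the optional ``lpips`` package.

    Plug-in hook only (the network and its pretrained weights are external);
    reports flag this metric as "n/a" when the dependency is absent.
    """
    try:
        import lpips  # type: ignore[import-not-found]
        import torch  # type: ignore[import-not-found]
    except ImportError as exc:
        raise InvalidInputError(
            "lpips_distance requires the optional 'lpips' and 'torch' packages"
        ) from exc
    reference, test = _check_pair(reference, test)
    model = lpips.LPIPS(net="alex", verbose=False)
    to_t = lambda a: torch.as_tensor(
        (2.0 * np.clip(a, 0, 1) - 1.0)[None, None], dtype=torch.float32
    ).repeat(1, 3, 1, 1)
    with torch.no_grad():
        return float(model(to_t(reference), to_t(test)).item())


def line_profile(image: np.ndarray, axis: str, index: int) -> np.ndarray:
    """Pixel values along one row (``axis='row'``) or column (``axis='col'``)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidInputError(f"expected a 2D image, got shape {image.shape}")
    if axis not in ("row", "col"):
        raise InvalidInputError(f"axis must be 'row' or 'col', got {axis!r}")
    n = image.shape[0] if axis == "row" else image.shape[1]
    if not (0 <= index < n):
        raise InvalidInputError(f"index {index} out of range for axis {axis!r} ({n})")
    return image[index, :].copy() if axis == "row" else image[:, index].copy()


@dataclass
class EvaluationReport:
    """Per-image and summary metrics for one method at one noise level."""

    method: str
    snr_db: float | None
    psnr_values: np.ndarray
    ssim_values: np.ndarray
    clipped: bool = True

    @property
    def psnr_mean(self) -> float:
        return float(np.mean(self.psnr_values))

    @property
    def psnr_std(self) -> float:
        return float(np.std(self.psnr_values))

    @property
    def ssim_mean(self) -> float:
        return float(np.mean(self.ssim_values))

    @property
    def ssim_std(self) -> float:
        return float(np.std(self.ssim_values))

    def summary(self) -> str:
        level = "noiseless" if self.snr_db is None else f"{self.snr_db:g} dB"
        return (
            f"{self.method} @ {level}: PSNR {self.psnr_mean:.2f} ± {self.psnr_std:.2f} dB, "
            f"SSIM {self.ssim_mean:.3f} ± {self.ssim_std:.3f} (n={len(self.psnr_values)})"
        )


def evaluate_reconstructions(
    method: str,
    references,
    reconstructions,
    snr_db: float | None = None,
    clip: bool = True,
) -> EvaluationReport:
    """PSNR/SSIM of each reconstruction against its reference (data range 1).

    Reconstructions are clipped to [0, 1] first unless ``clip=False``.
    """
    p_vals = []
    s_vals = []
    for ref, rec in zip(references, reconstructions, strict=True):
        rec = np.clip(rec, 0.0, 1.0) if clip else rec
        p_vals.append(psnr(ref, rec))
        s_vals.append(ssim(ref, rec))
    return EvaluationReport(
        method=method,
        snr_db=snr_db,
        psnr_values=np.asarray(p_vals),
        ssim_values=np.asarray(s_vals),
        clipped=clip,
    )
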