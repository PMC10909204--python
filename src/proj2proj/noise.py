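"""Additive white Gaussian sinogram noise at a target SNR in dB.

The signal power is the mean squared value over all (view, detector) entries
of the sinogram, and the noise variance is set to
``P_signal * 10**(-snr_db / 10)``.  Gaussian, zero-mean, i.i.d. per entry:
the projection-domain blind-spot scheme relies on per-pixel noise
independence, which holds in the projection domain but not in the image
domain after back projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["NoiseModel", "add_noise_snr"]


@dataclass(frozen=True)
class NoiseModel:
    """Target sinogram signal-to-noise ratio in dB plus the RNG seed.

    ``snr_db=None`` (or ``inf``) is the noiseless sentinel.
    """

    snr_db: float | None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_db is not None and np.isnan(self.snr_db):
            raise InvalidInputError("snr_db must be finite or None/inf")


def add_noise_snr(sino: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Contaminate ``sino`` with white Gaussian noise at ``model.snr_db``.

    Deterministic given ``model.seed``.  Raises if the sinogram has zero
    signal power (the SNR target would be undefined).
    """
    sino = np.asarray(sino, dtype=np.float64)
    if model.snr_db is None or np.isinf(model.snr_db):
        return sino.copy()
    p_signal = float(np.mean(sino**2))
    if p_signal <= 0.0:
        raise InvalidInputError("sinogram has zero power; SNR target undefined")
    sigma = np.sqrt(p_signal * 10.0 ** (-model.snr_db / 10.0))
    rng = np.random.default_rng(model.seed)
    return sino + sigma * rng.standard_normal(sino.shape)
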