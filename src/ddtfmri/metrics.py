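"""Reconstruction quality metrics: PSNR, HFEN, SSIM, error maps.

All metrics operate on magnitude images.  Complex inputs are converted to
magnitudes first, then both images are rescaled by 255 / max(|reference|) so
the conventional 8-bit peak value of 255 applies regardless of the source
intensity scale (the applied scale factor is logged at DEBUG level).

PSNR = 20*log10(255 / RMSE).  HFEN is the norm of the difference of the
Laplacian-of-Gaussian filtered images divided by the norm of the filtered
reference (15x15 kernel, sigma = 1.5), emphasizing edges and fine detail.
SSIM is the mean local structural similarity with the standard constants
(K1 = 0.01, K2 = 0.03, L = 255, 11x11 Gaussian window with sigma = 1.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate
from skimage.metrics import structural_similarity

logger = logging.getLogger(__name__)

PSNR_CAP_DB = 999.0  # sentinel reported for identical images (RMSE = 0)

HFEN_KERNEL_SIZE = 15
HFEN_SIGMA = 1.5


def _magnitude_pair(reference, reconstruction):
    ref = np.abs(np.asarray(reference, dtype=np.complex128)).real
    rec = np.abs(np.asarray(reconstruction, dtype=np.complex128)).real
    if ref.shape != rec.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {rec.shape}")
    peak = ref.max()
    if peak <= 0:
        raise ValueError("reference image is identically zero")
    scale = 255.0 / peak
    if not np.isclose(scale, 1.0):
        logger.debug("metrics: rescaling magnitudes by %.6g", scale)
    return ref * scale, rec * scale


def psnr(reference, reconstruction) -> float:
    """Peak signal-to-noise ratio in dB, with peak 255.

    Identical inputs would give infinite PSNR; the sentinel 999 dB is
    returned instead so downstream tables stay finite.
    """
    ref, rec = _magnitude_pair(reference, reconstruction)
    rmse = np.sqrt(np.mean((ref - rec) ** 2))
    if rmse == 0:
        return PSNR_CAP_DB
    return float(20.0 * np.log10(255.0 / rmse))


def log_kernel(size: int = HFEN_KERNEL_SIZE, sigma: float = HFEN_SIGMA) -> np.ndarray:
    """Laplacian-of-Gaussian kernel, mean-subtracted so it exactly kills DC."""
    half = (size - 1) / 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = x**2 + y**2
    g = np.exp(-r2 / (2 * sigma**2))
    k = (r2 - 2 * sigma**2) / sigma**4 * g
    k -= k.mean()
    return k


def hfen(reference, reconstruction) -> float:
    """High-frequency error norm, normalized by the filtered reference."""
    ref, rec = _magnitude_pair(reference, reconstruction)
    k = log_kernel()
    ref_f = correlate(ref, k, mode="reflect")
    rec_f = correlate(rec, k, mode="reflect")
    denom = np.linalg.norm(ref_f)
    if denom == 0:
        raise ValueError("LoG-filtered reference has zero norm")
    return float(np.linalg.norm(ref_f - rec_f) / denom)


def ssim(reference, reconstruction) -> float:
    """Mean structural similarity index on [0, 255] magnitudes."""
    ref, rec = _magnitude_pair(reference, reconstruction)
    return float(
        structural_similarity(
            ref,
            rec,
            data_range=255.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


@dataclass
class EvalReport:
    """The three scalar metrics plus the absolute-difference error map."""

    psnr_db: float
    hfen: float
    ssim: float
    error_map: np.ndarray


def evaluate(reference, reconstruction) -> EvalReport:
    """Compute all metrics and the |reference - reconstruction| map."""
    err = np.abs(
        np.abs(np.asarray(reference, dtype=np.complex128))
        - np.abs(np.asarray(reconstruction, dtype=np.complex128))
    )
    return EvalReport(
        psnr_db=psnr(reference, reconstruction),
        hfen=hfen(reference, reconstruction),
        ssim=ssim(reference, reconstruction),
        error_map=err,
    )
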