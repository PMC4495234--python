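"""Data-driven filter-bank update.

The adaptive step of the reconstruction alternates between sparse coding in
the current frame and re-fitting the frame itself.  Re-fitting minimizes

    || W x - C ||_F^2   subject to   W^H W = I,

over banks W generated by r x r filters.  In the patch domain this is an
orthogonal Procrustes problem: with G the r**2 x N matrix of all stride-1
image patches (one column per pixel) and A the flattened-filter matrix, the
convolutional objective equals ||A^H G - C||_F^2 under periodic boundary, and
the minimizer over A A^H = (1/r**2) I is obtained in closed form from one
SVD of G @ C^H.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .frames import FilterBank

logger = logging.getLogger(__name__)


@dataclass
class PatchMatrix:
    """All r x r patches of an image, one flattened patch per column."""

    data: np.ndarray  # (r**2, N)
    source_shape: tuple
    boundary: str = "periodic"

    @property
    def r(self) -> int:
        return int(round(np.sqrt(self.data.shape[0])))

    @property
    def n_patches(self) -> int:
        return self.data.shape[1]


def extract_patches(
    image: np.ndarray,
    r: int,
    boundary: str = "periodic",
    max_patches: int | None = None,
    seed: int | None = None,
) -> PatchMatrix:
    """Extract every stride-1 r x r patch of a 2D image.

    The patch anchored at pixel (i, j) covers image[i:i+r, j:j+r], with
    out-of-range indices wrapped (periodic) or reflected (symmetric), and is
    flattened in C order — the same order used to flatten filters, so that
    ``A^H @ G`` reproduces the analysis subbands exactly under periodic
    boundary.

    ``max_patches`` optionally subsamples columns uniformly (seeded); the
    default keeps all N = H*W patches.
    """
    image = np.asarray(image, dtype=np.complex128)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    h, w = image.shape
    if r > h or r > w:
        raise ValueError(f"patch size {r} exceeds image shape {image.shape}")
    mode = {"periodic": "wrap", "symmetric": "symmetric"}[boundary]
    padded = np.pad(image, ((0, r - 1), (0, r - 1)), mode=mode)
    windows = sliding_window_view(padded, (r, r))  # (h, w, r, r)
    G = windows.reshape(h * w, r * r).T
    if max_patches is not None and max_patches < G.shape[1]:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(G.shape[1], size=max_patches, replace=False))
        G = G[:, cols]
    else:
        G = np.ascontiguousarray(G)
    return PatchMatrix(G, source_shape=(h, w), boundary=boundary)


def filter_update(
    patches: PatchMatrix,
    target_coeffs: np.ndarray,
    boundary: str | None = None,
    rank_tol: float = 1e-12,
) -> FilterBank:
    """Closed-form Procrustes solution of the filter subproblem.

    Minimizes ``||A^H G - C||_F`` over A with A A^H = (1/r**2) I, where G is
    the patch matrix and C the target coefficients (shape r**2 x N, row i =
    flattened target subband i).  Solution: with G C^H = U S X^H a full SVD,
    A = (1/r) U X^H.  The returned bank satisfies the UEP constraint to
    machine precision by construction.

    A rank-deficient G C^H makes the minimizer non-unique; the deterministic
    SVD branch is returned and a warning is logged.
    """
    C = np.asarray(target_coeffs, dtype=np.complex128)
    G = patches.data
    if C.shape != G.shape:
        raise ValueError(
            f"target_coeffs shape {C.shape} does not match patches {G.shape}"
        )
    n = G.shape[0]
    r = patches.r
    if n != r * r:
        raise ValueError("patch rows must equal r**2")
    M = G @ C.conj().T
    U, s, Xh = np.linalg.svd(M)
    if s.size and s.min() <= rank_tol * max(s.max(), 1.0):
        logger.warning(
            "filter_update: G @ C^H is (near) rank-deficient "
            "(min singular value %.3e); solution is the deterministic SVD branch",
            float(s.min()) if s.size else 0.0,
        )
    A = (U @ Xh) / r
    return FilterBank.from_flattened(
        A, boundary=boundary or patches.boundary
    )


def procrustes_objective(bank: FilterBank, patches: PatchMatrix, C: np.ndarray) -> float:
    """The fitted objective ||A^H G - C||_F, for diagnostics and tests."""
    A = bank.flattened()
    return float(np.linalg.norm(A.conj().T @ patches.data - C))
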