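"""Undecimated tight-frame analysis/synthesis from an r x r filter bank.

A bank of r**2 complex filters of size r x r defines an analysis operator W
that maps an image to r**2 subband images (one per filter, same size as the
image) and a synthesis operator W^H mapping subbands back.  The bank is a
tight frame (W^H W = I, perfect reconstruction) exactly when the flattened
filters, stacked as the columns of an r**2 x r**2 matrix A, satisfy the
Unitary Extension Principle in matrix form::

    A @ A.conj().T == (1 / r**2) * I

Analysis of subband i is the correlation of the image with the conjugate of
filter a_i; synthesis is the exact adjoint.  With periodic boundary handling
the tight-frame identity holds exactly on the whole image; with symmetric
(reflective) boundary handling analysis/synthesis remain exact adjoints but
W^H W deviates from the identity near the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BOUNDARY_MODES = ("periodic", "symmetric")


@dataclass
class FilterBank:
    """An r x r filter bank defining an undecimated frame.

    Parameters
    ----------
    filters : ndarray, shape (r**2, r, r), complex
        The kernels, in a fixed scanning order (see :func:`haar_init`).
    boundary : {"periodic", "symmetric"}
        How image borders are handled by analysis/synthesis.
    """

    filters: np.ndarray
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=np.complex128)
        if self.filters.ndim != 3:
            raise ValueError("filters must have shape (r**2, r, r)")
        n, h, w = self.filters.shape
        if h != w or n != h * w:
            raise ValueError(
                f"expected r**2 filters of size r x r, got {n} of {h}x{w}"
            )
        if self.boundary not in BOUNDARY_MODES:
            raise ValueError(f"boundary must be one of {BOUNDARY_MODES}")

    @property
    def r(self) -> int:
        return self.filters.shape[1]

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    def flattened(self) -> np.ndarray:
        """Matrix A of shape (r**2, r**2) whose i-th column is filter i, C-flattened."""
        n = self.n_filters
        return self.filters.reshape(n, n).T.copy()

    @classmethod
    def from_flattened(cls, A: np.ndarray, boundary: str = "periodic") -> "FilterBank":
        A = np.asarray(A, dtype=np.complex128)
        n = A.shape[1]
        r = int(round(np.sqrt(n)))
        return cls(A.T.reshape(n, r, r), boundary=boundary)


@dataclass
class FrameCoefficients:
    """Stack of r**2 subband images produced by :func:`analysis`."""

    subbands: np.ndarray  # shape (r**2, H, W), complex
    source_shape: tuple = field(default=None)

    def __post_init__(self) -> None:
        self.subbands = np.asarray(self.subbands, dtype=np.complex128)
        if self.subbands.ndim != 3:
            raise ValueError("subbands must have shape (n_filters, H, W)")
        if self.source_shape is None:
            self.source_shape = self.subbands.shape[1:]
        self.source_shape = tuple(self.source_shape)

    @property
    def n_subbands(self) -> int:
        return self.subbands.shape[0]


def _haar_matrix(r: int) -> np.ndarray:
    """Orthonormal multi-level (log2 r levels) 1D Haar matrix of size r x r."""
    if r == 1:
        return np.array([[1.0]])
    h = _haar_matrix(r // 2)
    lo = np.kron(h, np.array([1.0, 1.0])) / np.sqrt(2.0)
    hi = np.kron(np.eye(r // 2), np.array([1.0, -1.0])) / np.sqrt(2.0)
    return np.vstack([lo, hi])


def haar_init(r: int = 8, boundary: str = "periodic") -> FilterBank:
    """Multi-level shift-invariant 2D Haar initialization.

    Returns the full log2(r)-level orthonormal 2D Haar basis on r x r blocks
    (r**2 separable filters, outer products of the rows of the 1D multi-level
    Haar matrix), globally rescaled by 1/r so that A @ A^H = (1/r**2) I holds
    exactly.  The default r = 8 gives the 3-level 8x8 bank.

    The subband order is row-major over (vertical, horizontal) 1D Haar row
    indices: filter i*r + j is outer(h_i, h_j)/r, with h_0 the coarsest
    scaling row and increasing j/i moving to finer detail rows.
    """
    if r < 1 or (r & (r - 1)) != 0:
        raise ValueError(f"r must be a positive power of 2, got {r}")
    H = _haar_matrix(r)
    filters = np.einsum("ip,jq->ijpq", H, H).reshape(r * r, r, r) / r
    return FilterBank(filters.astype(np.complex128), boundary=boundary)


def _check_image(image: np.ndarray, r: int) -> np.ndarray:
    image = np.asarray(image, dtype=np.complex128)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if image.size == 0 or min(image.shape) < r:
        raise ValueError(
            f"image must be at least {r}x{r}, got {image.shape}"
        )
    return image


def _kernel_ffts(bank: FilterBank, shape: tuple) -> np.ndarray:
    """FFTs of the kernels zero-embedded at the top-left corner of `shape`."""
    n = bank.n_filters
    r = bank.r
    kernels = np.zeros((n,) + tuple(shape), dtype=np.complex128)
    kernels[:, :r, :r] = bank.filters
    return np.fft.fft2(kernels, axes=(-2, -1))


def _pad_symmetric(image: np.ndarray, r: int) -> np.ndarray:
    return np.pad(image, ((0, r - 1), (0, r - 1)), mode="symmetric")


def _fold_symmetric(padded: np.ndarray, shape: tuple, r: int) -> np.ndarray:
    """Adjoint of `_pad_symmetric`: fold reflected border mass back in."""
    h, w = shape
    out = padded[:h].copy()
    for j in range(r - 1):  # rows h+j reflected from row h-1-j
        out[h - 1 - j] += padded[h + j]
    res = out[:, :w].copy()
    for j in range(r - 1):
        res[:, w - 1 - j] += out[:, w + j]
    return res


def analysis(bank: FilterBank, image: np.ndarray) -> FrameCoefficients:
    """Apply the analysis operator W.

    Subband i at pixel n is the inner product of filter a_i with the r x r
    patch anchored at n: sum_p conj(a_i[p]) * x[n + p], with out-of-range
    indices wrapped (periodic) or reflected (symmetric).
    """
    image = _check_image(image, bank.r)
    if bank.boundary == "periodic":
        khat = _kernel_ffts(bank, image.shape)
        xhat = np.fft.fft2(image)
        sub = np.fft.ifft2(xhat[None] * np.conj(khat), axes=(-2, -1))
    else:
        padded = _pad_symmetric(image, bank.r)
        from numpy.lib.stride_tricks import sliding_window_view

        windows = sliding_window_view(padded, (bank.r, bank.r))
        G = windows.reshape(image.shape[0] * image.shape[1], bank.r * bank.r).T
        sub = (bank.flattened().conj().T @ G).reshape(
            bank.n_filters, *image.shape
        )
    return FrameCoefficients(sub, source_shape=image.shape)


def synthesis(bank: FilterBank, coeffs: FrameCoefficients) -> np.ndarray:
    """Apply the synthesis operator W^H (exact adjoint of :func:`analysis`).

    For a bank passing :func:`verify_uep` under periodic boundary,
    ``synthesis(bank, analysis(bank, x)) == x`` to machine precision.
    """
    if coeffs.n_subbands != bank.n_filters:
        raise ValueError(
            f"coefficient stack has {coeffs.n_subbands} subbands, "
            f"bank has {bank.n_filters} filters"
        )
    shape = coeffs.source_shape
    if bank.boundary == "periodic":
        khat = _kernel_ffts(bank, shape)
        vhat = np.fft.fft2(coeffs.subbands, axes=(-2, -1))
        return np.fft.ifft2((vhat * khat).sum(axis=0))
    r = bank.r
    h, w = shape
    acc = np.zeros((h + r - 1, w + r - 1), dtype=np.complex128)
    for i in range(bank.n_filters):
        a = bank.filters[i]
        v = coeffs.subbands[i]
        for p in range(r):
            for q in range(r):
                acc[p : p + h, q : q + w] += a[p, q] * v
    return _fold_symmetric(acc, shape, r)


def verify_uep(bank: FilterBank, tol: float = 1e-8):
    """Check the UEP/tightness condition A @ A^H = (1/r**2) I.

    Returns ``(ok, max_deviation)`` where max_deviation is the largest
    absolute entry of A @ A^H - (1/r**2) I.
    """
    A = bank.flattened()
    n = bank.n_filters
    dev = A @ A.conj().T - np.eye(n) / n
    max_dev = float(np.abs(dev).max())
    return max_dev < tol, max_dev


def save_filter_bank(path, bank: FilterBank) -> None:
    """Serialize a bank to a single .npz container."""
    np.savez(path, filters=bank.filters, boundary=np.asarray(bank.boundary))


def load_filter_bank(path) -> FilterBank:
    with np.load(path) as data:
        return FilterBank(data["filters"], boundary=str(data["boundary"]))


def filter_mosaic(bank: FilterBank) -> np.ndarray:
    """Render the bank as an r x r grid of magnitude tiles (uint8 image).

    Each tile is one filter, independently contrast-stretched; tiles are
    separated by 1-pixel black gridlines.
    """
    r = bank.r
    tile = r
    size = r * (tile + 1) + 1
    mosaic = np.zeros((size, size), dtype=np.uint8)
    for i in range(bank.n_filters):
        a = np.abs(bank.filters[i])
        rng = a.max() - a.min()
        img = (a - a.min()) / rng if rng > 0 else np.zeros_like(a)
        row, col = divmod(i, r)
        y, x = 1 + row * (tile + 1), 1 + col * (tile + 1)
        mosaic[y : y + tile, x : x + tile] = np.round(255 * img).astype(np.uint8)
    return mosaic
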