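"""Fourier undersampling: the measurement model f = P F x + noise.

F is the unitary, centered 2D discrete Fourier transform (DC at the grid
center), P keeps only the k-space locations flagged by a sampling mask, and
the noise is complex white Gaussian with standard deviation sigma per complex
sample (sigma/sqrt(2) per real/imaginary component), added at sampled
locations only.

Mask generators cover the three retrospective undersampling schemes used in
undersampled-MRI experiments: variable-density 1D Cartesian (full rows),
variable-density 2D random (pointwise), and pseudo-radial (straight spokes
through the k-space center on the Cartesian grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCHEMES = ("cartesian1d", "random2d", "radial")

# Variable-density profile for cartesian1d/random2d: Gaussian with this scale
# (fraction of the grid size) and a fully sampled central band of this
# fraction of lines.  Published masks of this family are shown only as
# figures, never as numbers; these are configurable module defaults.
DENSITY_SCALE = 0.25
CENTER_FRACTION = 0.04


@dataclass
class SamplingMask:
    """Boolean k-space mask (True = sampled) with its generating scheme."""

    mask: np.ndarray
    scheme: str
    acceleration: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def sampling_ratio(self) -> float:
        return float(self.mask.sum()) / self.mask.size


@dataclass
class KSpaceSample:
    """Measured k-space on the full grid (zero at unsampled locations)."""

    f: np.ndarray
    mask: SamplingMask
    sigma: float = 0.0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.complex128)
        if self.f.shape != self.mask.mask.shape:
            raise ValueError("f and mask shapes differ")
        # enforce the invariant: nothing stored off the sampled set
        self.f = np.where(self.mask.mask, self.f, 0.0)


def fft2c(image: np.ndarray) -> np.ndarray:
    """Unitary centered 2D DFT (DC at (n//2, n//2))."""
    return np.fft.fftshift(np.fft.fft2(np.asarray(image), norm="ortho"))


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (also unitary)."""
    return np.fft.ifft2(np.fft.ifftshift(np.asarray(kspace)), norm="ortho")


def forward(image: np.ndarray, mask: SamplingMask) -> KSpaceSample:
    """Noiseless measurement P F x."""
    image = np.asarray(image, dtype=np.complex128)
    if image.shape != mask.mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {mask.mask.shape}"
        )
    return KSpaceSample(fft2c(image) * mask.mask, mask, sigma=0.0)


def adjoint(sample: KSpaceSample) -> np.ndarray:
    """Zero-filled reconstruction F^H P^H f."""
    return ifft2c(sample.f)


def add_noise(sample: KSpaceSample, sigma: float, seed: int) -> KSpaceSample:
    """Add complex white Gaussian noise (std sigma) at sampled locations."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return KSpaceSample(sample.f.copy(), sample.mask, sigma=0.0)
    rng = np.random.default_rng(seed)
    shape = sample.f.shape
    noise = (sigma / np.sqrt(2.0)) * (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )
    f = sample.f + noise * sample.mask.mask
    return KSpaceSample(f, sample.mask, sigma=sigma)


def _center_weights(n: int) -> np.ndarray:
    c = n // 2
    d = np.arange(n) - c
    return np.exp(-0.5 * (d / (DENSITY_SCALE * n)) ** 2)


def _cartesian1d(shape, R, rng) -> np.ndarray:
    h, w = shape
    n_rows = int(round(h / R))
    if n_rows < 1:
        raise ValueError(f"R={R} implies fewer than one sampled row")
    c = h // 2
    band = max(1, int(round(CENTER_FRACTION * h)))
    lo = c - band // 2
    center_rows = np.arange(lo, lo + band) % h
    rows = set(center_rows.tolist())
    weights = _center_weights(h)
    weights[list(rows)] = 0.0
    n_extra = max(0, n_rows - len(rows))
    if n_extra > 0:
        p = weights / weights.sum()
        extra = rng.choice(h, size=n_extra, replace=False, p=p)
        rows.update(extra.tolist())
    mask = np.zeros(shape, dtype=bool)
    mask[sorted(rows), :] = True
    return mask


def _random2d(shape, R, rng) -> np.ndarray:
    h, w = shape
    n_pts = int(round(h * w / R))
    if n_pts < 1:
        raise ValueError(f"R={R} implies fewer than one sampled point")
    cy, cx = h // 2, w // 2
    band = max(1, int(round(CENTER_FRACTION * min(h, w))))
    y0, x0 = cy - band // 2, cx - band // 2
    mask = np.zeros(shape, dtype=bool)
    mask[y0 : y0 + band, x0 : x0 + band] = True
    weights = np.outer(_center_weights(h), _center_weights(w))
    weights[mask] = 0.0
    n_extra = n_pts - int(mask.sum())
    if n_extra > 0:
        p = (weights / weights.sum()).ravel()
        idx = rng.choice(h * w, size=n_extra, replace=False, p=p)
        mask.ravel()[idx] = True
    return mask


def _radial_mask_for_spokes(shape, n_spokes: int) -> np.ndarray:
    """Straight diameters through the DC pixel, 180-degree symmetric.

    Each spoke is drawn as a half-line from the center and completed by its
    point reflection i -> (2c - i) mod n, which makes the mask exactly
    symmetric under 180-degree rotation about the k-space center.
    """
    h, w = shape
    cy, cx = h // 2, w // 2
    mask = np.zeros(shape, dtype=bool)
    angles = np.pi * np.arange(n_spokes) / n_spokes
    t = np.arange(0, int(np.ceil(np.hypot(h, w) / 2)) + 1)
    for theta in angles:
        dy, dx = np.sin(theta), np.cos(theta)
        ys = np.round(cy + t * dy).astype(int)
        xs = np.round(cx + t * dx).astype(int)
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        ys, xs = ys[keep], xs[keep]
        mask[ys, xs] = True
        mask[(2 * cy - ys) % h, (2 * cx - xs) % w] = True
    return mask


def _radial(shape, R, rng) -> np.ndarray:
    target = 1.0 / R
    best = None
    # sampling ratio is monotone in spoke count; scan for the closest hit
    max_spokes = max(shape)
    lo, hi = 1, max_spokes
    counts = {}

    def ratio(k):
        if k not in counts:
            counts[k] = _radial_mask_for_spokes(shape, k)
        return counts[k].sum() / counts[k].size

    while lo < hi:
        mid = (lo + hi) // 2
        if ratio(mid) < target:
            lo = mid + 1
        else:
            hi = mid
    candidates = [k for k in (lo - 1, lo) if 1 <= k <= max_spokes]
    best = min(candidates, key=lambda k: abs(ratio(k) - target))
    if ratio(best) <= 0:
        raise ValueError(f"R={R} implies fewer than one spoke")
    return counts[best]


def make_mask(shape, scheme: str, R: float, seed: int = 0) -> SamplingMask:
    """Generate a sampling mask hitting ratio ~ 1/R for the given scheme.

    All schemes include the DC (grid-center) sample; cartesian1d and random2d
    are variable-density (center-weighted Gaussian) with a fully sampled
    central band, radial is deterministic given the spoke count.
    """
    if R <= 1:
        raise ValueError("acceleration factor R must exceed 1")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    shape = tuple(shape)
    rng = np.random.default_rng(seed)
    if scheme == "cartesian1d":
        mask = _cartesian1d(shape, R, rng)
    elif scheme == "random2d":
        mask = _random2d(shape, R, rng)
    else:
        mask = _radial(shape, R, rng)
    mask[shape[0] // 2, shape[1] // 2] = True
    return SamplingMask(mask, scheme, float(R))
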