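"""Synthetic complex-valued ground-truth images and experiment assembly.

The reconstruction experiments need fully sampled ground truths to
retrospectively undersample.  Two generators are provided: the analytic
Shepp-Logan ellipse phantom (modified, high-contrast intensity table) and a
seeded piecewise-texture phantom (Voronoi regions with sharp edges plus
band-limited texture) emulating images with fine-detailed structure.

Magnitudes live in [0, 255] so the 8-bit PSNR convention applies directly.
Phantoms are complex by default: a smooth low-order polynomial phase of
configurable amplitude multiplies the magnitude, exercising solvers on
complex data the way in-vivo scans do.  Every generator is a pure function
of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .sampling import KSpaceSample, SamplingMask, add_noise, forward, make_mask

# Modified Shepp-Logan ellipses: (intensity, a, b, x0, y0, phi_degrees)
# on the [-1, 1]^2 square; intensities are cumulative (overlapping ellipses add).
SHEPP_LOGAN_ELLIPSES = (
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.874, 0.0, -0.0184, 0.0),
    (-0.2, 0.11, 0.31, 0.22, 0.0, -18.0),
    (-0.2, 0.16, 0.41, -0.22, 0.0, 18.0),
    (0.1, 0.21, 0.25, 0.0, 0.35, 0.0),
    (0.1, 0.046, 0.046, 0.0, 0.1, 0.0),
    (0.1, 0.046, 0.046, 0.0, -0.1, 0.0),
    (0.1, 0.046, 0.023, -0.08, -0.605, 0.0),
    (0.1, 0.023, 0.023, 0.0, -0.606, 0.0),
    (0.1, 0.023, 0.046, 0.06, -0.605, 0.0),
)


@dataclass
class Phantom:
    """A complex ground-truth image with magnitude in [0, 255]."""

    image: np.ndarray
    kind: str
    seed: int


def ellipse_membership(points: np.ndarray, ellipse) -> np.ndarray:
    """Boolean membership of (x, y) points in one table ellipse."""
    _, a, b, x0, y0, phi_deg = ellipse
    phi = np.deg2rad(phi_deg)
    x = points[..., 0] - x0
    y = points[..., 1] - y0
    u = x * np.cos(phi) + y * np.sin(phi)
    v = -x * np.sin(phi) + y * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _polynomial_phase(n: int, amplitude: float, rng) -> np.ndarray:
    """Smooth random quadratic phase map with max |phase| = amplitude (rad)."""
    coords = np.linspace(-1.0, 1.0, n)
    x, y = np.meshgrid(coords, coords, indexing="xy")
    c = rng.uniform(-1.0, 1.0, size=6)
    phase = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x**2 + c[5] * y**2
    peak = np.abs(phase).max()
    if peak > 0:
        phase = phase / peak * amplitude
    return phase


def shepp_logan(n: int = 256, phase_amplitude: float = 0.5, seed: int = 0) -> Phantom:
    """Analytic modified Shepp-Logan phantom at n x n, magnitude in [0, 255].

    Each pixel gets the cumulative intensity of the ellipses containing its
    center; the result is rescaled so the maximum magnitude is 255, then
    multiplied by exp(1j * phase) with a smooth seeded quadratic phase of the
    given peak amplitude in radians (0 gives a purely real image).
    """
    if n < 32:
        raise ValueError(f"n must be at least 32, got {n}")
    coords = np.linspace(-1.0, 1.0, n)
    x, y = np.meshgrid(coords, -coords, indexing="xy")  # row 0 = top (y=+1)
    pts = np.stack([x, y], axis=-1)
    img = np.zeros((n, n))
    for ell in SHEPP_LOGAN_ELLIPSES:
        img += ell[0] * ellipse_membership(pts, ell)
    img = np.clip(img, 0.0, None)
    img *= 255.0 / img.max()
    rng = np.random.default_rng(seed)
    phase = _polynomial_phase(n, phase_amplitude, rng)
    return Phantom(img * np.exp(1j * phase), kind="shepp_logan", seed=seed)


def piecewise_texture(
    n: int = 256,
    n_regions: int = 12,
    texture_scale: float = 10.0,
    phase_amplitude: float = 0.5,
    seed: int = 0,
) -> Phantom:
    """Voronoi partition with per-region levels plus band-limited texture.

    Regions have sharp edges (for edge-preservation checks); texture is
    Gaussian-low-pass-filtered white noise of standard deviation
    ``texture_scale`` added inside regions (0 gives a piecewise-constant
    image).  Magnitude is kept in [0, 255].
    """
    if n < 64:
        raise ValueError(f"n must be at least 64, got {n}")
    if n_regions < 2:
        raise ValueError("n_regions must be at least 2")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n, 0:n]
    grid = np.column_stack([yy.ravel(), xx.ravel()])
    for _ in range(100):
        sites = rng.uniform(0, n, size=(n_regions, 2))
        labels = cKDTree(sites).query(grid)[1].reshape(n, n)
        if len(np.unique(labels)) == n_regions:
            break
    else:  # pragma: no cover - vanishingly unlikely for n >= 64
        raise RuntimeError("could not seat all Voronoi regions")
    levels = rng.uniform(40.0, 230.0, size=n_regions)
    img = levels[labels]
    if texture_scale > 0:
        noise = gaussian_filter(rng.standard_normal((n, n)), sigma=2.0)
        noise *= texture_scale / noise.std()
        img = img + noise
    img = np.clip(img, 0.0, 255.0)
    phase = _polynomial_phase(n, phase_amplitude, rng)
    return Phantom(img * np.exp(1j * phase), kind="piecewise_texture", seed=seed)


def make_experiment(
    phantom: Phantom,
    scheme: str,
    R: float,
    sigma: float = 0.0,
    seed: int = 0,
):
    """Compose mask generation, Fourier undersampling, and noise.

    Returns ``(ground_truth, KSpaceSample)``.  ``scheme="full"`` keeps every
    k-space sample (the R argument is then ignored), which is useful as a
    sanity baseline.  Mask and noise randomness both derive from ``seed``.
    """
    image = phantom.image
    rng = np.random.default_rng(seed)
    mask_seed, noise_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    if scheme == "full":
        mask = SamplingMask(np.ones(image.shape, dtype=bool), "full", 1.0)
    else:
        mask = make_mask(image.shape, scheme, R, seed=mask_seed)
    sample = forward(image, mask)
    if sigma > 0:
        sample = add_noise(sample, sigma, seed=noise_seed)
    return image, sample
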