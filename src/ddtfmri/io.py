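"""On-disk containers and image export.

Complex images, k-space samples, masks and filter banks are stored as NumPy
``.npz`` containers (a single file carrying shape + dtype headers), which
round-trip losslessly.  PNG export of magnitudes is provided for inspection
and is explicitly lossy (8-bit quantization of the magnitude only).
"""

from __future__ import annotations

import hashlib
import os
import zipfile

import numpy as np
from PIL import Image

from .frames import FilterBank
from .sampling import KSpaceSample, SamplingMask


class ContainerError(IOError):
    """A container file failed to parse."""


def _load_npz(path, required_keys):
    try:
        data = np.load(path, allow_pickle=False)
    except (zipfile.BadZipFile, ValueError, OSError) as exc:
        size = os.path.getsize(path) if os.path.exists(path) else 0
        raise ContainerError(
            f"{path}: corrupt or truncated container "
            f"(parse failed at or before byte offset {size}): {exc}"
        ) from exc
    missing = [k for k in required_keys if k not in data]
    if missing:
        data.close()
        raise ContainerError(f"{path}: missing keys {missing}")
    return data


def save_image(path, image: np.ndarray) -> None:
    np.savez(path, image=np.asarray(image, dtype=np.complex128))


def load_image(path) -> np.ndarray:
    with _load_npz(path, ["image"]) as data:
        return np.asarray(data["image"])


def save_mask(path, mask: SamplingMask) -> None:
    np.savez(
        path,
        mask=mask.mask,
        scheme=np.asarray(mask.scheme),
        acceleration=np.asarray(mask.acceleration),
    )


def load_mask(path) -> SamplingMask:
    with _load_npz(path, ["mask", "scheme", "acceleration"]) as data:
        return SamplingMask(
            data["mask"], str(data["scheme"]), float(data["acceleration"])
        )


def save_kspace(path, sample: KSpaceSample) -> None:
    np.savez(
        path,
        f=sample.f,
        mask=sample.mask.mask,
        scheme=np.asarray(sample.mask.scheme),
        acceleration=np.asarray(sample.mask.acceleration),
        sigma=np.asarray(sample.sigma),
    )


def load_kspace(path) -> KSpaceSample:
    with _load_npz(path, ["f", "mask", "scheme", "acceleration", "sigma"]) as d:
        mask = SamplingMask(d["mask"], str(d["scheme"]), float(d["acceleration"]))
        return KSpaceSample(d["f"], mask, sigma=float(d["sigma"]))


def export_magnitude_png(path, image: np.ndarray, vmax: float | None = None) -> None:
    """Lossy 8-bit export of the magnitude image."""
    mag = np.abs(np.asarray(image))
    peak = vmax if vmax is not None else (mag.max() or 1.0)
    arr = np.clip(mag / peak * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def export_mask_png(path, mask: SamplingMask) -> None:
    arr = (mask.mask.astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def import_mask_png(path, scheme: str = "unknown", acceleration: float = 0.0) -> SamplingMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return SamplingMask(arr > 127, scheme, acceleration)


def export_gray_png(path, arr: np.ndarray) -> None:
    """Export an arbitrary nonnegative array contrast-stretched to 8 bits."""
    a = np.asarray(arr, dtype=float)
    peak = a.max() or 1.0
    Image.fromarray(
        np.clip(a / peak * 255.0, 0, 255).astype(np.uint8), mode="L"
    ).save(path, format="PNG")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
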