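"""Raster I/O and synthetic co-registered phantom pairs.

The phantom generator produces a CT-like image (bright elliptical
"bone" ring, flat interior) and an MRI-like image (dark ring, textured
soft tissue) of the same scene, so the whole fusion pipeline can be
exercised without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .image import RANGE_LIMITS, GrayImage

# Rec.601 luminance weights for RGB -> gray
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path: str | Path) -> GrayImage:
    """Read an 8- or 16-bit PNG/TIFF as a raw8 grayscale image.

    RGB(A) input is converted to luminance with Rec.601 weights; 16-bit
    input is rescaled to [0, 255].
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises assorted types on corrupt files
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {arr.ndim}")
    arr = arr.astype(np.float64)
    if arr.max() > 255.0:  # 16-bit input
        arr = arr * (255.0 / 65535.0)
    return GrayImage(np.clip(arr, 0.0, 255.0), "raw8")


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write as an 8-bit single-channel PNG/TIFF.

    Unit-range images are scaled by 255 and rounded half-up.
    """
    px = img.pixels
    if img.range_tag == "unit":
        px = px * 255.0
    # round-half-up so 127.5 -> 128
    data = np.clip(np.floor(px + 0.5), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic co-registered CT-like / MRI-like pair."""

    size: tuple[int, int] = (256, 256)
    seed: int = 0
    noise_sigma: float = 0.02  # additive Gaussian noise std on the unit scale
    bone_intensity: float = 0.95
    tissue_contrast: float = 0.6

    def __post_init__(self) -> None:
        if len(self.size) != 2 or min(self.size) < 32:
            raise ValidationError(f"size components must be >= 32, got {self.size}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        for name in ("bone_intensity", "tissue_contrast"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")


def generate_phantom_pair(spec: PhantomSpec) -> tuple[GrayImage, GrayImage]:
    """Generate a deterministic (CT-like, MRI-like) raw8 pair.

    Geometry is two concentric ellipses; the annulus between them is the
    "skull". The MRI interior texture is band-limited noise (white noise
    blurred with a 4 px Gaussian) so gradient-based salience finds real
    structure.
    """
    m, n = spec.size
    rng = np.random.default_rng(spec.seed)

    yy = (np.arange(m) - (m - 1) / 2.0) / (m / 2.0)
    xx = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    rho_outer = (X / 0.80) ** 2 + (Y / 0.90) ** 2
    rho_inner = (X / (0.80 * 0.84)) ** 2 + (Y / (0.90 * 0.84)) ** 2
    outer = rho_outer <= 1.0
    inner = rho_inner <= 1.0
    ring = outer & ~inner

    texture = rng.standard_normal((m, n))
    texture = gaussian_filter(texture, sigma=4.0, mode="reflect")
    tstd = texture.std()
    if tstd > 0:
        texture = texture / tstd

    ct = np.full((m, n), 0.10)
    ct[inner] = 0.32 + 0.06 * (1.0 - rho_inner[inner])  # near-flat soft tissue
    ct[ring] = spec.bone_intensity

    mri = np.full((m, n), 0.06)
    mri[ring] = 0.10  # bone is dark on MRI
    mri[inner] = np.clip(
        0.50 + 0.28 * spec.tissue_contrast * texture[inner], 0.0, 1.0
    )

    out = []
    for base in (ct, mri):
        img = base * 255.0
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma * 255.0, size=(m, n))
        out.append(GrayImage(np.clip(img, 0.0, 255.0), "raw8"))
    return out[0], out[1]


def add_noise(img: GrayImage, sigma: float, seed: int) -> GrayImage:
    """Add i.i.d. Gaussian noise of std ``sigma`` (image units), clipped
    to the declared range. Deterministic given ``seed``."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return img
    rng = np.random.default_rng(seed)
    lo, hi = RANGE_LIMITS[img.range_tag]
    noisy = img.pixels + rng.normal(0.0, sigma, size=img.shape)
    return GrayImage(np.clip(noisy, lo, hi), img.range_tag)
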