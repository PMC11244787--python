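"""Grayscale image container shared by every pipeline stage.

An image is a 2-D float array plus an explicit range tag so that
raw 8-bit intensities ([0, 255]) and normalized intensities ([0, 1])
cannot be mixed up silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: Allowed value ranges per tag.
RANGE_LIMITS: dict[str, tuple[float, float]] = {
    "raw8": (0.0, 255.0),
    "unit": (0.0, 1.0),
}

# slack for accumulated float error, not for genuinely out-of-range data
_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class GrayImage:
    """A two-dimensional grid of intensities with a declared value range.

    Parameters
    ----------
    pixels
        2-D array of intensities (any real dtype; stored as float64,
        read-only).
    range_tag
        Either ``"raw8"`` (values in [0, 255]) or ``"unit"`` (values in
        [0, 1]).
    """

    pixels: np.ndarray
    range_tag: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"image must be 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError(f"image must be at least 2x2, got {arr.shape}")
        if self.range_tag not in RANGE_LIMITS:
            raise ValidationError(
                f"unknown range_tag {self.range_tag!r}; expected one of "
                f"{sorted(RANGE_LIMITS)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("image contains non-finite pixels")
        lo, hi = RANGE_LIMITS[self.range_tag]
        if arr.min() < lo - _RANGE_TOL or arr.max() > hi + _RANGE_TOL:
            raise ValidationError(
                f"pixels outside declared range {self.range_tag} "
                f"[{lo}, {hi}]: observed [{arr.min()}, {arr.max()}]"
            )
        arr = np.clip(arr, lo, hi)
        arr.flags.writeable = False
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def same_shape(self, other: "GrayImage") -> bool:
        return self.shape == other.shape


def require_same_shape(a: GrayImage | np.ndarray, b: GrayImage | np.ndarray) -> None:
    """Raise :class:`ValidationError` unless the two grids share a shape."""
    sa = a.shape if isinstance(a, np.ndarray) else a.pixels.shape
    sb = b.shape if isinstance(b, np.ndarray) else b.pixels.shape
    if sa != sb:
        raise ValidationError(f"shape mismatch: {sa} vs {sb}")
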