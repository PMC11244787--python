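"""Intensity normalization and the adaptive local Wiener filter.

The filter shrinks each pixel toward its local window mean by a factor
``k = var / (var + lam)``: flat (low-variance) neighbourhoods are
averaged away while high-variance structure is kept nearly intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import ValidationError
from .image import GrayImage


@dataclass(frozen=True)
class WienerParams:
    """Window half-width and shrinkage regularizer of the local Wiener filter."""

    radius: int = 3
    lam: float = 0.01

    def __post_init__(self) -> None:
        if self.radius < 1 or int(self.radius) != self.radius:
            raise ValidationError(f"radius must be an integer >= 1, got {self.radius}")
        if self.lam < 0:
            raise ValidationError(f"lam must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class LocalStats:
    """Per-pixel mean and population variance over a square window."""

    mean_map: np.ndarray
    var_map: np.ndarray


def normalize(S: GrayImage) -> GrayImage:
    """Rescale a raw8 image to [0, 1] by dividing by 255."""
    if S.range_tag != "raw8":
        raise ValidationError("input already normalized (range_tag must be raw8)")
    return GrayImage(S.pixels / 255.0, "unit")


def local_stats(G: GrayImage | np.ndarray, radius: int) -> LocalStats:
    """Local mean and population variance over a (2*radius+1)^2 window.

    Edges use replicate padding; computed with separable box sums so the
    per-pixel cost is independent of the radius.
    """
    if radius < 1 or int(radius) != radius:
        raise ValidationError(f"radius must be an integer >= 1, got {radius}")
    px = G.pixels if isinstance(G, GrayImage) else np.asarray(G, dtype=np.float64)
    size = 2 * int(radius) + 1
    mean = uniform_filter(px, size=size, mode="nearest")
    mean_sq = uniform_filter(px * px, size=size, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return LocalStats(mean_map=mean, var_map=var)


def wiener_filter(G: GrayImage, params: WienerParams = WienerParams()) -> GrayImage:
    """Adaptive local Wiener filtering of a unit-range image.

    Output is ``mean + k * (G - mean)`` with ``k = var / (var + lam)``;
    since k is in [0, 1] the result lies between the local mean and the
    input, hence within [0, 1] up to float error.
    """
    if G.range_tag != "unit":
        raise ValidationError("wiener_filter expects a unit-range image")
    stats = local_stats(G, params.radius)
    if params.lam == 0.0:
        # k == 1 wherever var > 0 and the var == 0 limit is the identity too
        return GrayImage(G.pixels.copy(), "unit")
    k = stats.var_map / (stats.var_map + params.lam)
    out = stats.mean_map + k * (G.pixels - stats.mean_map)
    return GrayImage(np.clip(out, 0.0, 1.0), "unit")
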