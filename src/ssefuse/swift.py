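"""Swift contrast algorithm: log compression, statistical adjustment
factors, a nonlinear tone map, and dynamic-range regularisation.

Stages
------
1. ``u = ln(1 + G)`` compresses intensities into [0, ln 2].
2. ``sigma`` — the corrected (n-1) sample standard deviation of u — and
   ``eta = u**lam / lam!`` act as global/local adjustment factors.
3. A nonlinear exponential tone map combines them.
4. A min-max rescale restores the full [0, 1] dynamic range.

The tone map's printed form is typographically ambiguous, so two parses
are offered (``parse_mode``): ``fraction`` (default),
``f = exp((tan u - sigma) / (gamma * (exp u - eta)))``, and ``literal``,
``f = exp(tan u - sigma * exp(u) - eta) ** gamma``.  Both are monotone
in u over the reachable range, and the final rescale makes them nearly
equivalent in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import NumericError, ValidationError
from .image import GrayImage

PARSE_MODES = ("fraction", "literal")


@dataclass(frozen=True)
class SwiftParams:
    lambda_tune: int = 3
    gamma: float = 1.0
    parse_mode: str = "fraction"

    def __post_init__(self) -> None:
        if int(self.lambda_tune) != self.lambda_tune or self.lambda_tune < 1:
            raise ValidationError(
                f"lambda_tune must be a positive integer, got {self.lambda_tune}"
            )
        if not self.gamma > 0:
            raise ValidationError(f"gamma must be > 0, got {self.gamma}")
        if self.parse_mode not in PARSE_MODES:
            raise ValidationError(
                f"parse_mode must be one of {PARSE_MODES}, got {self.parse_mode!r}"
            )


@dataclass(frozen=True)
class SwiftIntermediates:
    """Every intermediate of the enhancement chain, kept for inspection."""

    u: np.ndarray
    sigma_adj: float
    u_bar: float
    eta: np.ndarray
    f: np.ndarray


def log_compress(G: GrayImage) -> np.ndarray:
    """``u = ln(1 + G)`` per pixel; maps [0, 1] onto [0, ln 2]."""
    if G.range_tag != "unit":
        raise ValidationError("log_compress expects a unit-range image")
    return np.log1p(G.pixels)


def adjustment_sigma(u: np.ndarray) -> tuple[float, float]:
    """Corrected (n-1 denominator) sample std and mean of all pixels of u."""
    u = np.asarray(u, dtype=np.float64)
    if u.size < 2:
        raise ValidationError("adjustment_sigma needs at least 2 pixels")
    u_bar = float(u.mean())
    if np.ptp(u) == 0:  # constant grid: exactly zero spread
        return 0.0, u_bar
    sigma = float(np.sqrt(np.sum((u - u_bar) ** 2) / (u.size - 1)))
    return sigma, u_bar


def adjustment_eta(u: np.ndarray, lambda_tune: int = 3) -> np.ndarray:
    """``eta = u**lam / lam!`` element-wise."""
    if int(lambda_tune) != lambda_tune or lambda_tune < 1:
        raise ValidationError("lambda_tune must be a positive integer")
    lam = int(lambda_tune)
    return np.asarray(u, dtype=np.float64) ** lam / math.factorial(lam)


def tone_map(
    u: np.ndarray, sigma: float, eta: np.ndarray, params: SwiftParams = SwiftParams()
) -> np.ndarray:
    """Nonlinear exponential tone map (tan evaluated in radians)."""
    u = np.asarray(u, dtype=np.float64)
    with np.errstate(over="raise", divide="raise", invalid="raise"):
        try:
            if params.parse_mode == "fraction":
                f = np.exp((np.tan(u) - sigma) / (params.gamma * (np.exp(u) - eta)))
            else:
                f = np.exp(np.tan(u) - sigma * np.exp(u) - eta) ** params.gamma
        except FloatingPointError as exc:
            raise NumericError(f"tone map overflow/degeneracy: {exc}") from exc
    if not np.all(np.isfinite(f)):
        loc = tuple(np.argwhere(~np.isfinite(f))[0])
        raise NumericError(f"tone map produced a non-finite value at pixel {loc}")
    return f


def rescale_dynamic_range(f: np.ndarray) -> GrayImage:
    """Min-max rescale to [0, 1]; a constant grid maps to all 0.5."""
    f = np.asarray(f, dtype=np.float64)
    if not np.all(np.isfinite(f)):
        raise ValidationError("rescale_dynamic_range requires finite input")
    lo, hi = f.min(), f.max()
    if hi == lo:
        return GrayImage(np.full_like(f, 0.5), "unit")
    return GrayImage((f - lo) / (hi - lo), "unit")


def swift_enhance(
    G: GrayImage, params: SwiftParams = SwiftParams()
) -> tuple[GrayImage, SwiftIntermediates]:
    """Full enhancement chain; returns the enhanced image and intermediates."""
    u = log_compress(G)
    sigma, u_bar = adjustment_sigma(u)
    eta = adjustment_eta(u, params.lambda_tune)
    f = tone_map(u, sigma, eta, params)
    out = rescale_dynamic_range(f)
    return out, SwiftIntermediates(u=u, sigma_adj=sigma, u_bar=u_bar, eta=eta, f=f)
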