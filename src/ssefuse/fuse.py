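"""Pipeline orchestration and the weighted-sum fusion rule.

Stage order: normalize both sources, Wiener-filter both, optionally
swift-enhance both, extract the salient-structure decision map, smooth
it edge-aware into a weight map, then take the per-pixel convex
combination of the original 8-bit intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError
from .image import GrayImage, require_same_shape
from .ncfilter import NCParams, nc_smooth
from .preprocess import WienerParams, normalize, wiener_filter
from .sse import GRADIENT_MODES, DecisionMap, extract_salient_structure
from .swift import PARSE_MODES, SwiftParams, swift_enhance

GUIDANCE_MODES = ("a", "mean")


@dataclass(frozen=True)
class FusionConfig:
    """Every tunable of the fusion pipeline, with method defaults."""

    wiener: WienerParams = field(default_factory=WienerParams)
    swift: SwiftParams = field(default_factory=SwiftParams)
    sse_window: int = 7
    sse_gradient_mode: str = "paper"
    sse_use_swift: bool = True
    nc: NCParams = field(default_factory=NCParams)
    use_enhanced_sources: bool = False
    guidance: str = "a"
    output_range: str = "raw8"

    def __post_init__(self) -> None:
        if self.sse_window < 1 or self.sse_window % 2 == 0:
            raise ValidationError(
                f"sse_window must be odd and >= 1, got {self.sse_window}"
            )
        if self.sse_gradient_mode not in GRADIENT_MODES:
            raise ValidationError(
                f"sse_gradient_mode must be one of {GRADIENT_MODES}"
            )
        if self.guidance not in GUIDANCE_MODES:
            raise ValidationError(f"guidance must be one of {GUIDANCE_MODES}")
        if self.output_range not in ("raw8", "unit"):
            raise ValidationError("output_range must be 'raw8' or 'unit'")

    # -- plain-dict (de)serialization used by the YAML config loader ------

    def to_dict(self) -> dict[str, Any]:
        return {
            "wiener": {"radius": self.wiener.radius, "lambda": self.wiener.lam},
            "swift": {
                "lambda_tune": self.swift.lambda_tune,
                "gamma": self.swift.gamma,
                "parse_mode": self.swift.parse_mode,
            },
            "sse": {
                "window": self.sse_window,
                "gradient_mode": self.sse_gradient_mode,
                "use_swift": self.sse_use_swift,
            },
            "nc": {
                "sigma_s": self.nc.sigma_s,
                "sigma_r": self.nc.sigma_r,
                "iterations": self.nc.iterations,
            },
            "fuse": {
                "use_enhanced_sources": self.use_enhanced_sources,
                "guidance": self.guidance,
                "output_range": self.output_range,
            },
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "FusionConfig":
        defaults = cls().to_dict()
        if not isinstance(data, dict):
            raise ValidationError("config must be a mapping of sections")
        for section, keys in data.items():
            if section not in defaults:
                raise ValidationError(
                    f"unknown config section {section!r}; valid sections: "
                    f"{sorted(defaults)}"
                )
            if keys is None:
                continue
            if not isinstance(keys, dict):
                raise ValidationError(f"config section {section!r} must be a mapping")
            for key, value in keys.items():
                if key not in defaults[section]:
                    raise ValidationError(
                        f"unknown config key {section}.{key}; valid keys: "
                        f"{sorted(defaults[section])}"
                    )
                defaults[section][key] = value
        sigma_r = defaults["nc"]["sigma_r"]
        if isinstance(sigma_r, str):
            if sigma_r.lower() not in ("inf", "infinity"):
                raise ValidationError(f"nc.sigma_r: cannot parse {sigma_r!r}")
            sigma_r = math.inf
        return cls(
            wiener=WienerParams(
                radius=defaults["wiener"]["radius"], lam=defaults["wiener"]["lambda"]
            ),
            swift=SwiftParams(**defaults["swift"]),
            sse_window=defaults["sse"]["window"],
            sse_gradient_mode=defaults["sse"]["gradient_mode"],
            sse_use_swift=defaults["sse"]["use_swift"],
            nc=NCParams(
                sigma_s=defaults["nc"]["sigma_s"],
                sigma_r=sigma_r,
                iterations=defaults["nc"]["iterations"],
            ),
            use_enhanced_sources=defaults["fuse"]["use_enhanced_sources"],
            guidance=defaults["fuse"]["guidance"],
            output_range=defaults["fuse"]["output_range"],
        )


@dataclass(frozen=True)
class FusionResult:
    fused: GrayImage
    weight_map: np.ndarray
    decision: DecisionMap
    intermediates: dict[str, Any]


def weighted_fusion(I_T: np.ndarray, S_A: GrayImage, S_B: GrayImage) -> GrayImage:
    """Per-pixel convex combination ``F = w*S_A + (1-w)*S_B``.

    Computed as ``S_B + w*(S_A - S_B)`` (with the w == 1 plane taken
    from S_A directly) so that identical sources fuse to themselves
    bit-exactly; the result is clipped to the per-pixel envelope
    [min(S_A, S_B), max(S_A, S_B)].
    """
    w = np.asarray(I_T, dtype=np.float64)
    require_same_shape(w, S_A.pixels)
    require_same_shape(S_A, S_B)
    if S_A.range_tag != S_B.range_tag:
        raise ValidationError(
            f"source range mismatch: {S_A.range_tag} vs {S_B.range_tag}"
        )
    if w.min() < 0.0 or w.max() > 1.0:
        raise ValidationError("weight map must lie in [0, 1]")
    a, b = S_A.pixels, S_B.pixels
    f = np.where(w == 1.0, a, b + w * (a - b))
    f = np.clip(f, np.minimum(a, b), np.maximum(a, b))
    return GrayImage(f, S_A.range_tag)


def fuse_pipeline(
    S_A: GrayImage, S_B: GrayImage, cfg: FusionConfig = FusionConfig()
) -> FusionResult:
    """Run the full fusion pipeline on a co-registered raw8 pair."""
    require_same_shape(S_A, S_B)
    if S_A.range_tag != "raw8" or S_B.range_tag != "raw8":
        raise ValidationError("fuse_pipeline expects raw8 sources")

    G_A, G_B = normalize(S_A), normalize(S_B)
    Gbar_A = wiener_filter(G_A, cfg.wiener)
    Gbar_B = wiener_filter(G_B, cfg.wiener)

    intermediates: dict[str, Any] = {
        "G_A": G_A, "G_B": G_B, "Gbar_A": Gbar_A, "Gbar_B": Gbar_B,
    }

    if cfg.sse_use_swift:
        t_A, sw_A = swift_enhance(Gbar_A, cfg.swift)
        t_B, sw_B = swift_enhance(Gbar_B, cfg.swift)
        intermediates.update(
            swift_A=t_A, swift_B=t_B, swift_A_info=sw_A, swift_B_info=sw_B
        )
    else:
        t_A, t_B = Gbar_A, Gbar_B

    decision = extract_salient_structure(
        t_A, t_B, window=cfg.sse_window, mode=cfg.sse_gradient_mode
    )

    if cfg.guidance == "a":
        guidance = G_A
    else:
        guidance = GrayImage((G_A.pixels + G_B.pixels) / 2.0, "unit")
    weight = nc_smooth(decision.I_A, guidance, cfg.nc)

    if cfg.use_enhanced_sources:
        src_A = GrayImage(t_A.pixels * 255.0, "raw8")
        src_B = GrayImage(t_B.pixels * 255.0, "raw8")
    else:
        src_A, src_B = S_A, S_B
    fused = weighted_fusion(weight, src_A, src_B)
    if cfg.output_range == "unit":
        fused = GrayImage(fused.pixels / 255.0, "unit")

    return FusionResult(
        fused=fused, weight_map=weight, decision=decision, intermediates=intermediates
    )
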