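"""Twelve fusion-quality measures for an (A, B, F) image triple.

Intensity statistics (API, SD, AG, H, MI, FS, CC, SF) use 256-level
histograms on rounded raw8 intensities where a distribution is needed.
The gradient-preservation family (Q, L, N, Nm) scores, per pixel, how
well the fused image retains each source's Sobel edge strength and
orientation, weighted by source edge strength; Q + L + Nm is exactly 1
by construction (L is the restricted-sum complement of Q and Nm, which
coincides with the identity form).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import sobel

from .errors import ValidationError
from .image import GrayImage, require_same_shape

logger = logging.getLogger(__name__)

# Sigmoid constants of the gradient-preservation model, adopted from the
# objective-fusion-evaluation literature; overridable per call.
GAMMA_G, KAPPA_G, SIGMA_G = 0.9994, -15.0, 0.5
GAMMA_A, KAPPA_A, SIGMA_A = 0.9879, -22.0, 0.8
WEIGHT_EXP = 1.0


@dataclass(frozen=True)
class MetricReport:
    """The twelve metric values for one (A, B, F) triple."""

    API: float
    SD: float
    AG: float
    H: float
    MI: float
    FS: float
    CC: float
    SF: float
    Q_abf: float
    L_abf: float
    N_abf: float
    Nm_abf: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class EdgeField:
    """Sobel edge strength g >= 0 and orientation alpha in (-pi/2, pi/2]."""

    g: np.ndarray
    alpha: np.ndarray


def _raw8(img: GrayImage) -> np.ndarray:
    if img.range_tag != "raw8":
        raise ValidationError("metrics expect raw8 images")
    return img.pixels


def _levels(img: GrayImage) -> np.ndarray:
    return np.clip(np.rint(_raw8(img)), 0, 255).astype(np.int64)


def api(F: GrayImage) -> float:
    """Average pixel intensity (mean)."""
    return float(_raw8(F).mean())


def sd(F: GrayImage) -> float:
    """Population standard deviation (mn denominator)."""
    px = _raw8(F)
    return float(np.sqrt(np.mean((px - px.mean()) ** 2)))


def ag(F: GrayImage) -> float:
    """Average gradient: mean over valid pixels of the forward-difference
    gradient norm (last row and column excluded)."""
    px = _raw8(F)
    dx = px[:-1, 1:] - px[:-1, :-1]
    dy = px[1:, :-1] - px[:-1, :-1]
    return float(np.mean(np.sqrt(dx * dx + dy * dy)))


def entropy(X: GrayImage) -> float:
    """Shannon entropy (bits) of the 256-level histogram."""
    counts = np.bincount(_levels(X).ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def mutual_information(X: GrayImage, Y: GrayImage) -> float:
    """Mutual information (bits) from the 256x256 joint histogram."""
    require_same_shape(X, Y)
    lx, ly = _levels(X).ravel(), _levels(Y).ravel()
    joint = np.bincount(lx * 256 + ly, minlength=256 * 256).reshape(256, 256)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def mi_total(A: GrayImage, B: GrayImage, F: GrayImage) -> float:
    """MI(A, F) + MI(B, F)."""
    return mutual_information(A, F) + mutual_information(B, F)


def spatial_frequency(F: GrayImage) -> float:
    """Row/column frequency RMS combined as sqrt(RF^2 + CF^2).

    The squared-difference sums are divided by the full pixel count mn
    (as printed in the defining formulas), not by the number of
    difference terms.
    """
    px = _raw8(F)
    mn = px.size
    rf2 = np.sum((px[:, 1:] - px[:, :-1]) ** 2) / mn
    cf2 = np.sum((px[1:, :] - px[:-1, :]) ** 2) / mn
    return float(np.sqrt(rf2 + cf2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    return float(np.sum(xd * yd) / np.sqrt(np.sum(xd * xd) * np.sum(yd * yd)))


def correlation_coefficient(A: GrayImage, B: GrayImage, F: GrayImage) -> float:
    """Mean of the Pearson correlations of F with A and with B."""
    require_same_shape(A, F)
    require_same_shape(B, F)
    for name, img in (("A", A), ("B", B), ("F", F)):
        if np.ptp(_raw8(img)) == 0:
            raise ValidationError(
                f"correlation undefined: image {name} has zero variance"
            )
    return (_pearson(_raw8(A), _raw8(F)) + _pearson(_raw8(B), _raw8(F))) / 2.0


def fusion_symmetry(A: GrayImage, B: GrayImage, F: GrayImage) -> float:
    """2 - |MI_AF / (MI_AF + MI_BF) - 0.5|; ranges over [1.5, 2]."""
    mi_af = mutual_information(A, F)
    mi_bf = mutual_information(B, F)
    total = mi_af + mi_bf
    if total <= 0:
        raise ValidationError("fusion symmetry undefined: total mutual information is 0")
    return 2.0 - abs(mi_af / total - 0.5)


def edge_field(X: GrayImage) -> EdgeField:
    """Sobel edge strength and orientation.

    alpha = atan(sy/sx), with pi/2 on the sx = 0, sy != 0 plane and 0
    where both responses vanish.
    """
    px = _raw8(X)
    sx = sobel(px, axis=1, mode="nearest")
    sy = sobel(px, axis=0, mode="nearest")
    g = np.hypot(sx, sy)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.arctan(np.divide(sy, sx, out=np.zeros_like(sy), where=sx != 0))
    alpha = np.where((sx == 0) & (sy != 0), np.pi / 2.0, alpha)
    alpha = np.where((sx == 0) & (sy == 0), 0.0, alpha)
    return EdgeField(g=g, alpha=alpha)


def _preservation(src: EdgeField, fused: EdgeField,
                  constants: dict[str, float]) -> np.ndarray:
    gs, gf = src.g, fused.g
    both_zero = (gs == 0) & (gf == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gs > gf,
                         np.divide(gf, gs, out=np.zeros_like(gf), where=gs != 0),
                         np.divide(gs, gf, out=np.zeros_like(gs), where=gf != 0))
    G = np.where(both_zero, 1.0, ratio)
    A = 1.0 - np.abs(src.alpha - fused.alpha) / (np.pi / 2.0)
    q_g = constants["gamma_g"] / (1.0 + np.exp(constants["kappa_g"] * (G - constants["sigma_g"])))
    q_a = constants["gamma_a"] / (1.0 + np.exp(constants["kappa_a"] * (A - constants["sigma_a"])))
    return q_g * q_a


def gradient_preservation(
    A: GrayImage,
    B: GrayImage,
    F: GrayImage,
    *,
    gamma_g: float = GAMMA_G, kappa_g: float = KAPPA_G, sigma_g: float = SIGMA_G,
    gamma_a: float = GAMMA_A, kappa_a: float = KAPPA_A, sigma_a: float = SIGMA_A,
    weight_exp: float = WEIGHT_EXP,
) -> tuple[float, float, float, float]:
    """Gradient-information transfer family (Q_abf, L_abf, N_abf, Nm_abf).

    Per pixel the fused image earns a preservation score against each
    source (edge-strength ratio and orientation agreement mapped
    through sigmoids), aggregated with edge-strength weights.  AM marks
    artifact pixels where the fused gradient exceeds both sources;
    N_abf is the weighted artifact fraction, Nm_abf additionally scales
    by the preservation shortfall, and L_abf = 1 - Q_abf - Nm_abf.
    """
    require_same_shape(A, F)
    require_same_shape(B, F)
    constants = dict(gamma_g=gamma_g, kappa_g=kappa_g, sigma_g=sigma_g,
                     gamma_a=gamma_a, kappa_a=kappa_a, sigma_a=sigma_a)
    ea, eb, ef = edge_field(A), edge_field(B), edge_field(F)
    q_af = _preservation(ea, ef, constants)
    q_bf = _preservation(eb, ef, constants)
    w_a = ea.g ** weight_exp
    w_b = eb.g ** weight_exp
    w_sum = np.sum(w_a + w_b)
    if w_sum == 0:
        logger.warning(
            "all-zero edge strengths; gradient preservation is vacuous (Q=1)"
        )
        return 1.0, 0.0, 0.0, 0.0
    am = ((ef.g > ea.g) & (ef.g > eb.g)).astype(np.float64)
    q = float(np.sum(q_af * w_a + q_bf * w_b) / w_sum)
    n = float(np.sum(am * (w_a + w_b)) / w_sum)
    nm = float(np.sum(am * ((1.0 - q_af) * w_a + (1.0 - q_bf) * w_b)) / w_sum)
    loss = 1.0 - q - nm
    return q, loss, n, nm


def information_loss_restricted(
    A: GrayImage, B: GrayImage, F: GrayImage, **constants: float
) -> float:
    """Diagnostic: loss summed only over non-artifact pixels.

    Algebraically identical to ``1 - Q_abf - Nm_abf`` and computed
    independently here as a cross-check.
    """
    require_same_shape(A, F)
    require_same_shape(B, F)
    defaults = dict(gamma_g=GAMMA_G, kappa_g=KAPPA_G, sigma_g=SIGMA_G,
                    gamma_a=GAMMA_A, kappa_a=KAPPA_A, sigma_a=SIGMA_A)
    defaults.update(constants)
    ea, eb, ef = edge_field(A), edge_field(B), edge_field(F)
    q_af = _preservation(ea, ef, defaults)
    q_bf = _preservation(eb, ef, defaults)
    w_a, w_b = ea.g, eb.g
    w_sum = np.sum(w_a + w_b)
    if w_sum == 0:
        return 0.0
    not_am = ~((ef.g > ea.g) & (ef.g > eb.g))
    return float(
        np.sum(not_am * ((1.0 - q_af) * w_a + (1.0 - q_bf) * w_b)) / w_sum
    )


def metric_report(A: GrayImage, B: GrayImage, F: GrayImage) -> MetricReport:
    """All twelve measures for one (A, B, F) triple."""
    require_same_shape(A, F)
    require_same_shape(B, F)
    q, loss, n, nm = gradient_preservation(A, B, F)
    return MetricReport(
        API=api(F),
        SD=sd(F),
        AG=ag(F),
        H=entropy(F),
        MI=mi_total(A, B, F),
        FS=fusion_symmetry(A, B, F),
        CC=correlation_coefficient(A, B, F),
        SF=spatial_frequency(F),
        Q_abf=q,
        L_abf=loss,
        N_abf=n,
        Nm_abf=nm,
    )
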