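"""Independent brute-force oracles used by unit and acceptance tests.

Every function here is a direct, nested-loop (or otherwise naive)
evaluation of the defining formula, deliberately sharing no code with
the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def local_mean_var(px: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean/population variance over a square window, edge-replicated."""
    m, n = px.shape
    padded = np.pad(px, radius, mode="edge")
    mean = np.empty((m, n))
    var = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            win = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            mean[i, j] = win.mean()
            var[i, j] = ((win - win.mean()) ** 2).mean()
    return mean, var


def wiener(px: np.ndarray, radius: int, lam: float) -> np.ndarray:
    mean, var = local_mean_var(px, radius)
    out = np.empty_like(px)
    for i in range(px.shape[0]):
        for j in range(px.shape[1]):
            k = 1.0 if lam == 0 else var[i, j] / (var[i, j] + lam)
            out[i, j] = mean[i, j] + k * (px[i, j] - mean[i, j])
    return out


def mean_filter(D: np.ndarray, window: int) -> np.ndarray:
    r = window // 2
    m, n = D.shape
    padded = np.pad(D, r, mode="edge")
    out = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            out[i, j] = padded[i : i + window, j : j + window].mean()
    return out


def nc_box_line(signal: np.ndarray, ct: np.ndarray, r: float) -> np.ndarray:
    """O(N^2) normalized box filter over warped coordinates."""
    n = len(signal)
    out = np.empty(n)
    for p in range(n):
        acc, k = 0.0, 0
        for q in range(n):
            if abs(ct[p] - ct[q]) <= r:
                acc += signal[q]
                k += 1
        out[p] = acc / k
    return out


def sample_std(u: np.ndarray) -> float:
    """Textbook corrected (n-1) sample standard deviation, direct summation."""
    flat = u.ravel()
    mean = sum(flat) / len(flat)
    return math.sqrt(sum((v - mean) ** 2 for v in flat) / (len(flat) - 1))


# ---- metric oracles (all nested loops over pixels or histogram bins) ----

def sd(px: np.ndarray) -> float:
    m, n = px.shape
    fbar = px.sum() / (m * n)
    return math.sqrt(sum((px[i, j] - fbar) ** 2 for i in range(m) for j in range(n)) / (m * n))


def ag(px: np.ndarray) -> float:
    m, n = px.shape
    total = 0.0
    for i in range(m - 1):
        for j in range(n - 1):
            dx = px[i, j + 1] - px[i, j]
            dy = px[i + 1, j] - px[i, j]
            total += math.sqrt(dx * dx + dy * dy)
    return total / ((m - 1) * (n - 1))


def entropy(px: np.ndarray) -> float:
    levels = np.clip(np.rint(px), 0, 255).astype(int)
    counts = [0] * 256
    for v in levels.ravel():
        counts[v] += 1
    total = levels.size
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    lx = np.clip(np.rint(x), 0, 255).astype(int).ravel()
    ly = np.clip(np.rint(y), 0, 255).astype(int).ravel()
    joint: dict[tuple[int, int], int] = {}
    cx: dict[int, int] = {}
    cy: dict[int, int] = {}
    for a, b in zip(lx, ly):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        cx[a] = cx.get(a, 0) + 1
        cy[b] = cy.get(b, 0) + 1
    n = len(lx)
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab / ((cx[a] / n) * (cy[b] / n)))
    return mi


def spatial_frequency(px: np.ndarray) -> float:
    m, n = px.shape
    rf = sum((px[i, j] - px[i, j - 1]) ** 2 for i in range(m) for j in range(1, n)) / (m * n)
    cf = sum((px[i, j] - px[i - 1, j]) ** 2 for i in range(1, m) for j in range(n)) / (m * n)
    return math.sqrt(rf + cf)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    xb, yb = x.mean(), y.mean()
    num = sum((x[i, j] - xb) * (y[i, j] - yb)
              for i in range(x.shape[0]) for j in range(x.shape[1]))
    dx = sum((x[i, j] - xb) ** 2 for i in range(x.shape[0]) for j in range(x.shape[1]))
    dy = sum((y[i, j] - yb) ** 2 for i in range(y.shape[0]) for j in range(y.shape[1]))
    return num / math.sqrt(dx * dy)


def _sobel_fields(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sobel strength/orientation with nearest-edge padding, per pixel."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    ky = kx.T
    m, n = px.shape
    padded = np.pad(px, 1, mode="edge")
    g = np.empty((m, n))
    alpha = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            win = padded[i : i + 3, j : j + 3]
            sx = (win * kx).sum()
            sy = (win * ky).sum()
            g[i, j] = math.hypot(sx, sy)
            if sx == 0:
                alpha[i, j] = 0.0 if sy == 0 else math.pi / 2
            else:
                alpha[i, j] = math.atan(sy / sx)
    return g, alpha


def gradient_family(
    a: np.ndarray, b: np.ndarray, f: np.ndarray,
    gamma_g: float = 0.9994, kappa_g: float = -15.0, sigma_g: float = 0.5,
    gamma_a: float = 0.9879, kappa_a: float = -22.0, sigma_a: float = 0.8,
) -> tuple[float, float, float, float]:
    """Direct per-pixel evaluation of (Q, L_restricted, N, Nm)."""
    ga, aa = _sobel_fields(a)
    gb, ab = _sobel_fields(b)
    gf, af = _sobel_fields(f)
    m, n = a.shape

    def q_pixel(gs, als, gft, alf):
        if gs == 0 and gft == 0:
            G = 1.0
        elif gs > gft:
            G = gft / gs
        elif gft == 0:
            G = 0.0
        else:
            G = gs / gft
        A = 1.0 - abs(als - alf) / (math.pi / 2)
        qg = gamma_g / (1.0 + math.exp(kappa_g * (G - sigma_g)))
        qa = gamma_a / (1.0 + math.exp(kappa_a * (A - sigma_a)))
        return qg * qa

    num_q = num_n = num_nm = num_l = den = 0.0
    for i in range(m):
        for j in range(n):
            qaf = q_pixel(ga[i, j], aa[i, j], gf[i, j], af[i, j])
            qbf = q_pixel(gb[i, j], ab[i, j], gf[i, j], af[i, j])
            wa, wb = ga[i, j], gb[i, j]
            am = 1.0 if (gf[i, j] > ga[i, j] and gf[i, j] > gb[i, j]) else 0.0
            num_q += qaf * wa + qbf * wb
            num_n += am * (wa + wb)
            num_nm += am * ((1 - qaf) * wa + (1 - qbf) * wb)
            num_l += (1 - am) * ((1 - qaf) * wa + (1 - qbf) * wb)
            den += wa + wb
    return num_q / den, num_l / den, num_n / den, num_nm / den
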