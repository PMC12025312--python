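"""Independent brute-force oracles for the texture-feature families.

Everything here is written directly from the mathematical definitions with
plain Python loops and explicit enumeration, deliberately sharing no code
with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# first-order statistics over the pixel multiset
# ---------------------------------------------------------------------------


def fos_oracle(pixels: np.ndarray) -> dict[str, float]:
    x = sorted(float(v) for v in pixels)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    std = math.sqrt(var)

    def percentile(q: float) -> float:
        # linear interpolation between closest ranks (numpy 'linear' rule)
        pos = (n - 1) * q / 100.0
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return x[lo] * (1 - frac) + x[hi] * frac

    counts = [0] * 256
    for v in x:
        counts[int(round(v))] += 1
    probs = [c / n for c in counts]
    energy = sum(p * p for p in probs)
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    mode = float(max(range(256), key=lambda i: (counts[i], -i)))
    if std > 0:
        skew = sum(((v - mean) / std) ** 3 for v in x) / n
        kurt = sum(((v - mean) / std) ** 4 for v in x) / n - 3.0
    else:
        skew = kurt = 0.0
    p10, p90 = percentile(10), percentile(90)
    return {
        "FOS_p10": p10,
        "FOS_p25": percentile(25),
        "FOS_p75": percentile(75),
        "FOS_p90": p90,
        "FOS_cv": std / mean if mean != 0 else 0.0,
        "FOS_energy": energy,
        "FOS_entropy": entropy,
        "FOS_histogram_width": p90 - p10,
        "FOS_kurtosis": kurt,
        "FOS_max": x[-1],
        "FOS_mean": mean,
        "FOS_median": percentile(50),
        "FOS_min": x[0],
        "FOS_mode": mode,
        "FOS_skewness": skew,
        "FOS_variance": var,
    }


# ---------------------------------------------------------------------------
# GLCM by explicit pair enumeration + literal Haralick formulas
# ---------------------------------------------------------------------------

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(image: np.ndarray, mask: np.ndarray, levels: int, angle: int, distance: int = 1) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix by per-pixel loops."""
    vals = image[mask].astype(float)
    lo, hi = vals.min(), vals.max()
    h, w = image.shape
    q = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            if hi > lo:
                q[r, c] = min(levels - 1, int((image[r, c] - lo) / (hi - lo) * levels))
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    M = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                M[q[r, c], q[r2, c2]] += 1
                M[q[r2, c2], q[r, c]] += 1  # symmetric
    total = M.sum()
    if total == 0:
        raise ValueError("no valid pairs")
    return M / total


def haralick_oracle(P: np.ndarray) -> dict[str, float]:
    L = P.shape[0]
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(L))

    asm = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    if var_x > 0 and var_y > 0:
        corr = sum(
            (i - mu_x) * (j - mu_y) * P[i, j] for i in range(L) for j in range(L)
        ) / math.sqrt(var_x * var_y)
    else:
        corr = 0.0
    ssv = sum((i - mu_x) ** 2 * P[i, j] for i in range(L) for j in range(L))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))

    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]
    sum_average = sum(k * p_sum[k] for k in range(len(p_sum)))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(len(p_sum)))
    sum_entropy = -sum(p * math.log2(p) for p in p_sum if p > 0)
    mu_d = sum(k * p_diff[k] for k in range(L))
    diff_variance = sum((k - mu_d) ** 2 * p_diff[k] for k in range(L))
    diff_entropy = -sum(p * math.log2(p) for p in p_diff if p > 0)
    entropy = -sum(
        P[i, j] * math.log2(P[i, j]) for i in range(L) for j in range(L) if P[i, j] > 0
    )

    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hy = -sum(p * math.log2(p) for p in py if p > 0)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if px[i] * py[j] > 0
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - entropy))))

    present = [i for i in range(L) if px[i] > 0]
    if len(present) >= 2:
        Q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    P[i, k] * P[j, k] / (px[i] * py[k]) for k in present if py[k] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = math.sqrt(min(1.0, max(0.0, ev[1])))
    else:
        mcc = 0.0

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": corr,
        "sum_of_squares_variance": ssv,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": diff_variance,
        "difference_entropy": diff_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "mcc": mcc,
    }


# ---------------------------------------------------------------------------
# Laws texture energy by direct 3x3 correlation loops with reflect padding
# ---------------------------------------------------------------------------

_LAWS = {
    "L": [1.0, 2.0, 1.0],
    "E": [-1.0, 0.0, 1.0],
    "S": [-1.0, 2.0, -1.0],
}


def _reflect(i: int, n: int) -> int:
    # scipy 'reflect' boundary: (d c b a | a b c d | d c b a)
    if i < 0:
        return -i - 1
    if i >= n:
        return 2 * n - i - 1
    return i


def laws_energy_oracle(image: np.ndarray, mask: np.ndarray, u: str, v: str) -> float:
    """Mean absolute response of outer(u, v) over masked pixels (reflect border)."""
    h, w = image.shape
    kern = [[_LAWS[u][a] * _LAWS[v][b] for b in range(3)] for a in range(3)]
    total, count = 0.0, 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            acc = 0.0
            for a in range(3):
                for b in range(3):
                    rr = _reflect(r + a - 1, h)
                    cc = _reflect(c + b - 1, w)
                    acc += kern[a][b] * float(image[rr, cc])
            total += abs(acc)
            count += 1
    return total / count
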