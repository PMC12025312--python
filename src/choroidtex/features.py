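"""The 52-feature radiomics registry: FOS, GLCM (Haralick), Gabor, and Laws TE.

All features are computed from the masked ROI only.  Filter-based families
(Gabor, Laws) convolve the full image — with reflect padding at the borders —
and then pool statistics over pixels whose kernel centre lies in the mask, so
texture estimates never see zero-fill values.

Conventions (the image model is 8-bit):

* entropies are in bits;
* histogram statistics (energy, entropy, mode) use 256 unit-width bins
  centred on the integers 0..255;
* skewness and kurtosis are standardized central moments, kurtosis excess
  (a constant ROI scores 0 for both);
* GLCM gray levels are 32 equal-width bins over the ROI min-max, distance 1,
  four directions, symmetric and normalized, statistics averaged over the
  directions that have at least one valid in-mask pair;
* Gabor filters are DC-corrected so a constant image yields zero response;
  intensities are rescaled to [-0.5, 0.5] before filtering and the complex
  response magnitude is pooled;
* Laws texture energies use the 3-tap vectors L3, E3, S3; energies of
  non-identical pairs average both orders, and all but LL are normalized by
  the LL energy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import fft, ndimage
from skimage.filters import gabor_kernel

from .roi_model import ImageSample

__all__ = [
    "GLCMSpec",
    "GaborBankSpec",
    "FeatureVector",
    "FEATURE_GROUPS",
    "FEATURE_NAMES",
    "feature_names",
    "compute_fos",
    "compute_glcm",
    "compute_glcm_features",
    "compute_gabor_features",
    "compute_lte_features",
    "extract_all",
    "extract_table",
    "METADATA_COLUMNS",
]


class FeatureError(ValueError):
    """Raised when a ROI is unusable for a feature family."""


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_FOS_NAMES = (
    "FOS_p10",
    "FOS_p25",
    "FOS_p75",
    "FOS_p90",
    "FOS_cv",
    "FOS_energy",
    "FOS_entropy",
    "FOS_histogram_width",
    "FOS_kurtosis",
    "FOS_max",
    "FOS_mean",
    "FOS_median",
    "FOS_min",
    "FOS_mode",
    "FOS_skewness",
    "FOS_variance",
)

_GLCM_STATS = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "mcc",
)
_GLCM_NAMES = tuple(f"GLCM_{s}_mean" for s in _GLCM_STATS)

_GABOR_ANGLES = (0, 45, 90, 135)
_GABOR_FREQS = (0.1, 0.4)
_GABOR_NAMES = tuple(
    f"GABOR_a{a}_f{f}_{stat}"
    for a in _GABOR_ANGLES
    for f in _GABOR_FREQS
    for stat in ("mean", "std")
)

_LTE_NAMES = ("LTE_LL", "LTE_LE", "LTE_LS", "LTE_EE", "LTE_ES", "LTE_SS")

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "fos": _FOS_NAMES,
    "glcm": _GLCM_NAMES,
    "gabor": _GABOR_NAMES,
    "lte": _LTE_NAMES,
}

FEATURE_NAMES: tuple[str, ...] = _FOS_NAMES + _GLCM_NAMES + _GABOR_NAMES + _LTE_NAMES

METADATA_COLUMNS = [
    "sample_id",
    "eye_id",
    "patient_id",
    "group",
    "modality",
    "depth_fraction",
    "slice_index",
]


def feature_names(groups: Iterable[str] | None = None) -> list[str]:
    """Registry names, optionally restricted to families ('fos','glcm','gabor','lte')."""
    if groups is None:
        return list(FEATURE_NAMES)
    out: list[str] = []
    for g in groups:
        key = g.lower()
        if key not in FEATURE_GROUPS:
            raise KeyError(f"unknown feature family {g!r}")
        out.extend(FEATURE_GROUPS[key])
    return out


def family_of(name: str) -> str:
    return name.split("_", 1)[0].lower()


@dataclass
class FeatureVector:
    """Ordered 52-feature mapping plus the sample's metadata."""

    values: dict[str, float]
    sample_id: str
    eye_id: str
    group: str
    modality: str
    depth_fraction: float | None = None

    def as_array(self, names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------


def compute_fos(sample: ImageSample) -> dict[str, float]:
    """16 first-order statistics of the masked pixel multiset."""
    x = sample.roi_pixels
    if x.size == 0:
        raise FeatureError(f"{sample.sample_id}: empty mask")
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    mean = float(x.mean())
    std = float(x.std())
    var = std * std
    if mean != 0.0:
        cv = std / mean
    else:
        warnings.warn(f"{sample.sample_id}: zero-mean ROI, reporting CV = 0")
        cv = 0.0
    hist, _ = np.histogram(x, bins=256, range=(-0.5, 255.5))
    p = hist / x.size
    nz = p[p > 0]
    energy = float(np.sum(p * p))
    entropy = float(-np.sum(nz * np.log2(nz)))
    mode = float(np.argmax(hist))  # lowest bin wins ties
    if std > 0:
        z = (x - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    return {
        "FOS_p10": float(p10),
        "FOS_p25": float(p25),
        "FOS_p75": float(p75),
        "FOS_p90": float(p90),
        "FOS_cv": float(cv),
        "FOS_energy": energy,
        "FOS_entropy": entropy,
        "FOS_histogram_width": float(p90 - p10),
        "FOS_kurtosis": kurt,
        "FOS_max": float(x.max()),
        "FOS_mean": mean,
        "FOS_median": float(np.median(x)),
        "FOS_min": float(x.min()),
        "FOS_mode": mode,
        "FOS_skewness": skew,
        "FOS_variance": var,
    }


# ---------------------------------------------------------------------------
# gray-level co-occurrence matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GLCMSpec:
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    levels: int = 32
    symmetric: bool = True
    normalized: bool = True


_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _quantize(sample: ImageSample, levels: int) -> np.ndarray:
    """Equal-width quantization of ROI intensities to ``levels`` gray levels."""
    img = sample.image.astype(float)
    roi = sample.roi_pixels
    lo, hi = roi.min(), roi.max()
    if hi == lo:
        return np.zeros_like(img, dtype=np.int64)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def compute_glcm(sample: ImageSample, spec: GLCMSpec = GLCMSpec(), angle: int = 0) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one direction.

    Only pixel pairs with both members in-mask are counted.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"unsupported angle {angle}")
    q = _quantize(sample, spec.levels)
    mask = sample.mask
    dr, dc = (spec.distance * o for o in _OFFSETS[angle])
    h, w = mask.shape
    a = q[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    b = q[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)]
    ma = mask[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    mb = mask[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)]
    valid = ma & mb
    if not valid.any():
        raise FeatureError(f"{sample.sample_id}: no valid pixel pairs at angle {angle}")
    L = spec.levels
    counts = np.bincount(a[valid] * L + b[valid], minlength=L * L).reshape(L, L).astype(float)
    if spec.symmetric:
        counts = counts + counts.T
    if spec.normalized:
        counts /= counts.sum()
    return counts


def _haralick_stats(P: np.ndarray) -> dict[str, float]:
    """The 14 Haralick statistics of one normalized symmetric GLCM (base-2 logs)."""
    L = P.shape[0]
    idx = np.arange(L, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(px @ idx)
    mu_y = float(py @ idx)
    var_x = float(px @ (idx - mu_x) ** 2)
    var_y = float(py @ (idx - mu_y) ** 2)

    asm = float(np.sum(P * P))
    contrast = float(np.sum((i - j) ** 2 * P))
    if var_x > 0 and var_y > 0:
        correlation = float((np.sum(i * j * P) - mu_x * mu_y) / math.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    ssv = float(np.sum((i - mu_x) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (i - j) ** 2)))

    ksum = (np.arange(L)[:, None] + np.arange(L)[None, :]).ravel()
    p_sum = np.bincount(ksum, weights=P.ravel(), minlength=2 * L - 1)
    ks = np.arange(p_sum.size, dtype=float)
    sum_average = float(p_sum @ ks)
    sum_variance = float(p_sum @ (ks - sum_average) ** 2)
    nz = p_sum[p_sum > 0]
    sum_entropy = float(-np.sum(nz * np.log2(nz)))

    kdiff = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).ravel()
    p_diff = np.bincount(kdiff, weights=P.ravel(), minlength=L)
    kd = np.arange(p_diff.size, dtype=float)
    mu_d = float(p_diff @ kd)
    difference_variance = float(p_diff @ (kd - mu_d) ** 2)
    nz = p_diff[p_diff > 0]
    difference_entropy = float(-np.sum(nz * np.log2(nz)))

    nzP = P[P > 0]
    entropy = float(-np.sum(nzP * np.log2(nzP)))

    def _h(v: np.ndarray) -> float:
        v = v[v > 0]
        return float(-np.sum(v * np.log2(v)))

    hx, hy = _h(px), _h(py)
    pxpy = px[:, None] * py[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-np.sum(P * lg))
    hxy2 = _h(pxpy.ravel())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - entropy))))

    present = px > 0
    if present.sum() >= 2:
        A = P[np.ix_(present, present)]
        pxs = px[present]
        pys = py[present]
        Q = (A / pxs[:, None]) @ (A / pys[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = math.sqrt(min(1.0, max(0.0, float(ev[1]))))
    else:
        mcc = 0.0

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares_variance": ssv,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "mcc": mcc,
    }


def compute_glcm_features(sample: ImageSample, spec: GLCMSpec = GLCMSpec()) -> dict[str, float]:
    """14 Haralick statistics averaged over the directions that have valid pairs."""
    per_dir: list[dict[str, float]] = []
    for angle in spec.angles:
        try:
            P = compute_glcm(sample, spec, angle)
        except FeatureError:
            continue
        per_dir.append(_haralick_stats(P))
    if not per_dir:
        raise FeatureError(f"{sample.sample_id}: no direction has a valid pixel pair")
    return {
        f"GLCM_{s}_mean": float(np.mean([d[s] for d in per_dir])) for s in _GLCM_STATS
    }


# ---------------------------------------------------------------------------
# Gabor filter bank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaborBankSpec:
    angles: tuple[int, ...] = _GABOR_ANGLES
    frequencies: tuple[float, ...] = _GABOR_FREQS
    bandwidth: float = 1.0


@lru_cache(maxsize=8)
def _gabor_kernels(spec: GaborBankSpec) -> tuple[tuple[int, float, np.ndarray], ...]:
    """Complex kernels, DC-corrected so the response to a constant image is 0."""
    kernels = []
    for a in spec.angles:
        for f in spec.frequencies:
            k = gabor_kernel(frequency=f, theta=np.deg2rad(a), bandwidth=spec.bandwidth)
            k = k - k.mean()
            kernels.append((a, f, k))
    return tuple(kernels)


def _pad_reflect(img: np.ndarray, pad_r: int, pad_c: int) -> np.ndarray:
    """Reflect padding that tolerates pads larger than the image extent."""
    out = img
    while pad_r > 0 or pad_c > 0:
        pr = min(pad_r, out.shape[0] - 1)
        pc = min(pad_c, out.shape[1] - 1)
        if pr == 0 and pc == 0:  # 1-pixel axis: fall back to edge padding
            out = np.pad(out, ((pad_r, pad_r), (pad_c, pad_c)), mode="edge")
            break
        out = np.pad(out, ((pr, pr), (pc, pc)), mode="reflect")
        pad_r -= pr
        pad_c -= pc
    return out


# transfer functions of each kernel, cached per padded image shape
_KERNEL_FFT_CACHE: dict[tuple, tuple] = {}


def _kernel_ffts(bank: GaborBankSpec, shape: tuple[int, int]):
    key = (bank, shape)
    cached = _KERNEL_FFT_CACHE.get(key)
    if cached is None:
        entries = []
        for a, f, k in _gabor_kernels(bank):
            cr, cc = k.shape[0] // 2, k.shape[1] // 2
            entries.append((a, f, cr, cc, fft.fft2(k, s=shape)))
        cached = tuple(entries)
        if len(_KERNEL_FFT_CACHE) > 32:
            _KERNEL_FFT_CACHE.clear()
        _KERNEL_FFT_CACHE[key] = cached
    return cached


def compute_gabor_features(
    sample: ImageSample, bank: GaborBankSpec = GaborBankSpec()
) -> dict[str, float]:
    """Mean and std of the complex Gabor response magnitude over masked pixels.

    Intensities are first rescaled from [0, 255] to [-0.5, 0.5]; responses are
    computed on the full image with reflect padding.  All filters share one
    forward FFT of the padded image; kernel transfer functions are cached per
    image shape.
    """
    if not sample.mask.any():
        raise FeatureError(f"{sample.sample_id}: empty mask")
    img = sample.image.astype(float) / 255.0 - 0.5
    kernels = _gabor_kernels(bank)
    pad_r = max(k.shape[0] // 2 for _, _, k in kernels)
    pad_c = max(k.shape[1] // 2 for _, _, k in kernels)
    padded = _pad_reflect(img, pad_r, pad_c)
    h, w = img.shape
    fshape = (fft.next_fast_len(padded.shape[0]), fft.next_fast_len(padded.shape[1]))
    img_fft = fft.fft2(padded, s=fshape)
    out: dict[str, float] = {}
    for a, f, cr, cc, kfft in _kernel_ffts(bank, fshape):
        full = fft.ifft2(img_fft * kfft)
        # circular conv equals linear 'same' conv at offset (centre + pad)
        mag = np.abs(full[pad_r + cr : pad_r + cr + h, pad_c + cc : pad_c + cc + w])
        vals = mag[sample.mask]
        out[f"GABOR_a{a}_f{f}_mean"] = float(vals.mean())
        out[f"GABOR_a{a}_f{f}_std"] = float(vals.std())
    return out


# ---------------------------------------------------------------------------
# Laws texture energy
# ---------------------------------------------------------------------------

_L3 = np.array([1.0, 2.0, 1.0])
_E3 = np.array([-1.0, 0.0, 1.0])
_S3 = np.array([-1.0, 2.0, -1.0])
_LAWS_VECTORS = {"L": _L3, "E": _E3, "S": _S3}


def compute_lte_features(sample: ImageSample) -> dict[str, float]:
    """Laws 3x3 texture energies: LL raw, the other pairs normalized by LL.

    The ROI mean is subtracted first (Laws' illumination-removal step), which
    makes every energy — including the LL normalizer — invariant to a constant
    intensity shift.  Energy of a kernel is the mean absolute response over
    masked pixels; non-identical pairs (LE, LS, ES) average the two kernel
    orders.  A constant image has zero fluctuation energy everywhere, so all
    six features are 0 there by convention.
    """
    if not sample.mask.any():
        raise FeatureError(f"{sample.sample_id}: empty mask")
    img = sample.image.astype(float) - sample.roi_pixels.mean()
    mask = sample.mask

    energies: dict[tuple[str, str], float] = {}
    for u in "LES":
        for v in "LES":
            kern = np.outer(_LAWS_VECTORS[u], _LAWS_VECTORS[v])
            resp = ndimage.correlate(img, kern, mode="reflect")
            energies[(u, v)] = float(np.mean(np.abs(resp[mask])))

    def pair(u: str, v: str) -> float:
        return (energies[(u, v)] + energies[(v, u)]) / 2.0

    ll = energies[("L", "L")]
    raw = {
        "LTE_LL": ll,
        "LTE_LE": pair("L", "E"),
        "LTE_LS": pair("L", "S"),
        "LTE_EE": energies[("E", "E")],
        "LTE_ES": pair("E", "S"),
        "LTE_SS": energies[("S", "S")],
    }
    if ll > 0:
        for name in ("LTE_LE", "LTE_LS", "LTE_EE", "LTE_ES", "LTE_SS"):
            raw[name] = raw[name] / ll
    return raw


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


def extract_all(
    sample: ImageSample,
    glcm_spec: GLCMSpec = GLCMSpec(),
    gabor_spec: GaborBankSpec = GaborBankSpec(),
    groups: Iterable[str] | None = None,
) -> FeatureVector:
    """Concatenate the four families in registry order (52 features)."""
    wanted = set(g.lower() for g in groups) if groups is not None else set(FEATURE_GROUPS)
    values: dict[str, float] = {}
    try:
        if "fos" in wanted:
            values.update(compute_fos(sample))
        if "glcm" in wanted:
            values.update(compute_glcm_features(sample, glcm_spec))
        if "gabor" in wanted:
            values.update(compute_gabor_features(sample, gabor_spec))
        if "lte" in wanted:
            values.update(compute_lte_features(sample))
    except FeatureError:
        raise
    except Exception as exc:  # pragma: no cover - identify the offending sample
        raise FeatureError(f"feature extraction failed for {sample.sample_id}: {exc}") from exc
    ordered = {n: values[n] for n in FEATURE_NAMES if family_of(n) in wanted}
    bad = [n for n, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise FeatureError(f"{sample.sample_id}: non-finite features {bad}")
    return FeatureVector(
        values=ordered,
        sample_id=sample.sample_id,
        eye_id=sample.eye_id,
        group=sample.group.value,
        modality=sample.modality.value,
        depth_fraction=sample.depth_fraction,
    )


def extract_table(
    samples: Iterable[ImageSample],
    glcm_spec: GLCMSpec = GLCMSpec(),
    gabor_spec: GaborBankSpec = GaborBankSpec(),
    groups: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Feature matrix for many samples: metadata columns + one column per feature."""
    rows = []
    for s in samples:
        fv = extract_all(s, glcm_spec=glcm_spec, gabor_spec=gabor_spec, groups=groups)
        row = {
            "sample_id": s.sample_id,
            "eye_id": s.eye_id,
            "patient_id": s.patient_id,
            "group": s.group.value,
            "modality": s.modality.value,
            "depth_fraction": s.depth_fraction,
            "slice_index": s.slice_index,
        }
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)
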