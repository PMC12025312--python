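"""Classification performance as a function of normalized choroid depth.

The en face stack of each eye is split into consecutive windows covering a
fixed fraction of choroid thickness (10% by default).  Cross-validation is
repeated within each window — training and test sets both restricted to the
window's slices — and the trend of mean accuracy against depth is summarized
by an OLS slope, reported in accuracy percentage points per 10% depth step,
with a percentile bootstrap CI obtained by resampling eyes and refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import CVResult, run_cv

__all__ = ["DepthProfile", "depth_sweep", "fit_depth_trend"]


@dataclass
class DepthBin:
    start_slice: int
    depth_fraction: float  # centre of the window in normalized depth
    result: CVResult


@dataclass
class DepthProfile:
    bins: list[DepthBin]
    slope_per_10pct: float | None = None
    slope_ci: tuple[float, float] | None = None

    def accuracy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_slice": [b.start_slice for b in self.bins],
                "depth_fraction": [b.depth_fraction for b in self.bins],
                "mean_accuracy": [b.result.mean_accuracy for b in self.bins],
                "accuracy_ci_lo": [b.result.accuracy_ci[0] for b in self.bins],
                "accuracy_ci_hi": [b.result.accuracy_ci[1] for b in self.bins],
                "auc": [b.result.auc for b in self.bins],
            }
        )


def depth_sweep(
    features: pd.DataFrame,
    groups: tuple[str, str],
    n_slices: int,
    bin_width: int | None = None,
    feature_subset: list[str] | None = None,
    **cv_kwargs,
) -> DepthProfile:
    """Windowed CV over the en face stack.

    ``bin_width`` defaults to 10% of ``n_slices``.  Windows start at
    0, bin_width, 2*bin_width, ... and are sample-disjoint.
    """
    enface = features[features["modality"] == "enface"]
    if enface.empty:
        raise ValueError("no en face samples in the feature table")
    if bin_width is None:
        bin_width = max(1, n_slices // 10)
    bins: list[DepthBin] = []
    for start in range(0, n_slices - bin_width + 1, bin_width):
        window = enface[
            (enface["slice_index"] >= start) & (enface["slice_index"] < start + bin_width)
        ]
        if window.empty:
            import warnings

            warnings.warn(f"depth window starting at slice {start} is empty; skipped")
            continue
        res = run_cv(window, groups, feature_subset=feature_subset, **cv_kwargs)
        centre = (start + bin_width / 2.0) / n_slices
        bins.append(DepthBin(start_slice=start, depth_fraction=centre, result=res))
    return DepthProfile(bins=bins)


def _ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def fit_depth_trend(
    profile: DepthProfile,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> DepthProfile:
    """OLS slope of per-bin mean accuracy (percent) on depth, per 10% step.

    The point estimate regresses the per-bin mean accuracies on the bin
    centres; the CI resamples eyes with replacement, recomputes each bin's
    mean accuracy from the resampled eyes present in that bin, and refits.
    """
    if len(profile.bins) < 3:
        raise ValueError("need >= 3 depth bins to fit a trend")
    depth_steps = np.array([b.depth_fraction / 0.10 for b in profile.bins])  # in 10% units
    acc_pct = np.array([b.result.mean_accuracy * 100.0 for b in profile.bins])
    profile.slope_per_10pct = _ols_slope(acc_pct, depth_steps)

    eyes = sorted({e for b in profile.bins for e in b.result.per_eye_accuracy})
    # per-bin per-eye accuracy matrix (NaN where an eye is absent from a bin)
    acc = np.full((len(profile.bins), len(eyes)), np.nan)
    eye_pos = {e: i for i, e in enumerate(eyes)}
    for bi, b in enumerate(profile.bins):
        for e, v in b.result.per_eye_accuracy.items():
            acc[bi, eye_pos[e]] = v
    rng = np.random.default_rng(seed)
    slopes = []
    n_eyes = len(eyes)
    for _ in range(n_boot):
        chosen = rng.integers(0, n_eyes, size=n_eyes)
        sub = acc[:, chosen]
        with np.errstate(invalid="ignore"):
            means = np.nanmean(sub, axis=1) * 100.0
        ok = np.isfinite(means)
        if ok.sum() < 3:
            continue
        slopes.append(_ols_slope(means[ok], depth_steps[ok]))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(slopes, [alpha, 1.0 - alpha])
    profile.slope_ci = (float(lo), float(hi))
    return profile
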