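"""Feature-level group comparison: z-scoring, unpaired t-tests, Bonferroni, ranking.

Comparisons operate at the image level by default, matching the study design
being replicated (images within an eye are correlated; an eye-level
aggregation mode — mean feature per eye — is available via ``unit='eye'``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, family_of

__all__ = ["zscore_global", "compare_groups", "top_features"]


def zscore_global(
    features: pd.DataFrame | np.ndarray,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each feature across all images (population std).

    Returns the normalized matrix and the per-feature (mean, std) used, so the
    same transform can be applied elsewhere.  Zero-variance features are left
    at 0 with a warning.
    """
    values = np.asarray(features, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    flat = std == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance feature(s) left at 0 after centering")
    z = (values - mean) / np.where(flat, 1.0, std)
    if isinstance(features, pd.DataFrame):
        z = pd.DataFrame(z, index=features.index, columns=features.columns)
    return z, mean, std


def _welch_or_pooled(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    if a.std() == 0 and b.std() == 0:
        return 0.0, 1.0  # degenerate variance in both groups
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if not np.isfinite(t):
        return 0.0, 1.0
    return float(t), float(p)


def compare_groups(
    features: pd.DataFrame,
    groups: tuple[str, str],
    feature_names: list[str] | None = None,
    equal_var: bool = False,
    unit: str = "image",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature unpaired t-test between two groups with Bonferroni correction.

    Parameters
    ----------
    features
        Table from :func:`choroidtex.features.extract_table` (metadata columns
        plus feature columns).
    groups
        The two group labels to compare, e.g. ``("healthy", "cscr")``.
    equal_var
        False (default) for Welch's t; True for the pooled-variance test.
    unit
        'image' tests every image as an observation; 'eye' first averages
        features within each eye.

    Returns a DataFrame indexed by feature with columns ``t``, ``p_raw``,
    ``p_bonferroni``, ``significant``, group means/medians, ``family`` and
    ``rank_in_family`` (by raw p; ties broken by |t| then name).
    """
    if feature_names is None:
        feature_names = [c for c in features.columns if c in FEATURE_NAMES]
    if not feature_names:
        raise ValueError("no feature columns found")
    a_lbl, b_lbl = groups
    sub = features[features["group"].isin(groups)]
    if unit == "eye":
        sub = (
            sub.groupby(["eye_id", "group"], as_index=False)[feature_names].mean()
        )
    elif unit != "image":
        raise ValueError("unit must be 'image' or 'eye'")
    a = sub[sub["group"] == a_lbl]
    b = sub[sub["group"] == b_lbl]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"both groups need >= 2 observations (got {len(a)}, {len(b)})")

    n_tests = len(feature_names)
    rows = []
    for name in feature_names:
        av = a[name].to_numpy(dtype=float)
        bv = b[name].to_numpy(dtype=float)
        t, p = _welch_or_pooled(av, bv, equal_var)
        p_adj = min(1.0, p * n_tests)
        rows.append(
            {
                "feature": name,
                "family": family_of(name),
                "t": t,
                "p_raw": p,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
                f"mean_{a_lbl}": float(av.mean()),
                f"mean_{b_lbl}": float(bv.mean()),
                f"median_{a_lbl}": float(np.median(av)),
                f"median_{b_lbl}": float(np.median(bv)),
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    # rank within family by raw p, ties by |t| descending then name
    out["rank_in_family"] = 0
    for fam, sub_idx in out.groupby("family").groups.items():
        fam_tbl = out.loc[sub_idx]
        order = sorted(
            fam_tbl.index,
            key=lambda n: (fam_tbl.at[n, "p_raw"], -abs(fam_tbl.at[n, "t"]), n),
        )
        for r, name in enumerate(order, start=1):
            out.at[name, "rank_in_family"] = r
    return out


def top_features(comparison: pd.DataFrame, k: int = 2) -> dict[str, list[str]]:
    """The ``k`` best-ranked features of each family (smallest raw p first)."""
    out: dict[str, list[str]] = {}
    for fam, tbl in comparison.groupby("family"):
        if k > len(tbl):
            raise ValueError(f"k={k} exceeds family size {len(tbl)} for {fam}")
        out[fam] = list(tbl.sort_values("rank_in_family").index[:k])
    return out
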