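"""Leave-one-eye-out classification with leakage-safe normalization.

Every fold holds out all images of one eye; feature z-scoring parameters and
the logistic-regression weights are fit on the training eyes only and then
applied to the held-out eye.  Accuracy is summarized per eye (fraction of the
eye's images correct at probability threshold 0.5) with a percentile
bootstrap CI over eyes; ROC-AUC is computed on the pooled out-of-fold
predicted probabilities (a single eye contains one class, so per-eye AUC is
undefined) and its CI bootstraps eyes and re-pools.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .features import FEATURE_GROUPS, FEATURE_NAMES, feature_names

__all__ = [
    "CVResult",
    "TransferResult",
    "loeo_folds",
    "run_cv",
    "bootstrap_ci",
    "shuffle_control",
    "per_family_cv",
    "transfer_classify",
]


@dataclass
class FoldParams:
    """Training-set normalization and model parameters of one fold."""

    held_out: str
    mean: np.ndarray
    std: np.ndarray
    coef: np.ndarray
    intercept: float


@dataclass
class CVResult:
    per_eye_accuracy: dict[str, float]
    pooled_predictions: pd.DataFrame  # sample_id, eye_id, true_label, prob
    mean_accuracy: float
    accuracy_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    feature_subset: list[str]
    positive_label: str
    fold_params: list[FoldParams] = field(default_factory=list, repr=False)

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "n_eyes": len(self.per_eye_accuracy),
            "n_samples": int(len(self.pooled_predictions)),
            "positive_label": self.positive_label,
            "n_features": len(self.feature_subset),
        }


@dataclass
class TransferResult:
    """Fraction of a target group's images classified as the positive class."""

    fraction_positive: float
    ci: tuple[float, float]
    per_eye_fractions: dict[str, float]
    positive_label: str


def _feature_cols(features: pd.DataFrame, subset: list[str] | None) -> list[str]:
    if subset is None:
        subset = [c for c in features.columns if c in FEATURE_NAMES]
    missing = [c for c in subset if c not in features.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    if not subset:
        raise ValueError("empty feature subset")
    return list(subset)


def loeo_folds(
    features: pd.DataFrame, groups: tuple[str, str], unit: str = "eye"
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """One fold per eye (or per patient): (held-out id, train index, test index).

    Eyes with zero samples of the requested groups are impossible by
    construction here; empty folds are skipped with a warning.
    """
    if unit not in ("eye", "patient"):
        raise ValueError("unit must be 'eye' or 'patient'")
    sub = features[features["group"].isin(groups)]
    for g in groups:
        if sub[sub["group"] == g]["eye_id"].nunique() < 2:
            raise ValueError(f"need >= 2 eyes in group {g!r}")
    key = "eye_id" if unit == "eye" else "patient_id"
    folds = []
    for unit_id in sorted(sub[key].unique()):
        test_mask = sub[key] == unit_id
        if not test_mask.any():  # pragma: no cover - defensive
            warnings.warn(f"{key} {unit_id} has no samples; skipped")
            continue
        folds.append(
            (str(unit_id), sub.index[~test_mask].to_numpy(), sub.index[test_mask].to_numpy())
        )
    return folds


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """L2-penalized logistic regression (unit penalty); stronger penalty on retry."""
    for C in (1.0, 0.1):
        clf = LogisticRegression(penalty="l2", C=C, solver="lbfgs", max_iter=2000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X, y)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return clf
        warnings.warn(f"logistic fit did not converge at C={C}; retrying with stronger penalty")
    return clf


def _zscore_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def run_cv(
    features: pd.DataFrame,
    groups: tuple[str, str],
    feature_subset: list[str] | None = None,
    unit: str = "eye",
    n_boot: int = 1000,
    seed: int = 0,
    keep_fold_params: bool = False,
) -> CVResult:
    """Leave-one-eye-out cross-validation of a two-group image classifier.

    The second label in ``groups`` is the positive class; its predicted
    probability is reported for every out-of-fold sample.
    """
    cols = _feature_cols(features, feature_subset)
    positive = groups[1]
    folds = loeo_folds(features, groups, unit=unit)
    per_eye_acc: dict[str, float] = {}
    pred_rows = []
    fold_params: list[FoldParams] = []
    for held_out, train_idx, test_idx in folds:
        train = features.loc[train_idx]
        test = features.loc[test_idx]
        Xtr = train[cols].to_numpy(dtype=float)
        ytr = (train["group"] == positive).to_numpy()
        mean, std = _zscore_train(Xtr)
        clf = _fit_logistic((Xtr - mean) / std, ytr)
        Xte = (test[cols].to_numpy(dtype=float) - mean) / std
        prob = clf.predict_proba(Xte)[:, list(clf.classes_).index(True)]
        correct = (prob >= 0.5) == (test["group"] == positive).to_numpy()
        for eye_id, eye_mask in test.groupby("eye_id").groups.items():
            acc = float(correct[test.index.get_indexer(eye_mask)].mean())
            per_eye_acc[str(eye_id)] = acc
        pred_rows.append(
            pd.DataFrame(
                {
                    "sample_id": test["sample_id"].to_numpy(),
                    "eye_id": test["eye_id"].to_numpy(),
                    "true_label": test["group"].to_numpy(),
                    "prob": prob,
                }
            )
        )
        if keep_fold_params:
            fold_params.append(
                FoldParams(
                    held_out=held_out,
                    mean=mean,
                    std=std,
                    coef=clf.coef_.ravel().copy(),
                    intercept=float(clf.intercept_[0]),
                )
            )
    pooled = pd.concat(pred_rows, ignore_index=True)
    acc_values = np.array(list(per_eye_acc.values()))
    mean_acc = float(acc_values.mean())
    rng = np.random.default_rng(seed)
    acc_ci = bootstrap_ci(acc_values, n_iter=n_boot, rng=rng)
    auc = float(
        roc_auc_score((pooled["true_label"] == positive).to_numpy(), pooled["prob"].to_numpy())
    )
    auc_ci = _bootstrap_auc_ci(pooled, positive, n_iter=n_boot, rng=rng)
    return CVResult(
        per_eye_accuracy=per_eye_acc,
        pooled_predictions=pooled,
        mean_accuracy=mean_acc,
        accuracy_ci=acc_ci,
        auc=auc,
        auc_ci=auc_ci,
        feature_subset=cols,
        positive_label=positive,
        fold_params=fold_params,
    )


def bootstrap_ci(
    values: np.ndarray,
    n_iter: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean, resampling eyes with replacement."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values to bootstrap")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_iter, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _bootstrap_auc_ci(
    pooled: pd.DataFrame,
    positive: str,
    n_iter: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap eyes, re-pool their predictions, recompute AUC each replicate."""
    if rng is None:
        rng = np.random.default_rng()
    eyes = pooled["eye_id"].unique()
    by_eye_true = {e: (pooled.loc[pooled["eye_id"] == e, "true_label"] == positive).to_numpy() for e in eyes}
    by_eye_prob = {e: pooled.loc[pooled["eye_id"] == e, "prob"].to_numpy() for e in eyes}
    aucs = []
    for _ in range(n_iter):
        chosen = rng.choice(eyes, size=eyes.size, replace=True)
        y = np.concatenate([by_eye_true[e] for e in chosen])
        p = np.concatenate([by_eye_prob[e] for e in chosen])
        if y.all() or not y.any():
            continue  # single-class replicate: AUC undefined
        aucs.append(roc_auc_score(y, p))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def shuffle_control(
    features: pd.DataFrame,
    groups: tuple[str, str],
    seed: int = 0,
    **cv_kwargs,
) -> CVResult:
    """Permute group labels across eyes (whole eyes keep one label) and rerun CV.

    Group sizes in eyes are preserved; all images of an eye share the
    reassigned label, so the permutation destroys real signal while keeping
    the within-eye correlation structure.
    """
    sub = features[features["group"].isin(groups)].copy()
    eye_group = sub.groupby("eye_id")["group"].first()
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(eye_group.to_numpy())
    new_label = dict(zip(eye_group.index, shuffled))
    sub["group"] = sub["eye_id"].map(new_label)
    return run_cv(sub, groups, seed=seed, **cv_kwargs)


def per_family_cv(
    features: pd.DataFrame,
    groups: tuple[str, str],
    families: list[str] | None = None,
    **cv_kwargs,
) -> tuple[dict[str, CVResult], pd.DataFrame]:
    """CV restricted to each feature family, plus pairwise paired t-tests.

    Families are compared on per-eye accuracies paired by held-out eye
    (two-tailed paired t-test).
    """
    families = families or list(FEATURE_GROUPS)
    results = {}
    for fam in families:
        subset = [c for c in feature_names([fam]) if c in features.columns]
        if not subset:
            raise ValueError(f"no columns of family {fam!r} in the feature table")
        results[fam] = run_cv(features, groups, feature_subset=subset, **cv_kwargs)
    rows = []
    for f1, f2 in itertools.combinations(families, 2):
        eyes = sorted(results[f1].per_eye_accuracy)
        a = np.array([results[f1].per_eye_accuracy[e] for e in eyes])
        b = np.array([results[f2].per_eye_accuracy[e] for e in eyes])
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append({"family_a": f1, "family_b": f2, "t": float(t), "p": float(p)})
    return results, pd.DataFrame(rows)


def transfer_classify(
    features: pd.DataFrame,
    train_groups: tuple[str, str] = ("healthy", "cscr"),
    target_group: str = "fellow",
    feature_subset: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> TransferResult:
    """Train once on the two training groups, score every target-group image.

    Reports the fraction of target images whose predicted label is the
    positive training class (threshold 0.5), with a bootstrap CI over target
    eyes re-pooling their images.
    """
    cols = _feature_cols(features, feature_subset)
    positive = train_groups[1]
    train = features[features["group"].isin(train_groups)]
    target = features[features["group"] == target_group]
    if train.empty or target.empty:
        raise ValueError("empty training or target set")
    Xtr = train[cols].to_numpy(dtype=float)
    mean, std = _zscore_train(Xtr)
    clf = _fit_logistic((Xtr - mean) / std, (train["group"] == positive).to_numpy())
    Xte = (target[cols].to_numpy(dtype=float) - mean) / std
    prob = clf.predict_proba(Xte)[:, list(clf.classes_).index(True)]
    classified = prob >= 0.5
    per_eye = {
        str(e): float(classified[target.index.get_indexer(idx)].mean())
        for e, idx in target.groupby("eye_id").groups.items()
    }
    eyes = sorted(per_eye)
    counts = {e: int((target["eye_id"] == e).sum()) for e in eyes}
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_boot):
        chosen = rng.choice(eyes, size=len(eyes), replace=True)
        num = sum(per_eye[e] * counts[e] for e in chosen)
        den = sum(counts[e] for e in chosen)
        fracs.append(num / den)
    lo, hi = np.quantile(fracs, [0.025, 0.975])
    return TransferResult(
        fraction_positive=float(classified.mean()),
        ci=(float(lo), float(hi)),
        per_eye_fractions=per_eye,
        positive_label=positive,
    )
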