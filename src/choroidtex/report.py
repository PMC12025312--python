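"""End-to-end orchestration: simulate -> extract -> compare -> classify -> depth.

``run_pipeline`` reproduces the full experiment grid on a (by default
synthetic) cohort: three pairwise group comparisons at the feature level,
leave-one-eye-out classification per modality with shuffle control and
per-family breakdown, fellow-eye transfer, and the depth profile — all
deterministically seeded from one configuration value.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classification, depth, group_stats
from .features import FEATURE_GROUPS, extract_table, feature_names
from .roi_model import CohortDataset, load_cohort
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

COMPARISONS = [("healthy", "cscr"), ("healthy", "fellow"), ("cscr", "fellow")]


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    manifest: str | None = None  # load a cohort instead of simulating one
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    modalities: tuple[str, ...] = ("horizontal", "enface")
    comparisons: tuple[tuple[str, str], ...] = tuple(COMPARISONS)
    families: tuple[str, ...] = tuple(FEATURE_GROUPS)
    fold_unit: str = "eye"
    n_boot: int = 1000
    depth_bin_fraction: float = 0.10
    run_depth: bool = True
    run_transfer: bool = True
    run_shuffle: bool = True
    run_families: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.setdefault("comparisons", COMPARISONS)
        raw["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        raw["modalities"] = tuple(raw.get("modalities", ("horizontal", "enface")))
        raw["families"] = tuple(raw.get("families", tuple(FEATURE_GROUPS)))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _cohort(config: RunConfig) -> CohortDataset:
    if config.manifest:
        return load_cohort(config.manifest)
    syn = dict(config.synthetic)
    syn.setdefault("seed", config.seed)
    if set(syn) - {"seed"}:
        return generate_cohort(SyntheticConfig(**syn))
    return generate_cohort(SyntheticConfig.desk_scale(seed=syn["seed"]))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write features, tables, and a JSON summary to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = feature_names(config.families)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    collected_warnings: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        dataset = _cohort(config)
        report["stages"]["simulate"] = {
            "n_eyes": len(dataset.eyes),
            "n_samples": sum(e.n_samples for e in dataset.eyes),
        }

        tables: dict[str, pd.DataFrame] = {}
        for modality in config.modalities:
            tbl = extract_table(dataset.samples(modality), groups=config.families)
            tbl.to_csv(out / f"features_{modality}.csv", index=False)
            tables[modality] = tbl
        report["stages"]["extract"] = {m: len(t) for m, t in tables.items()}

        comparisons_out = {}
        for modality, tbl in tables.items():
            for pair in config.comparisons:
                cmp_tbl = group_stats.compare_groups(tbl, pair, feature_names=cols)
                name = f"comparison_{modality}_{pair[0]}_vs_{pair[1]}"
                cmp_tbl.to_csv(out / f"{name}.csv")
                comparisons_out[name] = {
                    "n_significant": int(cmp_tbl["significant"].sum()),
                    "top_features": group_stats.top_features(cmp_tbl, k=2),
                }
        report["stages"]["compare"] = comparisons_out

        classify_out = {}
        for modality, tbl in tables.items():
            for pair in config.comparisons:
                res = classification.run_cv(
                    tbl,
                    pair,
                    feature_subset=cols,
                    unit=config.fold_unit,
                    n_boot=config.n_boot,
                    seed=config.seed,
                )
                entry = {"cv": res.summary()}
                if config.run_shuffle and pair == ("healthy", "cscr"):
                    entry["shuffle"] = classification.shuffle_control(
                        tbl, pair, seed=config.seed, n_boot=config.n_boot
                    ).summary()
                if config.run_families and pair == ("healthy", "cscr"):
                    fam_res, fam_cmp = classification.per_family_cv(
                        tbl,
                        pair,
                        families=list(config.families),
                        n_boot=config.n_boot,
                        seed=config.seed,
                    )
                    entry["families"] = {f: r.summary() for f, r in fam_res.items()}
                    entry["family_comparison"] = fam_cmp.to_dict(orient="records")
                classify_out[f"{modality}_{pair[0]}_vs_{pair[1]}"] = entry
        report["stages"]["classify"] = classify_out

        if config.run_transfer and any(e.group.value == "fellow" for e in dataset.eyes):
            transfer_out = {}
            for modality, tbl in tables.items():
                tr = classification.transfer_classify(
                    tbl, feature_subset=cols, n_boot=config.n_boot, seed=config.seed
                )
                transfer_out[modality] = {
                    "fraction_classified_cscr": tr.fraction_positive,
                    "ci": list(tr.ci),
                }
            report["stages"]["transfer"] = transfer_out

        if config.run_depth and "enface" in tables:
            n_slices = int(tables["enface"]["slice_index"].max()) + 1
            bin_width = max(1, round(n_slices * config.depth_bin_fraction))
            profile = depth.depth_sweep(
                tables["enface"],
                ("healthy", "cscr"),
                n_slices=n_slices,
                bin_width=bin_width,
                feature_subset=cols,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            profile = depth.fit_depth_trend(profile, n_boot=config.n_boot, seed=config.seed)
            profile.accuracy_table().to_csv(out / "depth_profile.csv", index=False)
            report["stages"]["depth"] = {
                "slope_per_10pct": profile.slope_per_10pct,
                "slope_ci": list(profile.slope_ci),
                "n_bins": len(profile.bins),
            }
        collected_warnings = [str(w.message) for w in caught]

    report["warnings"] = collected_warnings
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
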