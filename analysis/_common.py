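"""Shared settings for the numbered analysis drivers.

One desk-scale synthetic cohort (10 eyes per group, 20 b-scans and 50 en face
slices per eye, 64x256 px b-scans) is used by every step; the feature tables
are cached under results/ so later steps do not recompute them.
"""

from pathlib import Path

import pandas as pd

from choroidtex import SyntheticConfig, extract_table, generate_cohort

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def cohort_config() -> SyntheticConfig:
    return SyntheticConfig.desk_scale(seed=SEED)


def feature_tables() -> dict[str, pd.DataFrame]:
    """Load cached feature tables, extracting them first if missing."""
    RESULTS.mkdir(exist_ok=True)
    paths = {m: RESULTS / f"features_{m}.csv" for m in ("horizontal", "enface")}
    if not all(p.exists() for p in paths.values()):
        dataset = generate_cohort(cohort_config())
        for m, p in paths.items():
            extract_table(dataset.samples(m)).to_csv(p, index=False)
    return {m: pd.read_csv(p) for m, p in paths.items()}
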