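"""Feature-level group comparisons with Bonferroni correction.

For each modality and each pair (healthy vs CSCR, healthy vs fellow, CSCR vs
fellow): Welch t-test per feature at the image level, Bonferroni over the 52
features, top-2 features per family.  Writes one CSV per comparison plus a
summary of significant-feature counts.
"""

import sys
from pathlib import Path

import pandas as pd

from choroidtex import compare_groups, top_features

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, feature_tables

PAIRS = [("healthy", "cscr"), ("healthy", "fellow"), ("cscr", "fellow")]


def main() -> None:
    tables = feature_tables()
    summary = []
    for modality, tbl in tables.items():
        for a, b in PAIRS:
            cmp_tbl = compare_groups(tbl, (a, b))
            cmp_tbl.to_csv(RESULTS / f"comparison_{modality}_{a}_vs_{b}.csv")
            by_family = cmp_tbl.groupby("family")["significant"].sum()
            top2 = top_features(cmp_tbl, k=2)
            summary.append(
                {
                    "modality": modality,
                    "comparison": f"{a}_vs_{b}",
                    "n_significant": int(cmp_tbl["significant"].sum()),
                    **{f"sig_{f}": int(v) for f, v in by_family.items()},
                }
            )
            print(f"{modality} {a} vs {b}: {int(cmp_tbl['significant'].sum())}/52 significant; top-2 {top2}")
    pd.DataFrame(summary).to_csv(RESULTS / "comparison_summary.csv", index=False)


if __name__ == "__main__":
    main()
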