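"""Classification accuracy as a function of normalized choroid depth.

Repeats healthy-vs-CSCR LOEO classification inside consecutive 10%-of-depth
en face windows, then fits the accuracy-vs-depth OLS slope with an eye-level
bootstrap CI.  Writes results/depth_profile.csv and results/depth_trend.json.
"""

import json
import sys
from pathlib import Path

from choroidtex import depth_sweep, fit_depth_trend

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, cohort_config, feature_tables


def main() -> None:
    enface = feature_tables()["enface"]
    n_slices = cohort_config().enface_slices_per_eye
    profile = depth_sweep(enface, ("healthy", "cscr"), n_slices=n_slices, seed=SEED)
    profile = fit_depth_trend(profile, seed=SEED)
    tbl = profile.accuracy_table()
    tbl.to_csv(RESULTS / "depth_profile.csv", index=False)
    (RESULTS / "depth_trend.json").write_text(
        json.dumps(
            {
                "slope_pct_per_10pct_depth": profile.slope_per_10pct,
                "slope_ci": list(profile.slope_ci),
            },
            indent=2,
        )
    )
    print(tbl.to_string(index=False))
    print(
        f"accuracy slope {profile.slope_per_10pct:+.2f}% per 10% depth "
        f"(95% CI {profile.slope_ci[0]:+.2f} to {profile.slope_ci[1]:+.2f})"
    )


if __name__ == "__main__":
    main()
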