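"""Leave-one-eye-out classification of healthy vs CSCR eyes.

Full-feature LOEO accuracy and pooled ROC-AUC with 95% bootstrap CIs for
both modalities, an eye-level shuffle control, and the per-family breakdown
with paired comparisons.  Writes results/classification.json.
"""

import json
import sys
from pathlib import Path

from choroidtex import per_family_cv, run_cv, shuffle_control

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, feature_tables


def main() -> None:
    tables = feature_tables()
    out = {}
    for modality, tbl in tables.items():
        res = run_cv(tbl, ("healthy", "cscr"), seed=SEED)
        sh = shuffle_control(tbl, ("healthy", "cscr"), seed=SEED)
        fams, fam_cmp = per_family_cv(tbl, ("healthy", "cscr"), seed=SEED)
        out[modality] = {
            "cv": res.summary(),
            "shuffle": sh.summary(),
            "families": {f: r.summary() for f, r in fams.items()},
            "family_comparison": fam_cmp.to_dict(orient="records"),
        }
        print(
            f"{modality}: accuracy {res.mean_accuracy:.1%} "
            f"({res.accuracy_ci[0]:.1%}-{res.accuracy_ci[1]:.1%}), "
            f"AUC {res.auc:.3f} ({res.auc_ci[0]:.3f}-{res.auc_ci[1]:.3f}); "
            f"shuffle accuracy {sh.mean_accuracy:.1%}"
        )
    (RESULTS / "classification.json").write_text(json.dumps(out, indent=2))
    print("-> results/classification.json")


if __name__ == "__main__":
    main()
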