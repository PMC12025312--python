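"""Are unaffected fellow eyes of CSCR patients healthy-like or CSCR-like?

Trains the healthy-vs-CSCR classifier on all labelled images, scores every
fellow-eye image, and reports the fraction classified CSCR with a bootstrap
CI over fellow eyes; also runs healthy-vs-fellow and CSCR-vs-fellow LOEO
classification.  Writes results/transfer.json.
"""

import json
import sys
from pathlib import Path

from choroidtex import run_cv, transfer_classify

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, feature_tables


def main() -> None:
    tables = feature_tables()
    out = {}
    for modality, tbl in tables.items():
        tr = transfer_classify(tbl, seed=SEED)
        hv = run_cv(tbl, ("healthy", "fellow"), seed=SEED)
        cv = run_cv(tbl, ("cscr", "fellow"), seed=SEED)
        out[modality] = {
            "fellow_classified_cscr": tr.fraction_positive,
            "ci": list(tr.ci),
            "healthy_vs_fellow": hv.summary(),
            "cscr_vs_fellow": cv.summary(),
        }
        print(
            f"{modality}: {tr.fraction_positive:.1%} of fellow images classified CSCR "
            f"({tr.ci[0]:.1%}-{tr.ci[1]:.1%}); healthy-vs-fellow accuracy "
            f"{hv.mean_accuracy:.1%}, cscr-vs-fellow accuracy {cv.mean_accuracy:.1%}"
        )
    (RESULTS / "transfer.json").write_text(json.dumps(out, indent=2))
    print("-> results/transfer.json")


if __name__ == "__main__":
    main()
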