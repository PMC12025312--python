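"""Extract the 52-feature registry from every b-scan and en face slice.

Writes results/features_horizontal.csv and results/features_enface.csv
(one row per image: eye metadata + 52 feature columns in registry order).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import feature_tables


def main() -> None:
    tables = feature_tables()
    for modality, tbl in tables.items():
        n_feat = sum(c.startswith(("FOS", "GLCM", "GABOR", "LTE")) for c in tbl.columns)
        print(f"{modality}: {len(tbl)} images x {n_feat} features -> results/features_{modality}.csv")


if __name__ == "__main__":
    main()
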