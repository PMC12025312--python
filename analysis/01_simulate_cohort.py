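"""Synthesize the study cohort and record its structure.

Generates the desk-scale synthetic cohort (10 healthy / 10 CSCR / 10 fellow
eyes; 20 b-scans and 50 en face slices per eye) and writes the per-eye
manifest to results/cohort_manifest.csv.  Pass --dump-images to also write
every image/mask as PNG under scratch/cohort/ for visual inspection.
"""

import argparse
import sys
from pathlib import Path

from choroidtex import generate_cohort, save_cohort

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, cohort_config


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dump-images", action="store_true")
    args = ap.parse_args()

    cfg = cohort_config()
    dataset = generate_cohort(cfg)
    RESULTS.mkdir(exist_ok=True)
    manifest = dataset.manifest
    manifest.to_csv(RESULTS / "cohort_manifest.csv", index=False)
    print(manifest.groupby("group")[["n_horizontal", "n_enface"]].sum())
    print(f"{len(dataset.eyes)} eyes, seed {cfg.seed}; manifest -> results/cohort_manifest.csv")
    if args.dump_images:
        out = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
        path = save_cohort(dataset, out)
        print(f"images written under {out} (manifest {path})")


if __name__ == "__main__":
    main()
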