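"""Compute the three streamline-count-invariant graph measures per method.

For the reference and each harmonized cohort under scratch/cohort/, computes
modularity (raw counts), global efficiency (max-normalized counts) and average
betweenness centrality (mean lengths), and writes one measure table per method
under results/measures/.
"""

import argparse
from pathlib import Path

from connharm.io import WEIGHTINGS, read_cohort, read_manifest
from connharm.measures import compute_all

COHORT = Path("scratch/cohort")
OUT = Path("results/measures")

METHOD_DIRS = {
    "reference": COHORT / "matrices",
    "shift_site1": COHORT / "matrices_shift_site1",
    "shift_site2": COHORT / "matrices_shift_site2",
    "combat": COHORT / "matrices_combat",
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    manifest = read_manifest(COHORT / "manifest.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    for method, mdir in METHOD_DIRS.items():
        if not mdir.exists():
            print(f"{method}: no matrices at {mdir} (run 02_harmonize.py first)")
            continue
        matrices = []
        for weighting in WEIGHTINGS:
            matrices.extend(read_cohort(mdir, manifest, weighting))
        table = compute_all(matrices, manifest)
        path = OUT / f"{method}.csv"
        with open(path, "w") as fh:
            fh.write(f"# seed={args.seed}\n")
            table.to_csv(fh, index=False)
        summary = table.groupby(["measure"])["value"].agg(["mean", "std"])
        print(f"{method}: wrote {path}")
        print(summary.to_string(), "\n")


if __name__ == "__main__":
    main()
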