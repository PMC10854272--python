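"""Evaluate every harmonization method on the two study criteria.

Criterion 1 (site-effect removal): pooled coefficient of variation and the
Mann-Whitney U test between the sites' graph-measure distributions.
Criterion 2 (biological variability): Pearson correlation between age and
each measure on the pooled cohort.

Writes the three report tables (age correlations, U tests, CoV) under
results/reports/ and prints which methods pass each criterion.
"""

import argparse
from pathlib import Path

import pandas as pd

from connharm.evaluation import evaluate_all
from connharm.io import read_manifest

MEASURES_DIR = Path("results/measures")
OUT = Path("results/reports")


def main() -> None:
    argparse.ArgumentParser().parse_args()
    manifest = read_manifest(Path("scratch/cohort/manifest.csv"))
    tables = {
        p.stem: pd.read_csv(p, dtype={"subject_id": str}, comment="#")
        for p in sorted(MEASURES_DIR.glob("*.csv"))
    }
    report = evaluate_all(tables, manifest)
    paths = report.write(OUT)
    for name, path in paths.items():
        print(f"wrote {name} table -> {path}")

    t = report.table
    print("\nsite-effect removal (Mann-Whitney p > 0.05 = removed):")
    for _, row in t.iterrows():
        verdict = "removed" if row.u_p > 0.05 else f"remains{row.u_sig}"
        print(f"  {row.method:>12} / {row.measure:<18} U={row.u_stat:7.1f} p={row.u_p:.3g} -> {verdict}")
    print("\nage associations (Pearson p < 0.05 = preserved):")
    for _, row in t.iterrows():
        verdict = "significant" + row.r_sig if row.r_p < 0.05 else "not significant"
        print(f"  {row.method:>12} / {row.measure:<18} r={row.r:+.3f} p={row.r_p:.3g} -> {verdict}")


if __name__ == "__main__":
    main()
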