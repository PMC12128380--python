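#!/usr/bin/env python
"""Associations between hypomethylation and clinical variables.

Group comparison (Mann-Whitney), pooled PSA Spearman for both assays,
and - on the stratified run - Kruskal-Wallis/Dunn across stage and
grade plus the per-sample ordinal regressions.
"""
import argparse
from pathlib import Path

from spdefmeth.io import read_table
from spdefmeth.pipeline import stage_associate

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
args = ap.parse_args()

for mode in ("group", "stratified"):
    outdir = args.results / f"run_{mode}"
    stage_associate(outdir)
    assoc = read_table(outdir / "associations.csv")
    print(f"\n[{mode} mode]")
    keep = assoc[
        ~assoc["analysis"].str.contains("dunn")
    ]  # pairwise rows stay in the table file
    for row in keep.itertuples():
        p = "" if row.p_value != row.p_value else f", p={row.p_value:.3g}"
        print(
            f"  {row.analysis:28s} {row.statistic_name:18s} "
            f"{row.statistic:8.4f}{p}"
        )
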