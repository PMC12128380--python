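#!/usr/bin/env python
"""Diagnostic performance of the <55% methylation rule on the group-mode run.

Builds the ROC curve (lower methylation = more PCa-like), reports the
trapezoidal AUC with its Hanley-McNeil standard error and 95% CI, and
the sensitivity/specificity of the fixed cutoff.
"""
import argparse
from pathlib import Path

from spdefmeth.io import read_table
from spdefmeth.pipeline import stage_diagnose

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
ap.add_argument("--cutoff", type=float, default=55.0)
args = ap.parse_args()

outdir = args.results / "run_group"
stage_diagnose(outdir, cutoff=args.cutoff)
d = read_table(outdir / "diagnostics_summary.csv").iloc[0]
print(
    f"AUC {d['auc']:.4f} (SE {d['auc_se']:.4f}, "
    f"95% CI {d['auc_ci95_low']:.4f}-{d['auc_ci95_high']:.4f})"
)
print(
    f"at <{args.cutoff:.0f}% cutoff: sensitivity {100 * d['sensitivity']:.1f}% "
    f"({d['tp']:.0f}/{d['tp'] + d['fn']:.0f}), "
    f"specificity {100 * d['specificity']:.1f}% ({d['tn']:.0f}/{d['tn'] + d['fp']:.0f})"
)
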