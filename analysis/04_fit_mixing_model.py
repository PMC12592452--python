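#!/usr/bin/env python
"""Fit the Bayesian mixing model to every consumer.

Each consumer's δ15N_Phe/δ15N_Lys/δ13C_Leu profile is inverted to posterior
source proportions over the three particle size fractions (ALR random-walk
Metropolis, three chains).  Medium and large fractions are pooled per draw
into the '>6 µm' class.  Use --schedule paper for the full
50k-adapt/40k-burn-in/100k-step/thin-50 schedule; the default reduced
schedule keeps the same structure at desk scale.
"""

import argparse

import pandas as pd

from midmix.pipeline import run_pipeline

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", default="results/pipeline")
ap.add_argument("--schedule", choices=("reduced", "paper"), default="reduced")
args = ap.parse_args()

run_pipeline({"seed": args.seed, "outdir": args.outdir,
              "schedule": args.schedule,
              "stages": ("simulate", "select", "mix")})
summary = pd.read_csv(f"{args.outdir}/mixing_summary.csv")
n_conv = int(summary["converged"].sum())
print(f"fit {len(summary)} consumers ({args.schedule} schedule); "
      f"{n_conv} converged (R-hat <= 1.05)")
print("pooled large-fraction (>6 µm) contribution, mean across consumers: "
      f"{summary['p_large_mean'].mean():.3f}")
print(f"table: {args.outdir}/mixing_summary.csv")
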