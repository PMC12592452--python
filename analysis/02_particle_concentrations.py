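#!/usr/bin/env python
"""Amino-acid concentration contrasts: background vs plume/discharge.

Flags concentration outliers (Tukey fences per sample-type x fraction
stratum), then contrasts background against pooled plume/discharge records
with a one-way ANOVA per size fraction.  In the study regime the medium and
large fractions differ strongly (background particles are an order of
magnitude richer in amino-acid nitrogen) while the small fraction does not.
"""

import argparse

from midmix.pipeline import run_pipeline

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", default="results/pipeline")
args = ap.parse_args()

manifest = run_pipeline({"seed": args.seed, "outdir": args.outdir,
                         "stages": ("simulate", "prep")})
print("one-way ANOVA, background vs plume/discharge (normalized ngN/µgPN):")
for row in manifest["aa_contrasts"]:
    verdict = "different" if row["p"] < 0.05 else "not distinguishable"
    print(f"  {row['fraction']:>6}: F = {row['F']:8.2f}, p = {row['p']:.4f}"
          f"  (n = {row['group_sizes']}) -> {verdict}")
print(f"tables: {args.outdir}/aa_conc_flagged.csv, aa_anova.csv")
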