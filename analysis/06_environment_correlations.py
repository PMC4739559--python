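#!/usr/bin/env python
"""Spearman correlations between environment and genetic diversity/TMRCA.

Joins the diversity and growth tables with the population covariates and
computes the survey-style correlation matrix (altitude, lake area, basin
area, precipitation x h, p, pi, TMRCA) with 9999-replicate permutation
p-values. Writes results/correlations.tsv.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from phylodem.correlate import correlation_table
from phylodem.io import read_population_table, write_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20160110


def main():
    records = read_population_table(Path("results/study/populations.tsv"))
    meta = pd.DataFrame([dataclasses.asdict(r) for r in records])
    div = pd.read_csv("results/diversity.tsv", sep="\t")
    growth = pd.read_csv("results/growth_summary.tsv", sep="\t")
    frame = (
        meta.drop(columns=["precipitation"])  # diversity table carries it too
        .merge(div, on="locality")
        .merge(growth[["locality", "tmrca_kya"]], on="locality")
        .rename(columns={"tmrca_kya": "tmrca"})
    )
    results = correlation_table(frame, reps=9999, seed=SEED)
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    df["rho"] = df["rho"].round(4)
    df["star"] = np.where(df.p_perm <= 0.01, "**", np.where(df.p_perm <= 0.05, "*", ""))
    write_table(df, Path("results/correlations.tsv"))
    print(df.to_string(index=False))
    sig = df[(df.covariate == "precipitation") & (df.p_perm <= 0.05)]
    print(f"\nprecipitation is significantly correlated with: {', '.join(sig.metric)}")


if __name__ == "__main__":
    main()
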