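#!/usr/bin/env python
"""Neutrality tests and mismatch sudden-expansion fits per population.

Tajima's D and Fu's Fs with 1000-replicate coalescent p-values, plus the
mismatch (tau, theta0, theta1) fit with SSD bootstrap and raggedness -
the demographic-history table of the survey. Writes results/demography.tsv.
"""

import math
import sys
from pathlib import Path

import pandas as pd

from phylodem.io import read_fasta, read_population_table, write_table
from phylodem.mismatch import fit_sudden_expansion, mismatch_distribution, ssd_pvalue
from phylodem.neutrality import neutrality_pvalues, neutrality_summary

STUDY = Path("results/study")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20160110


def main():
    records = read_population_table(STUDY / "populations.tsv")
    rows = []
    for i, rec in enumerate(records):
        aln = read_fasta(STUDY / f"{rec.locality}.fasta")
        row = dict(locality=rec.locality, n=aln.n)
        if aln.n >= 4:
            s = neutrality_summary(aln)
            if math.isfinite(s.D) or math.isfinite(s.Fs):
                s = neutrality_pvalues(s, reps=1000, seed=SEED + i)
            row.update(
                n_hap=s.n_hap, S=s.S,
                D=round(s.D, 4), p_D=s.p_D,
                Fs=round(s.Fs, 4), p_Fs=s.p_Fs,
            )
            spectrum = mismatch_distribution(aln)
            if spectrum.size >= 2:
                fit = fit_sudden_expansion(spectrum, aln.n)
                fit = ssd_pvalue(fit, reps=200, seed=SEED + i)
                row.update(
                    tau=round(fit.tau, 3),
                    tau_lo=round(fit.tau_ci[0], 3),
                    tau_hi=round(fit.tau_ci[1], 3),
                    ssd=round(fit.ssd, 4),
                    p_ssd=fit.p_ssd,
                    raggedness=round(fit.raggedness, 4),
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    write_table(df, Path("results/demography.tsv"))
    print(df.to_string(index=False))
    n_sig = int((df.get("p_Fs") <= 0.05).sum())
    print(f"\n{n_sig}/{len(df)} populations show significant Fu's Fs "
          f"(expansion signal) -> results/demography.tsv")


if __name__ == "__main__":
    main()
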