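# phylodem

Comparative phylogeography of high-plateau lake and river fish populations
from single-locus (mtDNA cytochrome *b*) haplotype data.

Endorheic lakes on the Qinghai–Tibetan plateau expand and shrink with the
strength of the South Asian summer monsoon, and the schizothoracine cyprinids
trapped in them record those fluctuations in their genes: populations grow
when lakes are high and bottleneck when they desiccate or freeze. This
package implements the full analysis chain used to read that record from a
set of population alignments plus environmental covariates (altitude, lake
area, basin area, precipitation):

1. **Diversity** — haplotype diversity *h* with Nei's SD, mean pairwise
   differences *p* (= k̂), per-site nucleotide diversity π, segregating
   sites *S*, under complete deletion of gapped/ambiguous columns.
2. **Neutrality tests** — Tajima's
   *D* = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)) and Fu's
   *F*ₛ = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the Ewens sampling
   formula at θ = k̂ (unsigned Stirling numbers evaluated in log space,
   stable to n = 1200), with coalescent-simulated p-values.
3. **Mismatch distributions** — the sudden-expansion model
   F_j(τ, θ₀, θ₁) fit by least squares (SSD), parametric-bootstrap
   goodness-of-fit, Harpending's raggedness index.
4. **Statistical-parsimony networks** — TCS-style 95% connection limit and
   a minimum-spanning network with inferred intermediates.
5. **Clock genealogies and skylines** — strict-clock UPGMA trees on
   p-distances (1.82%/Myr pairwise divergence ⇒ 0.91%/Myr per lineage),
   TMRCA in kya, classic/generalized skyline trajectories on a 1-kyr grid.
6. **Growth pulses** — per-millennium growth rates
   r = ln(N_{t₂}/N_{t₁})/t, growth onset, fastest-growth interval, and
   gap-rule clustering of per-population times at maximum growth.
7. **Environment correlations** — Spearman rank correlations (midranks)
   with permutation p-values between covariates and genetic metrics.

A coalescent **synthetic-data generator** (constant / sudden-expansion /
exponential demographies, finite-sites transition-biased mutation,
precipitation→diversity link on a spatial gradient) makes every stage
testable end to end without any sequence downloads.

## Worked example

```python
>>> from phylodem import haplotype_diversity, tajimas_d_from_counts, fus_fs_from_counts
>>> haplotype_diversity([47, 1])        # 48 sequences, two haplotypes
(np.float64(0.04166666666666672), 0.0395310917901727)
>>> tajimas_d_from_counts(48, 1, 47/1128)
-1.1068648011209505
>>> fus_fs_from_counts(48, 2, 47/1128)
-1.602186821112107
```

A lake sample of 48 fish containing a single variant individual has
h = 0.0417 ± 0.0395 and significantly negative neutrality statistics —
the classic footprint of a recent expansion from a small founder pool.

Clustering the published per-basin times at maximum skyline growth rate
with 1-kyr bins and a 10-kyr gap rule recovers three expansion pulses:

```python
>>> from phylodem import pulse_histogram
>>> from phylodem.published import growth_time_values
>>> pulse_histogram(growth_time_values(), gap_threshold=10.0).clusters
[(2.4, 14.9), (31.0, 39.6), (54.8, 64.7)]
```

i.e. post-LGM, late MIS 3 and early MIS 3 — each a phase of strong summer
monsoon and high lake levels.

The numbered drivers under `analysis/` run the whole study on synthetic
data (`python analysis/01_simulate_study.py`, then 02…06), writing tables
under `results/`. On the default 24-population study the final stage prints
a correlation matrix in which precipitation is the only covariate
significantly associated with diversity, e.g.

```
metric     covariate    rho  p_perm  n_used star
     h precipitation 0.8687  0.0001      24   **
 tmrca precipitation 0.7191  0.0003      24   **
```

mirroring the monsoon-gradient signal the method is designed to detect.

## Layout

- `src/phylodem/` — the library: `io`, `simulate`, `diversity`,
  `neutrality`, `mismatch`, `network`, `clock`, `growth`, `correlate`,
  plus a `phylodem` CLI with one subcommand per stage.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
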