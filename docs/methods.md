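# Methods

## Scope and data model

The package analyses aligned single-locus haplotype data (mtDNA cytochrome
*b*, canonically 1140 bp) sampled from many populations, together with
per-population environmental covariates. All statistics treat the locus as
non-recombining and selectively neutral; populations are analysed
independently (no migration model). Missing data are handled by **complete
deletion**: any column containing `-` or `N` in any sequence is removed
before haplotype collapsing, distances, and site counts. This matches the
default of the classic population-genetics packages this pipeline mirrors
and keeps every statistic internally consistent; pairwise deletion is
available for distances via `p_distance_matrix`.

## Diversity indices

For haplotype counts c₁…c_K (n = Σcᵢ, pᵢ = cᵢ/n):

- h = n(1 − Σpᵢ²)/(n − 1) (unbiased haplotype diversity),
- Var(h) = (2/(n(n−1))) · {2(n−2)[Σpᵢ³ − (Σpᵢ²)²] + Σpᵢ² − (Σpᵢ²)²}
  (Nei's estimator); the table reports √Var.
- p (= k̂) is the mean count of differing analysed sites over all C(n,2)
  sequence pairs, computed through haplotype multiplicities;
  π = p / (number of analysed sites).

Distances are raw differing-site counts (p-distance numerators) with no
substitution-model correction, consistent with the mismatch analysis.

## Neutrality tests

Tajima's D uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂)
and is undefined (NaN, flagged) when S = 0. Fu's Fs is the log-odds
ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the Ewens sampling formula at
θ = k̂: P(K=k) = |S₁(n,k)| θᵏ / (θ)₍ₙ₎. The unsigned Stirling numbers of
the first kind are built by the row recurrence in log space, so the
evaluation is stable at least to n = 1200 (the pooled-study scale). θ = k̂
rather than θ_S follows Fu's definition; both tails of the K distribution
are summed separately in log space so the smaller tail keeps full relative
precision.

Simulated p-values condition on θ: null samples are constant-size
coalescent simulations at θ = k̂ with the same n (infinite sites), and
p is the lower-tail fraction of simulated statistics ≤ observed — the
direction diagnostic of expansion. Whether the original software
conditions on S or on θ is not documented; θ-conditioning was chosen
because it matches the definition of both statistics. A two-sided option
exists. No special Fs significance cutoff (e.g. 0.02) is imposed; raw
p-values are reported.

## Mismatch distributions and the sudden-expansion model

The observed spectrum counts pairs at 0…d differences. The model: a
population at equilibrium diversity θ₀ jumps to θ₁ at mutational time
τ = 2ut before present. Conditioning on whether a pair coalesces after or
before the expansion gives

F_j(τ, θ₀, θ₁) = F_j(θ₁) · P[Γ(j+1) ≤ (1 + 1/θ₁)τ]
               + e^(−τ/θ₁) · Σ_m Pois(m; τ) F_{j−m}(θ₀),

with F_j(θ) = θʲ/(1+θ)^{j+1} the equilibrium geometric distribution. The
two limits are exact: τ = 0 reduces to F_j(θ₀) and τ → ∞ to F_j(θ₁); the
expectation sums to 1 within 1e−6 when truncated ~20 classes past the
observed maximum.

Fitting minimises the **ordinary** least-squares SSD between observed
relative frequencies and F_j over classes 0…d (the original software's
weighting is undocumented; OLS is the simplest defensible choice), under
0 ≤ θ₀ ≤ θ₁. The SSD surface is multimodal, so a coarse vectorised grid
(τ up to 2d; θ geometric grids up to 10⁴) precedes bounded Nelder–Mead
refinement. Goodness-of-fit is a parametric bootstrap: coalescent samples
under the fitted expansion, each refit, p = fraction of simulated SSDs ≥
observed; τ gets a percentile bootstrap interval from the same refits.

Calibration caveats. (1) The bootstrap simulates infinite-sites data while
real (and generated) alignments are finite-sites; at large n (≳100) the
test has power against this small model strain, so very small SSD
p-values in large samples should be read with that in mind. (2) The
refitting bootstrap inherits a known pathology of this family of tests:
when the least-squares fit collapses to the boundary (θ₀ → 0 and/or
θ₁ → ∞, the "star" limit), the fitted null has less genealogical variance
than a moderate true expansion, and the p-value over-rejects — empirically
~15–25% at the nominal 5% level for n = 30 samples from a moderate
expansion (τ = 3, θ₀ = 0.5, θ₁ = 10), driven entirely by
boundary-collapsed fits. Where the truth itself is in the star regime the
p-value is close to uniform (checked in the test suite at 30 datasets ×
100 bootstrap replicates). Treat marginal SSD rejections of samples whose
fitted θ₀ is 0 or θ₁ is at its bound with corresponding caution.

Harpending's raggedness r = Σ_{i=1}^{d+1}(x_i − x_{i−1})² is computed over
relative frequencies **with a terminal zero class appended**; this
convention is pinned by the published two-class value 0.8420 (and makes a
monomorphic spectrum score exactly 1).

## Statistical parsimony networks

The connection limit is the largest step count j whose parsimony
probability stays ≥ α (default 0.95). The estimator follows the classic
statistical-parsimony argument: the total substitution count M separating
a pair is given the neutral-coalescent geometric distribution with mean
set to the Jukes–Cantor-corrected estimate for j observed differences over
L sites; substitutions fall uniformly on sites; P(parsimony | j) is the
posterior probability that M = j with all sites distinct, using Stirling
numbers of the second kind for the occupancy term (multiple hits at a site
count as one observed difference). A running minimum over j makes the
criterion cumulative; as α → 0 every connection up to L steps is allowed.
For L = 1140 at 95% the limit is 10 steps. This is an independent
implementation of the published *definition*, not a port of the original
program; the test suite checks it against an exact-arithmetic oracle.

Network construction joins haplotype pairs in ascending distance order;
all pairs at one distance are judged against the components formed at
strictly smaller distances, so **tied alternative joins are all retained**
(loops permitted) rather than resolved by the original program's
frequency/topology tie-break cascade — a reproducible, conservative
divergence that is documented here deliberately. A j-step join inserts
j−1 frequency-0 intermediate nodes.

## Clock genealogies, TMRCA, skylines

The Bayesian MCMC genealogy sampler of the original workflow is replaced
by a deterministic desk-scale surrogate: an average-linkage (UPGMA)
ultrametric tree on uncorrected p-distances, with ties broken
lexicographically by smallest member label. Node heights are in
substitutions/site; the strict clock converts them to time.

**Rate convention.** The calibration 1.82%/Myr is treated as a *pairwise
divergence* rate, so the per-lineage rate is 0.91%/Myr and
TMRCA(kya) = root height / (0.0091 × 10⁻⁶ per year) / 1000. Published
calibrations of this kind are often ambiguous between per-lineage and
pairwise conventions; the choice is explicit in `ClockConfig` and
adjustable. Generation time is never specified by mtDNA data alone, so
skyline values carry scaled units (Nₑ × generation time); growth *rates*
are ratios and unaffected.

The classic skyline assigns the interval with k lineages and duration w
the scaled size k(k−1)w/2; with pooling tolerance ε > 0 adjacent intervals
are grouped (generalized skyline) until the composite width reaches ε, a
group with c coalescences estimating (Σ k(k−1)w/2)/c. Trajectories are
resampled onto a 1-kyr grid, preserving step values exactly at step
midpoints.

**Quantisation caveat.** The smallest nonzero p-distance (one site)
corresponds to ~48.2 kyr under the default clock, so low-diversity
populations show their first skyline step — and often their maximum
growth rate — at that quantum. The surrogate resolves expansion times
reliably only when they are older than this floor and younger than the
typical coalescent depth (checked as a weak-recovery property: the largest
backward-time decrease falls within [T/2, 2T] of a true expansion at T in
≥ 70% of replicates, and ≥ 60% of per-population times at maximum growth
fall within ±50% of T in the strong-expansion regime θ₁ ≫ τ).

## Growth rates and pulses

For consecutive 1-kyr grid times t₁ (older) and t₂ (younger),
r = ln(N_{t₂}/N_{t₁})/Δt per millennium; negative r means decline toward
the present. The series telescopes exactly to ln(N_present/N_oldest) and
is invariant to rescaling the trajectory by any positive constant.

- **Onset**: scanning old → young, the oldest time with r > 0 that stays
  positive for the next 3 grid intervals. The 3-interval persistence
  window suppresses single-step skyline noise; it is a parameter.
- **Maximum growth**: t_max is the older endpoint of the argmax interval;
  ties go to the youngest occurrence and are flagged. The fastest-growth
  interval is the maximal contiguous run containing t_max with
  r ≥ β·r_max, β = 0.5 by default — the published tables never define how
  their intervals were delimited, so β is this artifact's definition.
- **Pulses**: per-population t_max values are binned at 1 kyr and
  clustered into maximal runs with consecutive gaps ≤ 10 kyr. The 10-kyr
  gap is the unique small-integer threshold that resolves the published
  26-value growth-time column into its three reported pulses; it is
  recorded as calibrated to that table.

## Environment–diversity correlations

Spearman ρ is the product-moment correlation of midranks; p-values are
two-sided permutation tests, p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(reps + 1).
Permutation rather than the asymptotic t was chosen because surveys of
this kind have few populations (~16–34) and heavy ties in precipitation
(range-valued cells resolved to midpoints). Populations with a missing
covariate are dropped pairwise per correlation. No multiple-testing
correction is applied across the correlation matrix, matching the
original reporting. The published coefficients themselves (e.g. 0.7878
for h × precipitation) are **not** reproduction targets: which of the 34
localities enter each correlation, and how range-valued precipitation was
coded, are not documented.

## Synthetic data generator

`simulate_study` emulates the survey design: P = 24 populations (default;
the published table has 26 basin-level samples), per-population n drawn
uniformly from 7–162 (the published range), 1140-bp alignments,
precipitation on a shuffled spatial gradient over 61–487 mm/yr (the
published extremes) with 8% multiplicative jitter, diversity linked by
θᵢ = exp(a + b·log precipᵢ) (defaults a = −4.6, b = 1, giving θ ≈ 0.6–4.9
— the bulk of the published per-population k̂ range), and 60% of
populations suddenly expanded at τ = 3 (the modal published mismatch τ)
with θ₀/θ₁ = 0.05.

Genealogies come from the standard single-population coalescent with time
rescaling for non-constant size (piecewise-constant for sudden expansion,
exponential via closed-form hazard inversion). Time is in coalescent units
internally; τ = 2ut places the expansion at τ/θ₁ coalescent units.
Mutation is finite-sites with transition bias κ = 4 (a typical mtDNA
value; the full GTR fit of the original workflow is out of scope), root
sequence uniform, no indels; an infinite-sites overlay exists for oracle
comparisons. All randomness flows through one numpy Generator, so a fixed
seed reproduces outputs bit-exactly.

What the generator does **not** emulate: migration/secondary contact
between populations (the real survey excludes admixed haplotypes at basin
level), recombination, selection, rate heterogeneity among sites, and
spatial autocorrelation of covariates beyond the single gradient. Passing
tests therefore validate the estimators under the stated model, not the
historical conclusions drawn from the real data.

## Problem sizes in the test suite

Stochastic properties run at the sizes stated in their tests: 2000
replicates for simulator moments and Tajima-D calibration, 200 replicates
for skyline consistency, mismatch τ recovery, neutrality type-I error and
Fs power (inner p-value simulations at 200 replicates), the weak-recovery
skyline property, and the 12-population pulse-concentration property; the
SSD-bootstrap calibration runs scaled down at 30 datasets × 100 bootstrap
replicates. These sizes keep every estimate's Monte-Carlo error well
inside the asserted bands.

## Known limitations

- Single non-recombining locus: all demographic inference rides on one
  genealogy; confidence statements are conditional on that tree.
- The UPGMA/classic-skyline surrogate is noisier than the Bayesian
  skyline it stands in for and has the 48-kyr quantisation floor above;
  published Bayesian-MCMC-derived TMRCAs, onsets and divergence dates are
  out of its reach by design.
- Fu's Fs p-values and the SSD bootstrap inherit the infinite-sites null
  approximation.
- The TCS connection-limit estimator is a re-derivation of the published
  definition, not a byte-level reimplementation of the original program;
  tie-breaking in networks deliberately keeps loops.
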