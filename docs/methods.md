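# Methods

## The classification model

The classifier assumes per-animal average defeat latencies are drawn from a
bimodal distribution — one mode per coping style — and asks not just "which
cluster?" but "how stable is that assignment under resampling?". The
procedure is:

1. **Average latency.** Arithmetic mean of the daily latencies over an
   explicit day window (`(1, 7)` for a 7-day paradigm; `(1, 5)` when drug
   treatment begins on day 6). Censored encounters (no defeat within
   15 min) enter at the 900 s cap: censoring is informative — the animal
   resisted for the whole encounter — and the cap value is the natural
   lower bound on its latency.
2. **PAM, k = 2.** Partitioning around medoids with absolute (L1) distance
   on the one-dimensional averages. Medoids are data points and cluster
   medians under L1, so extreme or censored values cannot drag the centers
   the way k-means means would.
3. **Bootstrap stability.** For each of B iterations (default 10,000),
   draw n latencies with replacement from the original averages, refit
   PAM on the resample, and classify *every original* average by its
   nearest medoid of that fit, with the higher-medoid cluster labeled
   active. `p_active(i)` is the fraction of iterations classifying animal
   i active; it is an exact multiple of 1/B.
4. **Exclusion rule.** Labels: active if `p_active ≥ 0.9`, passive if
   `p_active ≤ 0.1`, excluded otherwise. The exclusion interval is open:
   the boundary values themselves are retained.

Design points that were genuinely open, and how they were settled:

* *Out-of-resample classification.* An original average need not appear in
  a given resample; classifying every original by the resample's nearest
  medoid keeps every animal scored in every iteration. On well-separated
  data this coincides with scoring only in-resample occurrences.
* *Label alignment.* Active copers resist longer, so the cluster with the
  larger medoid is "active" in every iteration. On cohorts so small that a
  resample can land entirely inside one true cluster, this rule splits that
  cluster and scores the far cluster active for that iteration — the exact
  per-animal probabilities for a 4-animal cohort are enumerable and the
  test suite pins them. At realistic cohort sizes (n ≥ ~30) one-sided
  resamples have probability ~2⁻³⁰ and the effect vanishes.
* *Degenerate resamples* (fewer than two distinct values) cannot be split
  and are redrawn from the same stream, with a hard budget of 10 B redraws
  before erroring. This also makes two-point-mass cohorts exactly certain:
  every kept resample contains both values.
* *Ties.* Equidistant points assign to the lower medoid (an animal exactly
  at the midpoint stays passive); BUILD ties resolve to the lowest input
  index; SWAP accepts only strict improvements.

## PAM: algorithm and the exact 1-D solver

`pam_fit` implements classical BUILD (greedy cost-minimizing seeding) +
SWAP (steepest-descent single exchanges). Steepest-descent SWAP can stall
in a genuine local optimum — e.g. x = [11, 14, 15, 17], k = 2 seeds
{14, 17} (cost 4) from which no single exchange improves, although
{11, 15} costs 3 — and equal-cost optima exist whenever a cluster has even
size (both middle elements are medians). Because the data are
one-dimensional, the global optimum is cheaply available: under
nearest-medoid assignment clusters are contiguous in sorted order and the
optimal medoid of a contiguous block is its (lower) median, so a dynamic
program over contiguous partitions (O(k n²)) attains the global optimum.
`pam_fit` therefore canonicalizes its BUILD+SWAP result against this exact
solution, which also makes the returned medoid set deterministic and
permutation invariant. The test suite verifies global optimality against
exhaustive medoid-subset enumeration and agreement with R's
`cluster::pam` on a tie-free instance.

The bootstrap inner loop uses the k = 2 special case of the same exact
solver (`pam_k2_batch`): each iteration's resample is sorted and all n − 1
contiguous splits are scored via prefix sums, vectorized across all B
iterations at once. This is what makes B = 10,000 at n = 200 run in well
under a second; a per-iteration BUILD+SWAP loop would be thousands of
times slower for identical output. A dual-implementation test checks the
vectorized path value-for-value against a plain-Python reference.

## The synthetic cohort generator

What it emulates, per defeated animal:

* latent phenotype ~ Bernoulli(`pi_active` = 0.5);
* true mean latency ~ truncated normal on [3, 900] s:
  passive N(182, 45²), active N(419, 60²). The component means are the
  observed cluster means of the paradigm; the SDs are calibrated defaults
  (not reported quantities) chosen so the average-latency clusters
  separate near 300 s. A gamma family would be a plausible alternative
  shape; truncated normal was chosen as the simplest bounded choice.
* daily latency = true mean + N(0, 60²), clipped to [3, 900]; a value at
  the cap is flagged censored. The 3 s floor reflects the minimum hold
  required to call a defeat; both bounds are configurable.
* expression = 2000 − 2.0 · (avg latency) + N(0, 430²), in arbitrary
  densitometry units, so active copers (long latencies) express less. With
  default latency variance (Var ≈ 17,300 s²) the closed form
  R² = β₁²Var(L) / (β₁²Var(L) + σ²) gives ≈ 0.27, inside the 0.2–0.35
  band the paradigm reports across assays. Controls have no latencies and
  draw from their own N(1650, 430²).
* behavior: each endpoint drawn from its stress-by-drug cell (mean, SD);
  defaults encode the qualitative effect structure — vehicle-passive
  interaction below vehicle-active with CNO normalizing it; passive
  immobility above control with CNO normalizing it; CNO *raising*
  immobility in controls; no effects in active copers; no latency/distance
  differences. Forced-swim %immobile/%swim/%climb are clipped at 0 and
  renormalized to sum to 100 per animal (cell means are already
  compositions summing to 100). Endpoints are independent given the cell.

One master seed feeds deterministic substreams (phenotypes, true means,
daily noise, drug assignment, expression, behavior), so identical
parameters give byte-identical tables. Drug is assigned balanced within
each phenotype stratum.

What it does **not** emulate: within-day encounter dynamics, latency
autocorrelation across days, correlations between behavioral endpoints
within an animal, heavy-tailed or skewed latency shapes, batch/cohort
effects. Passing recovery tests therefore shows the pipeline is correct
and well-calibrated under the assumed mixture structure, not that real
defeat data satisfy that structure.

## Group statistics

One-way ANOVA and the two-sample t test are computed from the classical
sums-of-squares formulas with p-values from scipy's F and t distributions;
the all-constant degenerate case returns F = 0, p = 1 (a 0/0 that library
routines report as NaN). The two-way stress-by-drug ANOVA uses statsmodels
OLS with Type III sums of squares under sum-to-zero coding — the
interaction-robust convention for the unbalanced cells the exclusion rule
produces; when the residual SS is numerically zero the degenerate F values
are rebuilt from the sums of squares. Tukey HSD uses statsmodels'
Tukey–Kramer implementation (valid for unequal n), reporting mean
differences, 95% studentized-range CIs and adjusted p; a CI excluding 0
corresponds to adjusted p < 0.05. The t test defaults to pooled variance
with Welch available by flag. Pearson correlation reports R² with the sign
of r and the t-transform p. p-values are rounded to 4 decimals in reports;
no multiplicity correction is applied beyond Tukey.

## Expected behavior of the full pipeline, and two sharp edges

On default cohorts (n = 200 defeated, B = 10,000) the pipeline recovers
the passive cluster mean essentially unbiased (≈ 183 s vs. the generating
182 s) and retained labels agree with the hidden phenotype ≈ 98–99% of
the time. Two systematic effects of the exclusion rule are worth knowing:

* **Active-mean selection bias.** The active label requires
  `p_active ≥ 0.9`, i.e. an average latency above roughly the 90th
  percentile of the bootstrap midpoint (~307 s at n = 200). Truncating
  N(419, 64²) below ~307 raises its mean by ≈ +6 s, so the active-labeled
  group averages ≈ 424 s, not 419 s. The passive side is spared because
  its truncation losses and its gains (low-lying active strays) cancel
  almost exactly. This is a property of the exclusion rule itself, not an
  implementation artifact, and it would apply equally to real data.
* **The 300 s boundary is actually 300.5 s.** PAM medoids are cluster
  medians, so with component means 182/419 the theoretical decision
  boundary is their midpoint, 300.5 s. Retained passive animals can
  therefore sit marginally above 300 s (by < 1 s in practice) in seeds
  whose empirical midpoint drifts high; the nominal "passive < 300 s"
  description is an approximation to the symmetric-default geometry.

## Problem sizes and numerical choices

Simulation studies in the test suite and acceptance script use n = 200
defeated animals × 20 seeds for cluster-mean recovery, n = 32 × 50 seeds
for phenotype recovery, and B = 10,000 throughout — large enough that
binomial noise on p_active (≤ 0.005) and seed-to-seed SEMs (~1–2 s on
cluster means) are small against the effects measured. Bootstrap resample
indices come from numpy's PCG64 (`default_rng(seed)`); derived seeds are
spawned from `SeedSequence` and kept below 2³¹. Cost comparisons in the
PAM canonicalization use a relative 1e-9 guard so that summation-order
rounding can never promote a tied SWAP solution over the canonical exact
one.
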