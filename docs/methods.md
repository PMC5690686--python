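# Methods

## The statistic

A CpG dyad is fully methylated (frequency *M*), hemimethylated (*H*) or
unmethylated (*U*), with *M* + *H* + *U* = 1 and overall methylation
frequency *m* = *M* + *H*/2. The Ratio of Concordance Preference is

RCP = 2√(*MU*)/*H* = √(*U*(*U* + 2*m* − 1)) / (1 − *U* − *m*).

The two forms are algebraically identical under the substitution
*M* = *U* + 2*m* − 1, *H* = 2(1 − *U* − *m*); RCP² = 4*MU*/*H*² is the
classical Hardy–Weinberg disequilibrium ratio when dyad states are read as
two-allele genotypes. RCP is reported as +∞ when *H* = 0 with both
concordant classes present, as 0 when exactly one concordant class is
absent, and raises an error at *m* ∈ {0, 1}, where the data carry no
information about concordance preference.

In the (*m*, *U*) plane the feasible region is bounded by the fully
conservative line *U* = 1 − *m* (all methyl groups in concordant dyads) and
the fully dispersive boundary *U* = max(1 − 2*m*, 0) (all methyl groups
hemimethylated while possible). The random-placement curve *U* = (1 − *m*)²
(RCP = 1) runs between them. Contours of constant RCP solve the quadratic
(r² − 1)U² − (2(1 − m)r² + 2m − 1)U + r²(1 − m)² = 0; of the two roots
exactly one lies in the feasible band (the equation is linear at r = 1), and
we keep the smaller when both coincide at the degenerate edge, which is
continuous with the r → 1 limit.

## Conversion-error model

Bisulfite conversion misreads each cytosine independently: an unmethylated
cytosine escapes conversion with probability *f* ("failed") and a methylated
cytosine is converted with probability *c* ("inappropriate"). Rates are
assumed strand-symmetric and are supplied by the user (estimated upstream
from control DNA); the package never infers them. Applying the per-strand
2×2 kernel independently to both strands of a dyad and collapsing the two
hemimethylation orientations gives a 3×3 row-stochastic matrix **E** from
true to observed dyad state. Observed frequencies are **p**ᵒᵇˢ = **p**ᵗʳᵘᵉ·**E**;
correction solves this linear system exactly (invertible whenever
*f* + *c* < 1). Because both error modes break concordance more than they
create it, uncorrected data are biased toward RCP = 1; the forward/inverse
pair is exact to machine precision on the interior of the simplex, and
corrections that leave the simplex due to sampling noise are clipped to 0
and renormalized (logged). Correction operates on dyad frequencies, not on
individual read patterns; count-level uncertainty is propagated by
resampling reads first and correcting each resample.

## Inference

**Read-level BCa bootstrap.** Dyads on one molecule are correlated, so the
resampling unit is the read, never the dyad. Each of `n_boot` (default
10,000) replicates redraws reads with replacement, tallies dyads, corrects
for conversion error, and evaluates RCP. Intervals use the
bias-corrected-and-accelerated construction: the bias constant z₀ is the
normal quantile of the fraction of replicates below the plug-in estimate
(clamped to (0.5/B, 1 − 0.5/B) to keep it finite), and the acceleration is
the standard jackknife skewness estimate over leave-one-read-out samples
(set to 0 if jackknife values are non-finite). Endpoints are order
statistics at the adjusted quantile positions (ceiling convention), which
remain well defined when replicates are infinite. The reported `point_bc`
is the BCa median-adjusted estimate, clipped into the interval. Replicates
with undefined RCP are dropped and counted; a >10% drop warns, a 100% drop
errors. All resampling is driven by a user-supplied seed and is bit
reproducible.

**Bootstrap null test.** Observed p-values can be far below resampling
resolution, so the test against RCP = r₀ uses a normal approximation on
log-RCP: statistic z = log(point_bc/r₀)/se, with se the standard deviation
of finite bootstrap log-RCP values. One-tailed p-values take the tail in
the direction of the observed deviation.

**Independent-dyad likelihood.** When reads are short (1–3 dyads) the
tallies are treated as a multinomial sample parameterized by (*m*, r): the
true frequencies on the contour are pushed through **E** and the likelihood
is evaluated in observed space, so error correction and estimation are one
coherent model. The MLE is the plug-in corrected frequency point (refined
by Nelder–Mead only if simplex clipping occurred); the profile likelihood
over r maximizes over *m* by bounded scalar search; the CI inverts
2[ℓ(r̂) − ℓ_prof(r)] ≤ χ²₁(level) by bracketing and Brent root-finding on
log r. A zero cell puts the MLE on the boundary (r̂ = 0 or ∞) and yields a
one-sided interval, flagged in the result.

**MLCT.** One-sample: H0 fixes r = r₀ with *m* free (at r₀ = 1 the null
MLE is the closed-form binomial fit m̂ = (2M + H)/(2n)); two-sample: H0
shares one r with *m* free per sample (the shared-r profile is maximized
over log r). Both are df = 1 likelihood-ratio tests calibrated by χ²₁;
boundary zero-cell cases switch to a parametric bootstrap under the fitted
null (default 10,000 simulations) and are flagged.

**Permutation test.** Two-tailed comparison of |log rcp_a − log rcp_b| on
corrected frequencies, reshuffling read-to-group labels with group sizes
fixed; p = (1 + #{null ≥ obs})/(1 + valid permutations). A group whose
permuted RCP is 0 or ∞ while the other is finite contributes an infinite
(maximal) statistic; permutations undefined in either group are dropped and
counted.

**Heterogeneity and pooling.** Replicates are compared with the multinomial
likelihood-ratio (G) test of one shared (M, H, U) against per-replicate
frequencies, df = 2(k − 1). This is deliberately stricter than equality of
RCP alone — a conservative gate before pooling. `pool_replicates` sums
counts element-wise and refuses (attaching the test) when the gate rejects
at 0.05, unless forced.

## Simulator

Dyad states of each read follow a stationary first-order chain over
{FULL, HEMI, UNMETH} with stationary distribution equal to the target
frequencies (from (m, r) via the contour equation) and one-step kernel
(1 − ρ)·stationary + ρ·identity. ρ = 0 gives independent dyads; ρ > 0 is
the simplest one-parameter model of within-molecule correlation, which is
what makes read-level and dyad-level inference genuinely different (the
suite asserts bootstrap CIs widen relative to likelihood CIs as ρ grows).
Hemimethylation orientation is symmetric (top/bottom with probability ½),
conversion errors are injected per strand at the configured rates, and
barcodes are unique random strings over the non-cytosine alphabet {A, G, T}
so simulated files exercise deduplication. The generator emulates
molecule-level sampling only: it has no sequence context, no per-position
rate variation, no mechanistic enzyme kinetics, and no PCR-clonality
artifacts beyond exact barcode duplication — so passing tests demonstrate
estimator correctness under the stated sampling model, not robustness to
every artifact of real libraries.

## Numerical choices and problem sizes

Simplex and feasibility tolerance is 1e−9 throughout; frequencies within
tolerance are renormalized on construction. Quadratic contour roots use the
numerically stable q-formula. Profile optimizations bound *m* in
[1e−9, 1 − 1e−9] and shared-r searches bound log r in [−25, 25]. The test
suite exercises the advertised statistical properties at desk scale chosen
to finish in minutes on one CPU: CI coverage uses 300 simulated data sets of
500 reads × 4 dyads with 2,000 bootstrap replicates each (the user-facing
default remains 10,000); MLCT type-I error uses 2,000 null multinomials of
400 dyads; distributional convergence uses 10⁶ dyads; error-injection
goodness of fit uses 10⁵ dyads.

## Known limitations

* Conversion rates are treated as known constants; their sampling
  uncertainty is not propagated.
* Strand-asymmetric error rates and hydroxymethylation are out of scope;
  hemimethylation orientation is recorded in files but collapsed in
  analysis.
* Two-dimensional (m, U) confidence regions are not rendered; intervals are
  on RCP only.
* The heterogeneity gate tests full distributional equality, so it can
  refuse pooling of replicates that differ in *m* but share r; `force=True`
  overrides.
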