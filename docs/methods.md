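# Methods

## Model

Approach-to-equilibrium labeling: after the label is added at t = 0,
newly synthesized transcripts are thiolated while pre-existing ones are
not.  Assuming zeroth-order synthesis and first-order removal, the labeled
pool of a transcript follows

    Y(t) = Y_eq (1 − e^(−α (t − t_d)))      for t > t_d,  else 0,

with α = α_RNA + α_growth.  Removal of labeled molecules includes dilution
by cell division, so the observable labeling rate is the sum of the decay
constant and the culture growth constant α_growth = ln 2 / T_double
(0.0069 min⁻¹ at the default T_double = 100 min).  The detection delay t_d
(default 2 min) absorbs the lag between label addition and the first
appearance of labeled molecules; it is fixed, not fitted, because the
earliest sample (3 min) cannot resolve it.  Half-life = ln 2 / α_RNA; when
a fitted α does not exceed α_growth the half-life is reported as NaN
(undefined), never negative.  At steady state, synthesis balances removal,
k = α·[mRNA], which converts rates to synthesis fluxes given an external
abundance estimate (the assay itself does not measure absolute abundance).

## Spike-in normalization

Spike-ins are in-vitro-transcribed thiolated RNAs added at constant mass
to every sample; they ride through the pull-down with the labeled
transcripts.  Per replicate j with time points k and spike-ins n:

1. A[i,j,k,n] = M[i,j,k] / S[n,j,k] — gene count over spike-in count;
2. β[n,j] = mean_k S[n,j,k] / S[ref,j,k] — each spike-in's average ratio
   to a reference spike-in (configurable; default the first in the
   manifest).  β[ref] = 1 exactly.  Multiplying A by β puts all
   spike-in-specific values on the common M/S_ref scale, so they are
   commensurable when fit jointly;
3. normalized ratio = A · β;
4. multiply by the mean reference-spike-in count over all time points of
   both replicates to restore count units.

Step 4's constant is the only place raw library depth enters: a depth
change in one library cancels in every ratio and can only move this single
global constant, leaving every time-course shape and every fitted rate
unchanged.  Exact invariance of the *values* under a per-library rescaling
is impossible for any data-derived scale constant; invariance modulo that
one global factor is what the algebra guarantees and what the tests
assert.

Each (replicate, time point, spike-in) value is kept as a separate
observation for fitting (a time point contributes up to
replicates × spike-ins values); `collapse_timepoints` averages them
instead.  The separate-observation default follows the view that the
spike-in denominators carry independent noise; note the numerator (the
gene count) is shared within a library, so these observations are
positively correlated — see "Information limits" below.

**Deviant time points.**  Constant-mass spike-ins should keep constant
mutual ratios over time.  A time point is excluded (for all genes, that
library) when any spike-in's ratio to the reference deviates from that
spike-in's per-replicate median ratio by more than `deviance_threshold`
fold (default 2.0).  A spike-in count of zero flags the library outright —
a vanished spike-in indicates a failed pull-down and is never
pseudocounted.  The rule is all-or-none per library: no gene keeps a point
a spike-in condemned.

## Fitting

Per transcript, both replicates' included points are pooled and
(α, Y_eq) minimize

    Σ_i w_i (y_i − Y_eq (1 − e^(−α (t_i − t_d))))²,
    w_i = 1 / max(y_i, weight_floor).

1/Y weights counter the mean-variance growth of count data so the plateau
does not dominate; `weight_floor` (default 0.5 count) keeps weights finite
at y = 0.  Weights use the observed values and are held fixed.

The objective has a ridge: as α → 0 with α·Y_eq fixed the curve
degenerates to a line and Y_eq is unidentified, where joint Newton-type
steps can stall.  The optimizer therefore profiles Y_eq out (for fixed α
the problem is linear, Y_eq(α) in closed form), scans α on a 120-point
log grid over [1e−5, 10] min⁻¹, refines the bracket with bounded scalar
minimization (xatol 1e−12), and finally polishes with bounded least
squares (analytic Jacobian, ftol/xtol 1e−12), accepted only if it improves
the objective.  Agreement with a brute-force dense grid search on the
identical objective is part of the acceptance suite.  A transcript is
unfittable (NaN parameters, flagged, retained in the output) when it has
fewer than `min_points` (3) usable observations, fewer than 2 distinct
times past t_d, or no positive signal.

**Bootstrap CIs.**  95% intervals on α are percentile bootstrap (2.5/97.5)
over `n_bootstrap` (default 1000) resamples, drawn with replacement from
the observation list at its own size.  Each resample re-estimates α alone
with Y_eq frozen at the point estimate: resamples that miss the late part
of the curve cannot pin Y_eq down and a joint refit then fails often,
which is the rationale for the one-parameter refit.  Iterations are
counted as failures — and excluded from the percentile pool — when the
resample has fewer than two distinct times, no positive signal, the
optimizer errors, or α lands on a box bound.  If fewer than half the
iterations succeed the CI is flagged unreliable.  Resampling whole time
points instead of observations is available (`bootstrap_unit`).
Per-transcript RNG streams are keyed by (seed, CRC32 of the transcript
id), so results are independent of processing order.

## Synthesis rates and enrichment

k = α × abundance, with CI bounds from the α interval under the same
abundance.  Default mode uses α_total (in a dividing culture removal =
degradation + dilution); `rna_only` uses α_RNA — the steady-state balance
is ambiguous about dilution and both readings are exposed.  Relative
abundances can be rescaled to a per-cell total (default 60,000 mRNAs/cell,
the conventional budding-yeast figure).

Each category with ≥ `min_size` (5) annotated, converged genes is compared
against all remaining genes by a two-sided Mann–Whitney U on α.  Ranks are
invariant under monotone transforms, so testing α or half-life is
equivalent.  The exact null distribution is used when both groups have
≤ 20 members and the pooled values are tie-free; otherwise the normal
approximation with midranks and continuity correction.  P-values are
BH-adjusted across tested categories.  Direction compares median α in the
category vs the background ("faster" = larger α).

## Simulator

Per library (replicate × time point), expected labeled molecules follow
the model curve per transcript; spike-in molecules are constant; the
library is a compositional draw of fixed depth (default 2×10⁶ reads) and
per-feature counts are negative-binomial around their compositional
expectation.  Defaults: the two replicate designs 3/5/7/11/13/25 min and
5/7/9/13/20/25/30/100 min; half-lives log-uniform on 2–60 min (bracketing
fast and slow turnover); Y_eq log-normal; gene NB size 10 (CV ≈ 32%,
moderate biological overdispersion typical of RNA-seq); three spike-ins in
1:2:4 mass proportion sized so their summed read share is 30% at the first
time point, declining as labeling accumulates.  Spike-in counts use their
own NB size (default 100): spike-ins are a technical control whose
variability is pipetting/capture noise, not biological dispersion, and the
2-fold deviance detector presumes their ratios are stable — at size 10 it
would flag ~10% of clean libraries.  An optional length-bias factor
multiplies Y_eq (never α) by (length/1200 nt)^exponent, mimicking
preferential labeling of long transcripts, which shifts equilibrium levels
but not decay estimates.  Everything is deterministic given the seed.

What the simulator does not emulate: read-level artifacts (alignment,
rRNA contamination, mappability), nucleotide recycling after the pulse,
label-induced stress, or correlated library-preparation batch effects.
Passing recovery tests therefore demonstrates the estimator's correctness
under the stated noise model, not robustness to those real-data effects.

## Information limits at the default noise level

With NB size 10 the per-library count noise is ~32% CV, multiplicative at
realistic depths.  The three spike-in-normalized values at a time point
share the library's single gene-count draw, so the two designs provide 14
informative libraries per transcript, not 42 independent observations.
The Cramér–Rao bound for (α, Y_eq) on this design then puts the best
achievable relative standard deviation on α near 0.32 (median across the
2–60 min half-life range) — a median absolute relative error floor around
22%.  The acceptance script's recovery study sits at this floor
(~25% median error; a brute-force oracle fit on the same draws does no
better), and 1/Y weighting measurably beats unweighted fitting in α RMSE.
The frozen-Y_eq observation bootstrap, by the same token, conditions away
the α–Y_eq covariance and treats correlated triplicates as independent, so
its intervals undercover the truth at these conditions (the script reports
the measured coverage).  Lower dispersion or more time points tighten all
of this; the estimator, not the noise, is what the oracle-equivalence
checks certify.

## Problem sizes

The recovery and coverage studies use 200 transcripts with 250 bootstrap
iterations; the oracle-equivalence check uses 50 instances on a 10⁻⁴ α
grid; rank-test calibration enumerates all group-size pairs ≤ 8 and 200
random-label draws.  These sizes give stable medians and proportions while
keeping a full run under a minute.

## Limitations

- t_d is global and fixed; transcripts with genuine detection delays
  different from 2 min absorb the discrepancy into α.
- The deviance rule assumes at least two spike-ins and a majority of
  well-behaved time points per replicate (the median must be clean).
- Synthesis rates inherit all uncertainty of the external abundance
  estimates, which is not propagated.
- Enrichment treats genes as exchangeable; co-regulation within a
  category inflates significance as in any gene-set rank test.
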