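# Methods

## The model

The package models visual search through a display of `n` letters of
which `x` appeared as abrupt onsets as a two-stage serial
self-terminating scan. Up to `c` onsets carry a priority tag; when
`x > c` the tagged subset is a uniform random draw from the onsets. The
tagged subset is inspected first in uniformly random order, then the
remaining items in uniformly random order, and the scan stops at the
target. The expected number of comparisons `y` follows from the uniform
rank of the target within its stage: a uniformly ordered set of `m`
items yields `(m + 1)/2` expected inspections, and an onset target sits
in the priority stage with probability `min(c, x)/x`. The four-way
piecewise closed form (split on `c < x` vs `c ≥ x` and onset vs
no-onset target) is given in the README and in
`prioritytag/model.py`.

All model values are computed as exact rationals
(`fractions.Fraction`) and exported as floats. This makes the central
correctness argument a strict equality: the exhaustive enumerator in
`prioritytag/simulate.py` — which sums over priority subsets, target
identities and within-stage ranks, with the rank distribution itself
obtained by enumerating permutations — must agree with the closed forms
*exactly* on every valid condition with `n ≤ 8`, with no tolerance to
hide an error. The enumerator never evaluates the closed-form
expressions, so the agreement is a genuine two-route check.

Capacities larger than the display are accepted and clamped to `n`
(they are prediction-identical to `c = n`); invalid cells (onset target
with `x = 0`, no-onset target with `x = n`) are rejected with a message
naming the violated constraint, and prediction tables omit such cells
rather than NaN-filling them.

In blocked designs the participant knows the relevant target type, so
the tagged pool is the relevant set itself (whichever type it is) and
the onset-target branch applies with the relevant-set size `r` in place
of `x`; both block types therefore share one prediction at equal `r`.

## Design equivalence

Under a finite design, distinct capacities can predict identically on
every cell — in the mixed 8-item designs capacities 6, 7 and 8 differ
only on cells with 7–8 onsets and a no-onset target, which the designs
do not contain. `equivalent_capacities` partitions 0..n into such
groups from the exact predictions. Equivalence groups propagate through
the pipeline: identical predictions give bitwise-identical fits,
selection reports the full group of the winner, the R² ANOVA runs on
one representative per group (for the mixed designs with 22
participants this yields the 6-level, df = (5, 105) layout), and
recovery studies score a hit when selection lands anywhere in the true
capacity's group.

## Synthetic data generation

The generators emulate the statistical structure of the three designs:

* `exp1` — mixed, onsets ∈ {0, 1, 2, 4, 6, 8}, 400 experimental trials
  per participant; per-cell counts are fixed so the probability that
  the target is an onset equals `x/8` at every onset count, making
  target type uninformative.
* `exp2` — adds onset counts 3 and 5; 560 trials.
* `exp3` — target type blocked in two sessions (order alternates with
  participant parity), 32 trials per (type × relevant-set size 1..8)
  cell, 512 trials.

Each trial draws a comparison count `k` from the search process at the
generating capacity `c_true` and maps it to milliseconds:

    RT = a_i * k + b_i * 1[t = onset] + d_i + ε,  ε ~ N(0, σ²)

Defaults are the study-scale values `a = 31.6` ms/comparison,
`b = −74.1` ms, `d = 764` ms, `σ = 150` ms, a 3.7% lapse rate and a
1.1% outlier rate. Participant coefficients `(a_i, b_i, d_i)` are drawn
around the population values with SDs (8, 25, 80) ms — plausible
individual-difference scales chosen once, since pooled-fit standard
errors do not identify them — with `a_i` truncated at zero. Lapse
trials keep their RT but are flagged incorrect; outlier trials have
their RT replaced by a draw from [50, 195] ∪ [2100, 5000] ms, outside
the analysis window; RTs above the 10 s response deadline are censored
at 10 000 ms and flagged as errors (how such trials should enter error
tabulations is underdetermined; this is the package's reading). A
log-normal multiplicative noise option with matched coefficient of
variation is provided for robustness checks.

Two deliberate simplifications: lapses are condition-independent (small
observed error differences between target types are not modelled, as
they play no role in the fitted model), and the colour marking of
onsets in `exp2`-style experiments is not a distinct generative
mechanism — `exp2` differs from `exp1` only in its cells. Passing tests
on these generators therefore demonstrate correctness of the pipeline
under the stated generative model, not that real RT distributions are
Gaussian or that real lapses are condition-independent.

In the noiseless limit (`σ = 0`) the scan-order variability is removed
along with the Gaussian term and every trial carries the model's
expected comparison count, so cell means equal `a·y + b·t + d` exactly
and regression recovery is exact to machine precision — the
deterministic limit used by the recovery contracts. With `σ > 0`,
per-trial counts are sampled; for speed they come from a vectorized
rank sampler whose distribution is proven equal to the per-trial
permutation simulator against the enumerated pmf.

Determinism: one root `SeedSequence` per dataset, one spawned child
stream per participant; a written JSON config (parameters + seed)
regenerates a dataset bit-for-bit. Practice trials (20 per participant)
are generated, flagged, and never analysed.

## Preprocessing and fitting

Preprocessing drops practice trials, excludes error trials from RT
means while counting them in error rates, and excludes correct trials
with RT < 200 ms or > 2000 ms as outliers (strict inequalities; the
bounds are parameters). Per cell, `used + errors + outliers = raw` is
an enforced invariant, and cells left with no valid trials are reported
rather than silently dropped.

Fits are ordinary least squares on cell-mean RTs with the capacity's
predictions as regressor. Choices where the procedure was genuinely
open:

* **Target-type coding.** The onset indicator is 1 for onset targets,
  so a negative `b` is an onset advantage; this is the coding that
  makes the fitted sign match the observed advantage.
* **Pooling.** Pooled fits use the unweighted grand mean over
  participant cell means. Because per-cell trial counts are highly
  unbalanced, weighted least squares by cell count is offered
  (`weighted=True`) but is not the default.
* **Zero capacity.** `c = 0` predicts no RT variation, so no search
  slope is identifiable; the fit is flagged
  (`predicts_no_variation`), a reduced model (indicator + intercept) is
  reported, and the capacity is excluded from selection and the ANOVA.
* **Endpoint cells** (`x = 0`, `x = 8`) enter mixed regressions
  wherever defined.
* **Blocked fits** run separately per block type with the
  intercept-plus-slope form, and exclude the one-relevant-item level by
  default (`exclude_r=(1,)`): with a single relevant item the target
  location is fully predictable and the trial is a cued detection, not
  a search.
* **Selection** is argmax of pooled R² with ties broken toward the
  smaller capacity, and the winner's full equivalence group is always
  reported — parsimony arguments between statistically
  indistinguishable capacities are left to the analyst, who has the
  ANOVA and the uncorrected pairwise (LSD) post-hoc table for exactly
  that purpose. Rank-deficient design matrices are rejected with a
  diagnostic; a constant per-participant R² matrix marks the ANOVA
  inapplicable instead of fabricating an F statistic.

Standard errors are the usual OLS covariance estimates from the pooled
fit; with unbalanced designs and participant-level pooling they are
descriptive rather than exact sampling SEs.

## Recovery studies and problem sizes

`prioritytag.recovery.run_recovery` generates replicate datasets at a
known capacity, runs the full selection pipeline per replicate
(ANOVA stage off by default inside the loop — selection does not use
it), and reports the group-level selection accuracy with a Wilson 95%
interval plus coefficient bias/RMSE at the true capacity.

The shipped validation suite runs recovery at 100 replicates × 22
participants for generating capacities 1, 4 and 8 under the `exp1`
design, Monte-Carlo consistency at 10⁵ trials per condition on a
20-condition grid, and the full 648-condition exact enumeration sweep.
At study-scale noise the selection accuracy is high for `c_true = 1`
but degrades for intermediate capacities: under the `exp1` cell
structure, capacities 4 and 5 differ only on the 6-onset cells (Δy of
0.5 and 0.17 comparisons, i.e. roughly 16 and 5 ms at the default
search rate), which is commensurate with the pooled cell-mean noise at
σ = 150 ms. This is a genuine identifiability limit of the design at
that noise level, not a numerical artefact; the corresponding recovery
contracts in the test suite document it by failing loudly rather than
by relaxing their threshold.

## Known limitations

* No target-absent trials: the designs contain none and the scan rule
  for exhaustive search is therefore unspecified here.
* No modelling of inspection durations, eye movements or parallel
  search; `a` is a purely phenomenological ms-per-comparison rate.
* No mixed-effects or Bayesian fitting; OLS on cell means mirrors the
  classical analysis the package formalises.
* The enumeration oracle is bounded at `n ≤ 10` (factorial growth of
  the cached rank enumeration).
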