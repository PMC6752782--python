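# Methods

## Setting and data model

The unit of analysis is a randomized trial rated by two risk-of-bias
instruments. Each trial belongs to exactly one systematic review in
the main analysis set; reviews are the clusters for all inference.
A `TrialRecord` carries the review (cluster) id, up to 12 reported
CROB item variants rated low/unclear/high (variants a review did not
report are explicitly *not assessed*), and the 11 binary PEDro items,
which are always complete because they come from a central database
rather than from the individual reviews.

Reviews report the two CROB blinding items in heterogeneous formats.
The package maps the 12 reported variants onto 7 core items: the
participants-only, personnel-only and combined participants+personnel
variants all fill the single performance-bias item; the three
outcome-assessment variants fill the detection-bias item; and the
triple-combined variant fills both with the same judgement. When one
review reports two variants of the same core item for one trial, the
worst judgement wins (high > unclear > low), following the
conservative convention in risk-of-bias work. This mapping is a
package design choice: published analyses state the core-item frame
but not the collapse rule.

## Recoding and summary scores

Three dichotomizations of the CROB scale are supported: the main
scheme (low → 1, unclear or high → 0), a first sensitivity scheme
(low or unclear → 1, high → 0), and a second in which unclear ratings
are omitted (pairwise deletion). Not-assessed ratings are excluded
under every scheme. The exact count identities — scheme 1 adds the
unclear count to the numerator, scheme 2 removes it from the
denominator — are enforced as property tests.

The CROB summary score is 100 × (core items rated low) / (core items
evaluated), computed unrounded; trials with no core item evaluated
have an undefined score and are excluded from summary-score analyses.
A sensitivity variant counts low-or-unclear in the numerator. The
total PEDro score is the yes-count over the 10 scored items (the
eligibility item is rated but never scored). Display percentages are
rounded half-up to integers; internal values are never rounded.

## Agreement statistics

**Percent exact agreement** is 100 × trace/n of the square paired
table. **Cohen's kappa** is (P₀ − Pₑ)/(1 − Pₑ) with Pₑ from the
marginal products; the same code serves the 2 × 2 item comparisons and
the 3 × 3 between-review tables (unweighted, matching the use of raw
three-level scores). Tables with all marginal mass in one category
have Pₑ = 1 and are flagged *not calculable* rather than erroring,
since degenerate items (e.g. rarely-achieved blinding) produce such
tables routinely. The large-sample kappa variance
(Fleiss–Cohen–Everitt) backs the unclustered normal CIs used in the
between-review analysis; it is cross-checked against statsmodels in
the tests, while the kappa implementation itself is verified against
an explicit double-loop oracle.

**ICC(1,1)** is the one-way random-effects intraclass correlation for
k = 2 measurements per subject: ICC = (MSB − MSW)/(MSB + MSW). Because
it is scale-dependent, the 0–10 PEDro total is rescaled ×10 onto the
summary score's 0–100 range before pairing — published point estimates
on such data are only comparable under some such alignment, and a
common scale is the natural one. Zero total variance yields an
undefined flag. The between-review summary-score ICC uses the exact
F-distribution interval (Shrout–Fleiss form).

**Clustered bootstrap.** With the exception of the between-review
analyses (whose pairs already span two reviews), every CI resamples
whole reviews with replacement, keeping the number of clusters equal
to the original and treating resampled duplicates as distinct. The
interval is the percentile interval of the replicate distribution
(the interval type is a package choice; the number of replicates
defaults to 5000 and is configurable). Replicates where the statistic
is not calculable are dropped and counted; if more than half are
dropped the interval is refused. For statistics that depend on the
data only through the pooled contingency table (kappa, percent
agreement) the bootstrap is vectorized over per-cluster tables, which
is algebraically identical to row-level resampling; the equivalence of
the two routes is tested.

**Interpretation labels** follow the conventional bands: Landis–Koch
for kappa (< 0 poor, 0.00–0.20 slight, 0.21–0.40 fair, 0.41–0.60
moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect) and Fleiss
for ICC (< 0.40 poor, 0.40–0.75 fair to good, > 0.75 excellent), with
boundary values assigned to the band in which they are printed.

**Table reconstruction.** `reconstruct_two_by_two` inverts a printed
(n, % agreement, marginal₁, marginal₂) summary into the implied 2 × 2
table: with A = round(n·pct/100), a = (A + m₁ + m₂ − n)/2 and the
other cells by subtraction. Because printed agreement carries one
decimal, the diagonal count may shift by ±1 to reach an integral,
non-negative table; anything further raises an inconsistency error.
This utility exists to validate agreement arithmetic against published
summary tables without access to raw data.

## Duplicate-trial resolution

Trials appearing in k ≥ 2 reviews contribute one uniformly randomly
selected rating (seeded generator) to the main set; among the
remaining ratings, the first in a canonical sort of review ids becomes
the second member of a between-review reliability pair, and third and
later ratings are dropped. Processing trials in sorted order makes the
partition invariant to input row order. The random-retention rule and
the definition of the "second" rating are package choices; the
procedure they implement (random selection, second rating for
reliability, later ratings discarded) follows standard practice for
such studies.

## Synthetic-data generator

The generator is the package's own construction: the minimal structure
that makes every analysis stage testable with known truth.

Per review: a normal effect u ~ N(0, review_effect_sd) shifts every
domain prevalence on the probit scale, p(u) = Φ(Φ⁻¹(p) + u), keeping
probabilities bounded; a blinding reporting style is drawn
(separate participants/personnel columns 0.35, combined 0.40,
triple-combined 0.15, none 0.10), a detection style when not covered
by the triple variant (plain 0.85, subjective 0.06, objective 0.08,
none 0.01), and review-level flags for whether selective reporting
(0.91) and other bias (0.60) are assessed at all. Review sizes are
uniform on a configurable integer range, default 7–22 (bracketing the
typical interquartile range of trials per review in this literature).

Per trial and latent domain: status S ~ Bernoulli(p(u)), clarity
C ~ Bernoulli(clarity_d). The CROB rating tracks S with
misclassification probability `crob_error` when the report is clear;
an unclear report yields UNCLEAR with probability
1 − `unclear_to_rating`, otherwise the rater still commits to low/high
with the same error. The PEDro rating tracks S with `pedro_error` but
is degraded to *no* whenever the report is unclear, mirroring the
scale's requirement of explicit reporting (a *no* therefore conflates
"not done" and "not reported"). Combined blinding variants observe the
conjunction of their component statuses and clarities.

Default prevalences and clarities are calibrated once to the
qualitative shape of published marginals — participant (≈ 6%) and
personnel (≈ 3%) blinding rare, assessor blinding ≈ 40% of trials,
allocation concealment clarity 0.42 so that unclear dominates that
item — and asserted as distributional tolerances in the tests, not
matched cell by cell. Default error rates (5%), unclear-commit
probability (10%), review effect SD (0.3 probit), duplicate fraction
(5.4%) and duplicate perturbation (10%) are round values chosen for
realism, not fitted.

Duplicates: a configured fraction of trials is re-rated by a randomly
chosen different review; each assessed CROB item independently moves
to one of the other two categories with probability `duplicate_error`,
and PEDro ratings carry over unchanged (they are trial-level database
scores).

**Analytic oracle.** Because every stage is a finite mixture, the
joint distribution of (PEDro binary × CROB three-level) per domain is
computed exactly by enumerating (S, C, rating outcome) and integrating
the review effect with 41-point Gauss–Hermite quadrature; population
kappas per recoding scheme follow by applying the kappa formula to the
recoded cell probabilities (kappa is scale-invariant, so the count
formula applies to probabilities directly). The Monte-Carlo agreement
of the sampler with this oracle, the strict decrease of kappa in
`crob_error`, and the coverage of the clustered bootstrap CI against
the oracle value (95/100 at 100 reviews × ~15 trials in the shipped
configuration) are all asserted in the tests.

What the generator does *not* emulate: real instruments differ in item
definitions (e.g. one instrument demanding the precise randomization
method), raters vary across reviews, and "unclear" usage is
rater-dependent rather than purely reporting-driven. A single shared
clarity channel couples the two instruments more strongly than real
data, so synthetic item kappas run higher than typically published
ones. Passing tests therefore demonstrate correctness of the
statistical machinery and calibration of the inference under the
stated model — not that real instruments agree at these levels.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script run the full pipeline
at the study's natural scale (108 reviews, ≈ 1500 trials) with 400 and
1000 bootstrap replicates respectively; the package default of 5000
replicates is used when no override is given. The parameter-recovery
check uses 100 replicate studies at 500 replicates each. Percentile
endpoints use the default linear-interpolation quantile; ties in the
worst-rating collapse are resolved by the fixed severity order; the
probit transform clips prevalences to [1e-12, 1 − 1e-12]; kappa
denominators below 1e-12 are treated as degenerate.

## Known limitations

* Bootstrap CI bounds depend on the interval type; percentile
  intervals need not match normal-approximation or BCa bounds from
  other software, and no attempt is made to match any published CI.
* Weighted kappa, multi-rater kappa and studentized intervals are out
  of scope.
* The XLSX-export ingest path is limited to delimited text; convert
  spreadsheets to CSV before `robagree ingest`.
* ICC comparability across instruments rests on the ×10 rescaling
  decision; a different alignment changes the ICC.
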