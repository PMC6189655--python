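# Methods

## Data model

A study is a set of binary (more generally, nominal) features, each rated
by the same panel of `n` raters over a common set of items. Two kinds of
items exist: *nontesting* items rated once, used for interrater
agreement, and a *repeated* subset presented twice to every rater, used
exclusively for intrarater (test-retest) agreement. On disk, the long CSV
layout encodes the repetition with an `occasion ∈ {1, 2}` column; an item
is treated as repeated exactly when any occasion-2 row exists for it.
Missing ratings are permitted throughout — real panels have dropouts —
and category codes are opaque strings, binary being a special case rather
than an assumption.

## Agreement estimator

The single source of truth for agreement is the multi-rater,
missing-data-tolerant Gwet AC1:

- observed agreement `P_a` averages, over items with at least two
  ratings, the probability that two randomly drawn raters of the item
  agree;
- the chance term uses category marginals `π_q` averaged over every item
  with at least one rating, `P_e = Σ_q π_q(1 − π_q)/(Q − 1)`;
- `AC1 = (P_a − P_e)/(1 − P_e)`.

Items with fewer than two ratings are excluded from `P_a` and from
`n_items_used` but still inform `π_q`: this maximizes the information in
the chance term without biasing observed agreement. If the observed
category set is degenerate (`Q = 1`, e.g. a unanimous panel with inferred
categories), `P_e` is defined as 0, so perfect agreement yields AC1 = 1
rather than 0/0. Percent agreement is `P_a` with `P_e = 0`. Intrarater
agreement treats a rater's two occasions as a two-rater panel over the
repeated items; callers should pass the feature's full category set so
the chance term sees categories the rater never used.

### Standard error

The SD attached to an AC1 value is a delete-one-item jackknife over the
usable (≥ 2 ratings) items: each deletion removes the item from both the
`P_a` mean and the marginals, and

`SD = sqrt(((n′ − 1)/n′) · Σ_i (AC1₍₋ᵢ₎ − mean)²)`.

The jackknife was chosen because it is assumption-free, testable against
a looped oracle, and the detection rule below only needs a dispersion
scale for the reliability estimate, not an exact sampling variance. A
closed-form variance could be slotted in behind the same interface later.
The implementation is vectorized: per-item contributions to `P_a` and
`π_q` are precomputed once, so a full jackknife costs O(items × Q).

## Discordant-rater detection

For each rater in sequence: reliability `R_i` of the other `n − 1` raters
and its jackknife SD are computed, then extrapolated to `n` raters with
the Spearman–Brown prophecy formula (`k = n/(n − 1)`), giving `R_j`. The
interval is `R_j ± c·SD` with `c = 2` by default, by analogy with
two-sigma outlier screens. `ΔR = R_n − (R_j − c·SD) < 0` flags the rater
as discordant. Design choices:

- the SD in the interval is the jackknife SD of the `n − 1` panel,
  *not* pushed through the Spearman–Brown map — the literal reading of
  "`R_j ± 2SD`"; the map's derivative is ≈ 1 near the operating range for
  large `n`, so the difference is immaterial;
- the SD is recomputed for every excluded rater, matching the
  "in sequence … and its corresponding SD" procedure;
- only downward deviation acts: the symmetric case `R_n > R_j + c·SD`
  (removing the rater *lowers* reliability, i.e. the rater was carrying
  the panel) is recorded as an informational `beneficial` flag and never
  triggers exclusion;
- flagging is strict (`ΔR < 0`), so a panel of identical raters
  (`ΔR = 0` exactly) flags no one.

Leave-one-out needs `n ≥ 3` so the reduced panel still supports an
interrater estimate.

## Optimization loop

Round 1 always runs, even when the panel already exceeds the threshold —
the first identification is unconditional. Each round excludes *all*
currently discordant raters in one batch (multi-rater rounds are the
norm), then recomputes AC1. The loop continues while the coefficient is
still ≤ the threshold (0.6, the lower edge of "substantial" on the
Landis–Koch benchmark; convergence is strict `>`), new discordant raters
keep appearing, the panel stays at or above `min_raters`, and a safety
cap of `max_rounds = 50` has not been hit. If a batch would shrink the
panel below `min_raters`, only the most negative-ΔR raters are excluded
so exactly `min_raters` remain, and the loop then stops — a deterministic
tie-break for a situation the procedure itself leaves unspecified.
`min_raters` defaults to 3, the smallest panel on which another
leave-one-out round is possible. Non-convergence (`converged = false`) is
a first-class outcome; excluded raters are never re-admitted. Per-round
AC1 usually rises but is not mathematically guaranteed to — exclusion
only promises *predicted* improvement — which is why the improvement
property is asserted statistically over seeds, not per instance.

## Scoring and selection

Disagreement scores follow the `m − t + 1` rule per feature. Scores are
deliberately per-feature: selection policy B consumes the feature's own
score, since post-selection agreement is evaluated feature by feature.
The cross-feature aggregate (mean by default; sum and max available —
mean is comparable across raters who miss a feature) exists for
panel-level reporting only, and scores are not normalized across features
with different `m`.

Policies: **A** keeps raters with intrarater AC1 strictly above the
threshold (0.6); **B** keeps raters with score exactly 0; **C** is the
intersection. A rater with no intrarater estimate cannot pass A or C.
Features with fewer than two selected raters are dropped from that
policy's summary (logged), never imputed.

Policy distributions (per-feature AC1 values) are compared with a
reproducible normality gate: Shapiro–Wilk per group at α = 0.05. If every
group passes, one-way ANOVA with pairwise Welch tests under Sidak
adjustment; the classical alternative here is Dunnett's T3, whose
studentized-maximum-modulus critical values are not available in the
scientific Python stack, and Sidak-adjusted Welch statistics are the same
pairwise statistic with a marginally different critical value. Otherwise
Kruskal–Wallis with Dunn's rank-based pairwise z tests (tie-corrected)
under Bonferroni multiplication. Groups that are all constant and
identical yield an explicit "undefined" report rather than a p-value.

## Synthetic panels

The generator emulates the study design end to end: per feature, latent
binary item truth at a configurable prevalence; each rater reports the
truth with their profile's `accuracy`, erring symmetrically or toward
category "1" with probability `bias`; occasion-2 ratings of the repeated
items flip the rater's occasion-1 answer independently with the rater's
`flip_prob`. Defaults mirror a 50-expert study of 230 nontesting + 35
repeated items across 25 binary features: competent raters at accuracy
0.9 and flip 0.05, ten planted discordant raters at accuracy 0.55,
prevalence 0.5. A single root seed drives everything; per-feature streams
are spawned from it, so panels are bit-reproducible and features are
independent.

What the model does *not* capture: correlated errors between raters
(shared training, ambiguous images), item difficulty heterogeneity,
drift over the rating session, and display-dependent color bias. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under independent-error conditions, not that it would do so under
arbitrary real-world dependence.

Test and validation problem sizes were chosen to keep the full suite
fast while preserving the study's geometry: the detection-recovery and
round-one-improvement checks run the full 50 × 230 design over a 20-seed
grid; the selection-ordering check runs the full 25-feature study per
seed; oracle-equivalence checks use 1,000 random panels of ≤ 8 items × 5
raters, where brute-force enumeration is exact and cheap.

## Known limitations

- The jackknife SD is a dispersion scale, not a calibrated sampling
  variance; interval coverage of `R_j ± 2SD` is nominal, not exact.
- Batch exclusion can over-exclude relative to one-at-a-time exclusion
  when discordant raters mask each other; the procedure is defined as
  batch and the trace records every round for audit.
- Agreement on ordinal or continuous data (weighted coefficients, ICC)
  is out of scope; the detection machinery is coefficient-agnostic, but
  only AC1 is provided.
- Consensus-label generation for the curated database is downstream of
  this package and not included.
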