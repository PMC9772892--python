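# Methods

## The decision model

PBMA evaluates marginal changes to a fixed budget against a weighted
multi-criteria value function. The package's core identity is the
two-level weighted sum

    final(j) = Σ_c (w_c / 100) · crit(j, c)
    crit(j, c) = Σ_{s∈c} (w_{s|c} / 100) · score(j, s)

with main weights `w_c` summing to 100, within-criterion weights
`w_{s|c}` summing to 100 per criterion, and subcriterion scores in
[−2, +2]. Because both stages are linear, this equals the single pass
`Σ_s (overall_s/100)·score_s` with `overall_s = w_c·w_{s|c}/100`; the
test suite checks that equivalence to 1e-9 against a brute-force oracle.
The final score is therefore bounded by the score scale and strictly
monotone in every positively weighted criterion score.

Assumptions inherited from the method: value is additive across
criteria (no interactions), weights mean trade-off ratios, and the
−2..+2 scale is treated as interval-scaled so that medians and weighted
means are meaningful.

### Aggregation choices

* **Weights: mean, not median.** The panel weight of an item is the
  arithmetic mean of the panelists' 100-point allocations — the mean is
  the only common aggregator that preserves the simplex exactly. A
  median option exists behind a flag for sensitivity analysis.
* **Scores: median, then weighted means.** Subcriterion panel scores
  are medians of integer votes (half-integers at even counts are kept
  unrounded — rounding first cannot reproduce non-trivial criterion
  scores such as 0.73). Criterion scores are the within-weighted mean
  of subcriterion medians: the unique natural roll-up consistent with
  the verified final-score aggregation, adopted here as an explicit
  design decision. Final scores are computed from unrounded criterion
  scores; 2-dp rounding is display-only.
* **Likert evidence** (1–5) maps affinely to the score scale
  (`rating − 3`), preserving half-steps from even-count medians.

### Willingness to pay

Only complete cases (respondents who valued every component) enter the
aggregation. The societal value of a component is mean WTP × population,
in £M/year; "aggregation" is thus interpreted as a population scale-up
of the sample mean (recorded in every run manifest, since sample total
and sample mean are also defensible readings). A symmetric trimmed mean
(configurable trim) is available for outlier-heavy samples.

Two mappings project monetary values onto the bounded score scale, both
pluggable strategies recorded in the manifest because no canonical
convention exists:

* societal benefit: min–max affine map of aggregate values across the
  component set onto [−2, +2]; a degenerate range scores 0. Monotone
  and invariant to common positive rescaling.
* cost–benefit: `clamp((value − cost)/scale, −2, +2)`. The scale
  defaults to half the interquartile range of |value − cost| across
  components, which spreads typical net benefits over the usable range
  instead of piling them at the clamp; the IQR degenerating to 0 falls
  back to the largest absolute net benefit.

### Program budget

National spend per line = unweighted mean per-capita spend over
responding regions × national population. The mean is unweighted
because each return is treated as one observation of regional spending
policy; the same extrapolation is applied to NHS and local-authority
lines (flagged in output metadata — the local-authority response base
is far thinner). Primary-care spend is decomposed as
items × mean fee × correction factor; the factor is an input, never a
constant, because claim bundling varies by contract era. Budget shares
in (0, 1)% render as "<1", others to the nearest integer; all stored
tables keep full precision.

### Marginal analysis

* Feasibility: residual = Σ disinvestment releases + efficiency release
  − Σ investment costs; feasible ⇔ residual ≥ 0. Efficiency components
  are auto-applied; their release is a parameter because delivery-model
  savings are estimates, not listed costs.
* Components are **nondivisible** by default: scores were elicited for
  whole programs, so partial funding would invalidate them. A
  `divisible` flag exists but warns when set.
* Vote semantics: a ballot funds a new service by selecting it and
  funds a current service by *not* selecting it for disinvestment —
  the only reading that makes a single vote column coherent across
  both component kinds. A tie at exactly the threshold is funded.
* `enumerate_feasible` scans all 2^n selections (n ≤ 25, a few seconds
  at the limit; the bundled 14-component registry takes well under a
  second) and can filter to portfolios undominated on (total funded
  score, residual). The Pareto filter is a reporting aid only — the
  decision itself is the panel's vote, never score maximisation.
  Mutually exclusive alternatives (e.g. overlapping orthodontic
  eligibility tiers) can share an `exclusion_group` so no portfolio
  selects both.

### Sensitivity

Main weights are resampled from Dirichlet(α · w/100) — concentration
α = 100 by default, roughly the dispersion of a 100-point allocation —
and final scores and ranks recomputed per draw (default 1000). Summary
percentiles use the nearest-rank method. The threshold sweep applies
the decision rule at every threshold 1..n_voters and flags decisions
that flip within one vote of the operating threshold.

## Synthetic data

The generators emulate the case study's conditions: 10 panelists, 11
criteria / 24 subcriteria (weights default to the bundled elicited
weights, renormalised because the recorded values carry 1-dp rounding),
14 components, 339 WTP respondents, 9 of 16 regions responding.

* Point allocations are multinomial(100, true_weights): the elicitation
  forces ballots onto the 100-point integer simplex, so the generator
  must too.
* Score ballots are true scores + Gaussian noise (sd 0.5 by default —
  panelists typically agree to within a scale step), rounded
  half-away-from-zero, clamped to [−2, +2]. Zero noise reproduces
  integer truths exactly, giving exact downstream recovery.
* WTP is zero-inflated log-normal: P(zero) = 0.25, log-mean 3.0
  (median ≈ £20/year), log-sd 1.0. The case study published no WTP
  magnitudes, so these are the package's own choice of a realistic
  right-skewed stated-preference shape with genuine zeros; they are
  fully user-configurable and nothing downstream depends on their
  scale (the benefit mapping is min–max).
* Regional returns perturb configured per-capita line means
  (default ≈ £64/head/year split like a national dental budget) with
  10% multiplicative noise.
* One integer seed drives a `SeedSequence` hierarchy with a fixed spawn
  key per generator, so artifacts regenerate independently and
  byte-identically.

What the synthetic data does **not** model: respondent demographics and
survey waves, protest zeros, strategic panel behaviour, correlated
scoring across subcriteria, or real cost uncertainty. Passing tests on
synthetic data therefore demonstrate the arithmetic and the seeded
plumbing, not the behavioural realism of any elicitation.

## Numerical and degenerate-input rules

Weight sums are validated to ±0.2 (recorded tables carry 1-dp rounding);
allocation ballots must hit 100 exactly unless an explicit tolerance
enables proportional rescaling. Criteria keep input order — no
reordering by weight. Empty panels, empty surveys and zero responding
regions raise insufficient-data errors (CLI exit 3); structural and
range violations raise validation errors (exit 2). Ballot boxes bound
votes by voter count. A short panel (missing final ballots) is logged
and analysed as-is rather than rejected.

## Known limitations

* The bundled case-study table of overall subcriterion weights contains
  one internal rounding inconsistency: the recorded 1.8 for the
  pain-associated subcriterion differs from the product of its own
  recorded factors (9.1 × 19.2% = 1.7472) by more than a 1-dp rounding
  step. The package reports the computed product; the corresponding
  reproduction test documents and exposes the discrepancy rather than
  special-casing it.
* The case study's £134M unspent budget requires an efficiency release
  (≈£60M) that was never itemised; it is exposed as the
  `efficiency_release_gbp_m` parameter and documented as inferred.
* WTP magnitudes and the regional spend returns behind the budget
  shares were not published, so those stages are validated by synthetic
  round-trips and parameter recovery, not by numeric reproduction.
* No inter-rater reliability statistics, score imputation, ILP-based
  selection, or formal voting-theory treatment.
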