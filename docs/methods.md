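# Methods

## The survey model

A three-group competency survey asks faculty, recently graduated students,
and junior doctors (1–2 years of practice) about a fixed list of procedural
skills. Faculty rate each skill on two dimensions — *essentialness* (how
important it is that a graduate performs the skill autonomously) and
*utility* (suitability for teaching by simulation) — while each learner
group rates *autonomy* (self-perceived mastery) and *utility*. All ratings
are integers on a 1–9 semantic-differential scale. The group/dimension
pairing is a hard structural rule: a student essentialness rating is a data
error, not a missing category.

Scores are validated as integers; non-integer values are rejected rather
than rounded, because the instrument anchors only integer points and a
fractional score indicates corrupt input. Missing ratings are allowed — a
respondent may skip an item — and completeness is tracked per cell by n.
The interchange format is a UTF-8 long-format CSV
(`respondent_id, group, item_id, dimension, score`) with companion
`items.csv` and pre-coded `suggestions.csv` files; qualitative coding of
free-text suggestions into categories (new technical skill, non-technical,
duplication, replication) is human work supplied as input, and the package
only tallies it.

## Descriptive statistics

Each survey cell (item × group × dimension) is summarized by the arithmetic
mean of available scores, a dispersion estimate, and n. The dispersion
estimator is configurable:

* `iqr` (default): Q3 − Q1 with linear interpolation between order
  statistics (numpy's `linear` quantile method). This is the conventional
  report-alongside-the-mean choice for bounded ordinal scales.
* `sd`: sample standard deviation (ddof = 1), undefined at n = 1.

Column-level aggregates treat items, not respondents, as the unit: the
overall mean of a group+dimension column is the unweighted mean of per-item
means. This is deliberate — it is the definition under which a published
overall-mean row is recomputable from a table of printed cell means, and it
keeps the aggregate insensitive to per-cell response imbalance. Column
extremes return the *full* tied set of items at the minimum or maximum
rather than an arbitrary representative, because ties at the printed
precision genuinely occur. Cross-group utility for an item is the unweighted
mean of the three group means.

Reported values are rounded half-away-from-zero: 1 decimal for cell means,
cross-group means and rates, 2 decimals for overall column means and
desirability scores. Note that recomputing a published overall mean from
*already-rounded* cell means can disagree with the published value by one
unit in the last digit; the package computes from whatever precision its
input carries and does not chase print artifacts.

An empty cell (n = 0) has an undefined mean — it is flagged `None`, never
imputed — and undefined cells propagate explicitly through every downstream
stage.

## Desirability scoring

Priority scoring follows the desirability-function approach to
multi-response optimization: standardize each response onto [0, 1], then
combine by geometric mean. Per response,

    faculty:  d = sqrt( (utility − 1)/8 · (essentialness − 1)/8 )
    learner:  d = sqrt( (utility − 1)/8 · (9 − autonomy)/8 )

and the overall score is D = (d_faculty · d_student · d_junior)^(1/3).
The learner form reverses autonomy because low self-perceived mastery is
what makes training valuable. Properties guaranteed (and tested exhaustively
over the 81 integer rating pairs): both forms map into [0, 1]; the faculty
form is non-decreasing in both arguments; the learner form is non-decreasing
in utility and non-increasing in autonomy; the two forms are reflections of
one another, d_learner(a, u) = d_faculty(10 − a, u); the geometric mean is
bounded by its smallest and largest component, is idempotent on equal
components, and is annihilated by any zero component.

One modelling subtlety: the faculty form is the same algebraic expression as
the learner form with the autonomy scale reversed, and in source material
for this design the faculty equation is sometimes written with the symbol
"autonomy" even though faculty are surveyed on essentialness. This package
binds the faculty slot explicitly to essentialness — the dimension faculty
actually rate.

### Aggregation strategy

The composite's definition does not fix *where* averaging happens, and the
two natural choices differ on any non-degenerate data:

* `per_respondent_mean` (default): evaluate d on each respondent's own
  paired ratings, then average over respondents. A respondent contributes
  to an item only if they rated both of their group's dimensions for it;
  unpaired ratings are excluded from scoring (but still count in
  descriptive statistics).
* `of_group_means`: evaluate d once on the group's two mean ratings. This
  is the only strategy available when respondent-level data do not exist
  (e.g. a published table of group means), exposed as
  `score_from_summaries`.

Because sqrt(x·y) is jointly concave, Jensen's inequality orders the two:
per_respondent_mean ≤ of_group_means on the same data, with equality only
for degenerate (constant) groups. The per-respondent strategy is the default
because it respects within-respondent pairing of the two judgments; the gap
between the strategies is also why composite scores computed from published
group means systematically overstate respondent-level composites.

Differential weighting uses the weighted geometric mean
(∏ vᵢ^{wᵢ})^{1/∑wᵢ}; weights must be non-negative and not all zero, a zero
weight removes a component, and equal weights recover the plain composite.

### Ranking

Items are sorted by descending overall score. Ties are broken by ascending
item label — an arbitrary but documented and deterministic rule, so
re-running the pipeline on identical input is byte-reproducible. Items whose
score is undefined (some group had no paired ratings) are listed after all
scored items with a null score rather than being silently assigned zero.

## The synthetic generator

No respondent-level data accompany the published survey this package's
fixtures derive from, so testing respondent-level code paths requires a
generator. It emulates the study's structure:

* three invited cohorts, defaults 43 faculty / 53 students / 102 junior
  doctors (the study's invitation counts);
* all-or-nothing respondent participation with probability 0.667 (the
  study's overall response rate) — participation, not item completion, was
  the study's unit of non-response. Item-level skipping is available
  separately via `skip_prob` (default 0);
* each participant rates every item on both of their group's dimensions;
* a score is the item's latent mean for that (group, dimension), plus
  Gaussian noise with standard deviation `noise_sd` (default 1.5 rating
  points, the middle of the dispersion range seen in published tables of
  this kind of survey), rounded to the nearest integer and clamped to
  [1, 9];
* an optional within-respondent correlation between a respondent's two
  dimension ratings (default 0 — the real correlation is unknown and is
  exposed as a parameter rather than assumed).

A single seeded `numpy` generator drives every draw in a fixed iteration
order, so a survey is fully reproducible from its seed, which is recorded in
downstream artifacts. Latent item profiles matching the published 40-item
group means are packaged as a convenience (`reference_item_profiles`); this
is a fixture, not a calibration — respondent-level dispersion cannot be
validated against any published data.

What the generator does *not* emulate: ordinal response styles (central
tendency, extreme responding), respondent-level heterogeneity beyond the
shared noise term, item non-response correlated with ratings, and any
group-size-dependent dispersion. Passing recovery tests therefore shows the
pipeline is correct and well-conditioned under a plausible noise model, not
that real surveys of this size always yield stable rankings.

### Planted-ranking recovery

`make_recovery_scenario` builds items whose true priority order is known:
high-priority profiles (essentialness 8, autonomy 2, utility 8 — essential,
unmastered, simulable) versus low-priority profiles (8, 8, 8 — identical
except already mastered). The pipeline must rank every high item above every
low item. At the default cohort sizes and noise_sd = 1.5 this succeeds in
≥ 99 of 100 seeded runs (the test suite and acceptance script both run the
100-seed experiment; it is exact at noise_sd = 0).

## Packaged fixtures

`skillprior/data/table2_means.csv` holds published per-item group means and
dispersions for 40 skills plus each item's published overall desirability
score; `table3_suggestions.csv` holds per-group occurrence counts of 22
respondent-suggested new technical skills. Both are read-only reference
data. The published desirability column is shipped for comparison only: it
was computed from unpublished respondent-level data, and no aggregation of
the published means reproduces it (the of-group-means path gives ≈ 0.84 for
the top item against a published 0.77 — the direction and size of the gap
are exactly what the Jensen ordering predicts). The package ranks whatever
it computes and does not attempt to reverse-engineer the unpublished
procedure. Relatedly, the published suggestion counts are internally
inconsistent (76 collected − 23 − 11 − 10 excluded ≠ 22 distinct skills,
whose occurrence counts sum to 43); the tally operation reports the coded
input as-is and does not reconcile.

## Problem sizes

The test suite and acceptance script use: exhaustive 81-pair integer grids
for the scoring identities; 100 random groups (3–39 respondents) for the
Jensen ordering; 20 synthetic surveys for the aggregation-vs-naive-loop
oracle; and 100 seeded study-sized surveys for planted-ranking recovery.
The whole suite runs in a few seconds on one CPU.

## Known limitations

* Desirability is a one-sided transform here; target-value ("nominal is
  best") desirability is out of scope.
* The pipeline performs no inference — no confidence intervals or tests on
  ranks. Rank stability can be probed empirically through the generator.
* Self-perceived mastery is a biased proxy for competence; the scoring
  model inherits that bias from its inputs.
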