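# Methods

## Scoring model

Each performance indicator pairs one command-decision kind with a
stipulated time standard, in minutes from the incident alert:

| id | decision | standard (min) |
|----|----------|----------------|
| 1 | declare major incident | 1 |
| 2 | set staff alert level | 3 |
| 3 | send additional resources to scene | 3 |
| 4 | designate receiving hospitals | 5 |
| 5 | contact scene command | 10 |
| 6 | preliminary referral decision | 10 |
| 7 | first media information | 15 |
| 8 | formulate response guidelines | 15 |
| 9 | confirm referral information | 20 |
| 10 | assess own resources | 30 |
| 11 | notify referral decision | 40 |

A decision documented at elapsed time *t* scores 2 if *t* ≤ standard,
1 if *t* > standard, and 0 if absent from the log. Two boundary
conventions were genuinely open and are fixed as follows:

* **"within x minutes" is inclusive** (*t* = *x* scores 2): the plain
  reading of a deadline. Tests pin this boundary.
* **A decision documented without a usable timestamp is unevaluable**,
  which marks the whole incident's documentation incomplete and excludes
  it from the scored cohort — retrospective evaluation excludes poor
  documentation rather than imputing it. The alternative
  (`lenient_timeless=True`: score such decisions 1, "made but not
  demonstrably on time") is available but not the default.

Duplicate events of one kind keep the earliest timestamped occurrence,
because the rubric asks when the decision was *first* made. Times are
stored to one-second resolution and compared in minutes as reals; all
absolute timestamps are normalised to UTC on parse, and mixing naive
with offset-aware timestamps inside one record is an error.

## Cohort filters

Applicability is a property of the incident, not of single indicators:
the set applies to categories that directly or indirectly involve
casualties (accident, fire, threat, CBRNE) and not to the other five
categories. A per-record override flag exists because applicability is
adjudicated case by case in practice and published cohort counts cannot
always be reconstructed from category labels alone; the flow-replica
preset uses such flags. The two filters (applicability, completeness)
are independent predicates, so their order cannot change the scoreable
count — a property the tests check.

"Active 4 h or less" uses an inclusive 240-minute cutoff. The median is
the ordinary order-statistic median.

## Inference

The complete b × 11 score matrix is analysed as a randomized complete
block design with incidents as blocks — scores are ordinal {0,1,2} but
the parametric two-way additive ANOVA is applied deliberately, matching
the established analysis of this design; no rank transform is offered.
Sums of squares come from the standard mean-based decomposition;
treatment and block F statistics use MS_error on (a−1)(b−1) df.

Tukey HSD uses the studentized-range distribution (quantiles and CDF
from `scipy.stats.studentized_range`). With equal replication b per
treatment the significance threshold is the single constant
HSD = q·√(MS_error/b), and each pair also gets an adjusted p-value
(the survival function of |mean difference|/√(MS_error/b)), so
"p < 0.05" statements are testable rather than binary flags.

The underline grouping exploits that single constant: sorting the
treatment means ascending, every maximal contiguous run spanning at most
the HSD becomes one line, and two treatments share a line **iff** they
do not differ significantly — the construction is exact for equal
replication, not an approximation.

Degenerate inputs: fewer than 2 blocks or treatments is an error;
MS_error = 0 (e.g. a perfectly additive matrix) reports F and p as exact
limits with a warning, and flags every nonzero mean difference
significant (the continuity limit of the HSD rule).

## Synthetic cohorts

No real command-and-control logs are distributed, so the generator
emulates the published summary structure of the material:

* **Category mix** — default: the published 9-category classification of
  130 incidents as proportions (48:37:23:15:2:2:1:1:1); presets use
  exact integer counts.
* **Score distributions** — per indicator, (p0, p1, p2) either given
  directly or inverted from a target mean m and a "late share" λ (the
  fraction of met decisions that are late): p_met = m/(2−λ),
  p1 = λ·p_met, p2 = (1−λ)·p_met. The inversion is exact, so empirical
  means converge to the targets at rate 1/√n. Default λ = 0.3: the
  published aggregate (446 of 726 cells met fully or partly) constrains
  the 0-vs-nonzero split but not the 1-vs-2 split, so the late share is
  a package choice, fixed once.
* **Latency laws** — score 2 draws Uniform[0, standard); score 1 draws
  standard·(1+Exponential(1)). These are the simplest laws that respect
  the score boundary *strictly*, so re-scoring a generated record always
  recovers the drawn score exactly (a tested invariant). No latency
  distributions are published; these laws are package choices.
* **Activation duration** — log-normal with median 60 min and
  σ = ln(4)/z₀.₇₅ ≈ 2.055, calibrated so 75% of incidents close within
  4 h (the published 98/130).
* **Ancillary fields** — staffing extent multinomial (50,36,34,10)/130;
  casualties for applicable incidents log-normal (median 7, σ = 1.1)
  clipped to the published range 3–135; more-than-one-hospital
  probability 35/130; hospital-plan activation 15/130. These reproduce
  published marginals approximately and carry no role in the scoring.
* **Under-documentation** — a record is made incomplete by stripping the
  timestamp of one documented decision (or adding an untimed declaration
  when no decision was drawn), either at probability `p_incomplete` or
  as an exact per-cohort count for flow fixtures.

Randomness: one global integer seed; each record consumes a substream
keyed by (seed, record index) via `numpy` `SeedSequence` spawn keys, so
cohorts are reproducible and unaffected by later reordering.

Two presets define the package's study conditions:

* `calibration_preset()` — 66 incidents, all in applicable categories (the
  applicable mix 48:37:23:2 scaled to 66 by largest remainder →
  29/22/14/1), fully documented, per-indicator means set to the
  published values (1.48, 1.41, 1.32, 1.63, 1.53, 0.86, 0.75, 0.18,
  0.93, 0.03, 0.97), λ = 0.3, documented seed 20120817.
* `flow_replica_preset()` — 130 incidents in the published category counts;
  28 records carry an explicit not-applicable override (all 20 records
  of non-applicable categories plus 8 applicable-category records,
  mirroring case-by-case adjudication) and 36 applicable records are
  forced under-documented, leaving 66 scoreable. These counts are exact
  by construction, not stochastic.

What passing tests on synthetic cohorts do **not** show: the generator
draws indicator scores independently across incidents and indicators
(no true block effects, no correlation between, say, late referral
decisions and late referral notifications), event latencies follow
convenience laws, and inter-organisational reporting delays are not
modelled. Results on real logs can differ wherever those features
matter — in particular, real block effects would shrink MS_error and
sharpen the pairwise comparisons relative to the synthetic case.

## Reporting conventions

Percentages print as round-half-up integers (102/130 → 78%,
446/726 → 61%) and every printed percentage sits next to its numerator
and denominator, so it is always recomputable. Note one published
figure is not reproducible under any standard rounding: 280/726 =
38.57%, printed as 38% in the source material; this package's reports
give 39%.

## Problem sizes

The default verification runs use cohorts of 66 and 130 incidents, a
200-replicate Monte-Carlo for mean recovery (200 × 66 incidents,
13 200 score vectors), and randomized ANOVA oracle checks on layouts
from 3 × 2 to 12 × 8. The full test suite runs in well under a minute;
the acceptance script in a few seconds.
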