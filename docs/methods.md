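# Methods

## The decision procedure

Items are administered strictly in their original order. After question *q*
the engine holds the cumulative response score and the cumulative sums of the
per-question lower (TL) and upper (TU) thresholds, and evaluates, in order:

1. if *q* > `start_neg` and cumulative score ≤ cumulative TL → stop,
   non-depressed;
2. if *q* > `start_pos` and cumulative score > cumulative TU → stop,
   depressed;
3. if the number of zero answers so far strictly exceeds `zero_count` → stop,
   non-depressed;
4. after the ninth question without a stop → depressed (the default for the
   unclassified).

The lower check precedes the upper check because the procedure compares the
score against the lower boundary first; the zero-count gate is a supplementary
rule and is evaluated last so that threshold stops take precedence. The start
point gates suppress only the *comparison*: thresholds are still estimated
and logged for every question actually reached, which keeps traces complete
for audit.

Ground truth is always the full stored 9-item total (records are complete by
construction), even when the engine stops early.

## Threshold estimation

For a respondent with history H = (r₁,…,rᵢ), all estimates condition on the
historical records whose first *i* answers equal H exactly. With counts over
that matching set,

- TL = the smallest r ∈ {0..3} with P(depressed, next ≤ r | H) > λ,
- TU = the largest r with P(non-depressed, next ≥ r | H) > λ,

both implemented literally as printed rules: the *minimum* qualifying level
for TL (scanning r = 0..3) and the *maximum* for TU (scanning r = 3..0), with
strict `>` against λ. Degenerate branches: TL = 3 when no matching record is
depressed; TU = 0 when none is non-depressed. When no level qualifies and the
degenerate branch does not apply the threshold is UNDEFINED; the engine then
substitutes a neutral contribution into the cumulative sums (−1 for TL, +4
for TU — one below/above what any answer could reach) so that the interview
simply continues. Continuation is the conservative choice where the decision
rules are silent.

Probabilities are exact ratios of integer counts. Comparisons against λ are
performed in integer arithmetic via `float(λ).as_integer_ratio()`, so the
vectorized production path, the simple reference functions and the rational
brute-force oracle used in tests agree exactly, with no float-rounding edge
cases.

### First item

phq1 has no history; the same two rules are applied to the unconditional
response distribution of the full estimation set.

### KNN fallback for unseen histories

When a history matches no record, thresholds come from the K nearest records
by Euclidean distance over the answered items: for TL the *non-depressed*
group (the nearest confirmed non-depressed respondent's next answer is a safe
level at which to classify non-depressed), for TU the *depressed* group.
Neighbours are ordered by (distance, input order) — a stable tie-break that
makes results a deterministic function of dataset order. For K > 1 the
minimum of the neighbours' next answers is used for TL and the maximum for
TU, extending the "safe estimate" direction of the single-neighbour case; the
optimal configuration uses K = 1, so this aggregation is exercised but not
critical. Squared distances give the same ordering as true Euclidean
distances, so no square root is taken.

If a history is unseen *and* the relevant reference group is empty (after the
leave-one-out exclusion), estimation raises an error rather than guessing;
this can only occur in datasets with fewer than two records in a label group.

## Leave-one-out evaluation

Each respondent's thresholds are estimated from the dataset minus that
respondent. The implementation computes, once per distinct history, the
next-item response counts by label over the full dataset (a vectorized prefix
scan, cached), then subtracts the held-out respondent's own contribution —
algebraically identical to recounting over the reduced dataset, which the
test suite verifies against physical removal. This makes leave-one-out over
tens of thousands of records run in seconds; counts stay exact integers
throughout.

## Hyperparameters

| parameter    | meaning                                             | range      | default |
|--------------|-----------------------------------------------------|------------|---------|
| `zero_count` | zeros tolerated before a non-depressed stop (strict)| 0–9        | 6       |
| `start_neg`  | questions during which the lower check is suppressed| 0–3        | 1       |
| `start_pos`  | questions during which the upper check is suppressed| 0–3        | 2       |
| `k`          | neighbours in the KNN fallback                      | 1–4        | 1       |
| `lam` (λ)    | tolerated joint tail probability                    | 0.01–0.10  | 0.02    |

Defaults are the configuration reported optimal on both study populations:
negative classifications allowed from the second question, positive from the
third. `start_neg`/`start_pos` count suppressed questions, the only encoding
consistent with both the stated 0–3 range and those optima. Tuning is an
exhaustive grid search (λ step 0.01, ten values) selecting lexicographically:
maximal Youden index, then minimal average question count, then the smallest
(λ, zero_count, start_neg, start_pos, K) tuple for reproducibility. A single
λ serves both thresholds; the tuning protocol evaluates on the same
leave-one-out predictions it selects on — no nested cross-validation — which
reproduces the published protocol and shares its optimism caveat.

Metrics are kept at full float precision; the Youden identity
(youden = sensitivity + specificity − 1) is asserted unrounded. A rate with
an empty denominator is reported as NaN with a warning, never silently 0.

## Synthetic data generator

Real PHQ-9 interviews are not redistributable, so the package generates
populations with the statistical structure the method depends on: a latent
severity θ ~ N(μ, σ²) per respondent, item responses obtained by thresholding
aᵢθ + εᵢ (εᵢ standard normal) against three increasing per-item cutpoints —
a graded-response-style mechanism. Positive loadings make early items
informative about later items and about caseness, which is precisely what the
conditional thresholds exploit; with zero loadings the items collapse to
independent noise (a property the tests check). Default cutpoints are
right-skewed (most mass at zero) as in screening populations, with
sleep/fatigue items endorsed most and the suicidality item least. Prevalence
of the total ≥ 10 label is controlled by bisection on μ against a fixed
calibration sample of 50,000 draws (common random numbers make prevalence
deterministic and monotone in μ), with the 8.8% and 30% regimes of the two
study populations as the reference settings.

What the generator does **not** emulate: demographic covariates, item-level
missingness and refusal codes, measurement non-invariance across subgroups,
and any departure from the single-factor response process. Passing tests
therefore demonstrate the correctness and internal behaviour of the
procedure, not its clinical accuracy on real populations; the published
real-data figures (e.g. Youden 0.94/0.90 at 3.4–4.0 questions) require the
original datasets and are treated as optional integration checks, not
reproduced here.

## Problem sizes

The test suite runs leave-one-out end-to-end on a calibrated n = 5,000 /
30%-prevalence population; `scripts/acceptance.py` uses n = 44,749 at 8.8%
and n = 4,025 at 30%, matching the cleaned sample sizes of the two study
datasets. These sizes run in seconds thanks to the cached counting scheme and
were chosen to exercise the method at realistic scale.

## Known limitations

- Conditional probabilities are raw counts with no smoothing; very long rare
  histories fall to the KNN path by design rather than to a shrunk estimate.
- The TL rule's direction (larger λ ⇒ larger, more permissive lower
  thresholds) follows the printed decision rule and its worked walkthrough;
  the alternative risk-control reading (largest r with tail ≤ λ) is not
  implemented.
- The KNN output is used directly as the threshold, not passed through a
  λ-rule.
- Binary caseness at total ≥ 10 only; no severity banding, no imputation of
  partial records.
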