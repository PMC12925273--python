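# adaptive-screener

Adaptive-length administration of the PHQ-9 depression questionnaire.

The PHQ-9 asks nine questions, each answered on an ordinal 0–3 scale; a total
score ≥ 10 is the conventional indicator of probable major depression. For
screening, nine questions are often more than needed: many respondents reveal
enough after two or three items. This package implements a dynamic
questionnaire that administers the items in their usual order and stops as
soon as a confident classification — depressed or non-depressed — can be made,
using a historical dataset of completed PHQ-9 interviews to decide when.

It is aimed at researchers in psychometrics and epidemiology who want to
evaluate early-stopping screening rules against fixed short forms
(PHQ-DEP-4, PHQ-2) on their own data or on simulated populations.

## The model

After each question *i* the respondent's cumulative score is compared with
cumulative lower and upper thresholds. The per-question thresholds are
estimated from the respondents in the historical data whose first *i* answers
match the current respondent's history *H* = (r₁, …, rᵢ) exactly:

- **Lower threshold** TL = min{ r ∈ {0,1,2,3} : P(D, phqᵢ₊₁ ≤ r | H) > λ },
  where D is the event "total ≥ 10" and λ is a loss parameter — the joint
  tail probability tolerated before a level is selected. If no matching
  respondent is depressed, TL = 3. Stopping rule: cumulative score ≤
  cumulative TL ⇒ non-depressed.
- **Upper threshold** TU = max{ r : P(non-D, phqᵢ₊₁ ≥ r | H) > λ }, with
  TU = 0 when every matching respondent is depressed. Stopping rule:
  cumulative score > cumulative TU ⇒ depressed.
- For the first question the same rules are applied unconditionally.
- **KNN fallback**: when a history matches no record, the K nearest records
  by Euclidean distance over the answered items supply the threshold — the
  nearest non-depressed respondent's next answer for TL, the nearest
  depressed respondent's for TU.

Three further gates are tuned: the lower/upper checks are suppressed for the
first `start_neg` / `start_pos` questions; strictly more than `zero_count`
zero answers stops the interview as non-depressed; anyone still unclassified
after nine questions is labelled depressed. Evaluation is leave-one-out (each
respondent's thresholds are estimated with that respondent excluded) and
hyperparameters are chosen by maximizing the Youden index
(sensitivity + specificity − 1), ties broken by fewer questions asked.

## Worked example

```python
from adaptive_screener import (
    GeneratorConfig, HyperParams, calibrate_prevalence, generate,
    loo_predict, score_predictions, evaluate_baseline,
)

# a synthetic primary-care-like population, calibrated to 30% prevalence
config = calibrate_prevalence(GeneratorConfig(n=2000, seed=7), target=0.30)
dataset = generate(config)
print(f"prevalence: {dataset.prevalence():.3f}")

# leave-one-out adaptive screening at the optimal configuration
# (zero_count=6, start_neg=1, start_pos=2, K=1, λ=0.02)
result = score_predictions(loo_predict(dataset, HyperParams()))
print(f"dynamic   youden={result.youden:.3f} sens={result.sensitivity:.3f} "
      f"spec={result.specificity:.3f} avg questions={result.avg_questions:.2f}")

static = evaluate_baseline(dataset, "phqdep4")
print(f"PHQ-DEP-4 youden={static.youden:.3f} sens={static.sensitivity:.3f} "
      f"spec={static.specificity:.3f} avg questions={static.avg_questions:.2f}")
```

prints

```
prevalence: 0.291
dynamic   youden=0.834 sens=0.883 spec=0.951 avg questions=3.28
PHQ-DEP-4 youden=0.799 sens=0.948 spec=0.850 avg questions=4.00
```

The adaptive questionnaire beats the fixed four-item form on discrimination
(Youden 0.83 vs 0.80) while asking fewer questions on average (3.3 vs 4):
most respondents are classified after two or three items, and only those near
the decision boundary answer many or all nine.

The same pipeline is available from the shell:

```sh
adaptive-screener simulate --n 2000 --prevalence 0.3 --seed 7 --out data.csv
adaptive-screener evaluate --data data.csv --out results/
adaptive-screener trace --answers 3,2,2,3 --data data.csv
adaptive-screener baseline --data data.csv --model phqdep4
adaptive-screener tune --data data.csv --grid grid.json --out tuned/
```

NHANES-style depression-screener CSVs (`SEQN`, `DPQ010..DPQ090`, with codes
7 = refused and 9 = don't know excluded row-wise) are read with
`--dialect nhanes`.

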