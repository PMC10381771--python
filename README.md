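# emometrics

Graded-response psychometrics for forced-choice emotion recognition tests.

Emotion perception tests present raters with short emotion displays
(nonverbal, spoken, or with a concealed felt emotion) and a menu of emotion
labels. Building such an instrument requires a chain of analyses: norming
the stimuli (who recognizes what, and what gets confused with what),
turning confusions into distractor keys, scoring responses with partial
credit, calibrating an item response model, pruning weak items, and
checking that the test measures the same construct across demographic
groups. `emometrics` implements that chain as a library plus a set of
numbered analysis drivers, with a synthetic-respondent generator so every
stage can be exercised offline with known ground truth.

## The statistics at the core

**Proportion index.** A hit rate *P* from a *k*-option judgement is
rescaled to a dichotomous-equivalent scale,

    pi = P (k - 1) / (1 + P (k - 2)),

so chance responding (*P* = 1/*k*) always lands at pi = 0.50 and accuracy
is comparable across tasks with different menus. Concealed displays need
two judgements (the displayed and the hidden emotion); their joint hit
rate lives in a *k*₁ × *k*₂ response space and is converted with that
joint *k*.

**Graded scoring.** Because emotion categories overlap (fear–anxiety,
disgust–anger), responses are scored by degree of correctness: 0/1/2
(inaccurate / plausible distractor / correct) for single-judgement items,
and 0/1/2/3 for concealed items (neither label / one label / both labels
but swapped / both placed correctly).

**Graded response model.** Ordered scores are modeled with logistic
boundary curves P\*ⱼ(θ) = 1/(1+exp(−a(θ−bⱼ))), category probabilities
being adjacent differences. Calibration is marginal maximum likelihood via
EM over a fixed quadrature grid with a N(0,1) prior; the m = 2 case is the
two-parameter logistic model used for conventionally scored tests.
Diagnostics include Samejima item information, test information functions
and their areas, a summed-score item-fit χ² with the χ²/df ≥ 3 poor-fit
rule, Cronbach's α, and McDonald's ω from the model-implied loadings.

**Measurement equivalence.** Groups are calibrated separately, linked by
mean/mean anchoring, and compared by an expected-score area effect size
(d-DIF): the root-integrated-squared difference between the groups' item
characteristic curves, standardized by the pooled observed item-score SD,
read against 0.2/0.5/0.8 small/medium/large benchmarks.

## Worked example

The numbered drivers under `analysis/` run the full construction sequence
on a seeded synthetic cohort (4 race groups × 2 genders, 50 respondents
per cell, 64 items, sparse 16/12/4 assignment) and write tables under
`results/`:

```
$ python analysis/01_simulate_cohort.py
simulated 400 respondents, 64 stimuli, 12800 judgements (seed 20230719)

$ python analysis/02_stimulus_validation.py
mean pi by modality (joint-k for concealed):
            mean    std
concealed  0.912  0.047
nonverbal  0.703  0.173
verbal     0.664  0.234
accepted 38 / 64 stimuli under default criteria

$ python analysis/03_score_and_calibrate.py
nonverbal: 31 items, 400 respondents, converged=True, mean loading=0.67, loglik=-5010.2
...

$ python analysis/06_test_information.py
area under the TIF on [-3, 3]:
  nonverbal    80.9
  verbal       52.9
  concealed    46.1
paired TIF comparisons (60-point grid, df = 59):
            comparison      t  df  cohens_d  mean_diff
   nonverbal vs verbal  11.00  59      1.42       4.61
```

Reading the output: every emotion category is recognized above chance
(pi > 0.50) by the simulated population, so most stimuli pass selection;
the EM calibration converges with moderate-to-high loadings; and the
31-item nonverbal sub-test provides significantly more information than
the shorter sub-tests across the ability range (paired t on a 60-point θ
grid). Driver 05 reports mean d-DIF per group pair — all groups are drawn
from one population here, so those values show the sampling noise floor of
the effect size at this scale, not real inequivalence.

The same flow is available as a single command (`emometrics run`) or
stage-by-stage (`emometrics simulate | validate-stimuli | score | fit`).

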