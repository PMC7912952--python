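# aortanorm

Normalcy calculators for the thoracic aorta measured by 2-D
transthoracic echocardiography at four levels — aortic annulus (AAn),
sinuses of Valsalva (SoV), sinotubular junction (SJ) and proximal
ascending aorta (PAA) — for cardiologists, imaging researchers and
methodologists who need a single tool that works from pediatric to
elderly subjects without switching nomograms at age or body-size
boundaries.

Two complementary scores are provided:

* **Z-score** — the conventional approach: one ordinary-least-squares
  model per level predicts the diameter from normalized age,
  normalized body surface area (Du Bois) and sex, with a single
  homoscedastic residual scale σ = √MSE;
  z = (observed − predicted)/σ, abnormal when z > 2.
* **Q-score** — a novelty-detection approach: an ensemble of one-class
  SVMs, one per percentile ν on the grid 1 %…30 % (step 1 %), each
  estimating the support of the healthy joint distribution of
  (age, sex, BSA, diameters). The Q-score is the smallest grid ν whose
  machine flags the subject (decision function < 0): abnormal < 2 %,
  borderline 2–4 %, normal > 4 % ("> 30 %" = inside every support).
  Local Q uses one diameter; **global Q uses all four at once and so
  captures overall aortic shape** — a joint pattern can be abnormal
  while every individual diameter is unremarkable.

The package also ships the comparison machinery (stratified 10-fold
cross-validation with healthy-only training, ROC/AUC with stratified
bootstrap CIs, DeLong tests, best sensitivity+specificity cutoffs,
prevalence and discordance tabulation) and a synthetic cohort
generator calibrated to published healthy-population summaries, so
everything is testable end to end without clinical data.

## Worked example

Simulate a healthy reference cohort, train all nine models (4 Z +
4 local Q + 1 global Q), and score subjects:

```sh
python -c "from aortanorm import SyntheticConfig, generate_healthy; \
           generate_healthy(SyntheticConfig(seed=0)).to_csv('healthy.csv')"
aortanorm train healthy.csv --out models/
aortanorm score models/ --age 43 --sex M --height 176 --weight 78 \
                        --aan 26 --sov 41 --sj 30 --paa 34
```

```
Subject: age 43 y, sex M, height 176 cm, weight 78 kg, BSA 1.943 m2

Level  Size (mm)   Z-score   Q-score  Category (Q)
AAn           26     2.66*       27%  normal
SoV           41     3.14*       19%  normal
SJ            30      1.14      >30%  normal
PAA           34      1.79      >30%  normal
Global                           18%  normal

* Z-score > 2 (abnormal). Q: abnormal < 2%, borderline 2-4%, normal > 4%.
```

This subject is discordant: the regression calculator flags the
annulus (z = 2.66) and sinuses (z = 3.14), while the Q-score considers
a proportionately large aorta in a 1.94 m² man within the healthy
support (global Q 18 %). The reverse discordance also occurs — a
subject whose every single level passes the z > 2 rule but whose
*pattern* is off:

```sh
aortanorm score models/ --age 43 --sex M --height 176 --weight 78 \
                        --aan 16.5 --sov 35 --sj 20.5 --paa 32
```

```
Level  Size (mm)   Z-score   Q-score  Category (Q)
AAn         16.5     -3.08       10%  normal
SoV           35      1.05      >30%  normal
SJ          20.5     -2.57      >30%  normal
PAA           32      1.13      >30%  normal
Global                            1%  abnormal
```

No level exceeds z = 2, yet the combination — a small annulus and
sinotubular junction with a comparatively large root and ascending
aorta — lies outside the healthy joint distribution: global Q = 1 %,
abnormal. Only the four-diameter score can see this.

Other subcommands: `aortanorm simulate` writes healthy + patient
cohorts for the named assumption-violation scenarios
(`homoscedastic_linear`, `heteroscedastic`, `nonlinear_age`,
`shape_abnormality`); `aortanorm evaluate` runs the cross-validated
Z-vs-Q ROC comparison and emits a JSON report; `aortanorm heatmap`
maps the Q-score over a two-diameter plane with the 2 %/4 % level-set
contours and the 40 mm guideline overlay. All commands honor `--seed`
and `--log-level`.

The library surface mirrors the CLI: `fit_linear_model` / `z_score` /
`z_report`, `fit_qscore_ensemble` / `q_score` / `q_report` /
`q_heatmap`, `cv_scores` / `roc_auc` / `bootstrap_auc_ci` /
`delong_test`, and `generate_healthy` / `generate_patients` /
`assumption_violation_suite`. See `docs/methods.md` for the models,
their assumptions, all tunable parameters and known limitations.

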