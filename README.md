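# screendca

Screening-performance and decision-curve evaluation of binary phenotypic
screens against binary outcomes in clinical cohorts.

The motivating application is cardiovascular genetics: in intensive-care
infants with congenital heart disease (CHD), the presence of at least one
extracardiac anomaly (ECA) is widely used as the phenotypic trigger for
diagnostic genetic testing. Treating ECA status as a binary screen and
"genetic diagnosis identified" as the binary outcome, this package answers
the questions a program director would ask: how well does the screen
classify, how much predictive certainty does it add, and — via decision
curve analysis — at which risk thresholds does screen-guided testing beat
simply testing everyone?

## What it computes

Everything derives from the screen x outcome 2x2 table
(TP, FP, FN, TN; N = total):

- **Screening metrics** — sensitivity, specificity, accuracy; Youden index
  *J* = Se + Sp − 1 and number needed to diagnose NND = 1/*J*; predictive
  values PPV, NPV; predictive summary index PSI = PPV + NPV − 1 and number
  needed to predict NNP = 1/PSI; clinical utility indices
  CUI₊ = Se·PPV, CUI₋ = Sp·NPV and their sum SUI, with qualitative grades.
- **Association statistics** — Woolf odds ratio with 95% CI, Pearson χ² and
  Fisher exact tests, one-sided Cochran–Armitage trend tests over ordered
  time periods, the closed-form binary-predictor logistic fit (Wald χ²,
  AUC = (Se+Sp)/2, closed-form Brier score), and a per-anomaly-type
  association scan.
- **Tetrachoric correlation** — latent bivariate-normal correlation for 2x2
  tables (own high-accuracy Φ₂ quadrature plus bracketed root-finding),
  assembled into anomaly-type × CHD-class correlation matrices.
- **Decision curve analysis** — net benefit
  NB(R) = TP/N − [R/(1−R)]·FP/N for the screen-guided strategy against the
  Test-All (NB = P − [R/(1−R)](1−P)) and Test-None (NB = 0) references,
  with the exact crossing threshold R\* = FN/(FN+TN) = 1 − NPV.
- **Synthetic cohorts** — a seeded generator that emulates the published
  aggregate structure (class frequencies, anomaly-type prevalences with a
  latent-Gaussian copula, period trends), so the entire pipeline can be
  exercised and validated by parameter recovery without patient data.

## Worked example

```python
from screendca import ScreeningModel, TwoByTwoTable

table = TwoByTwoTable(tp=166, fp=267, fn=78, tn=502)
print(ScreeningModel(table).fit().summary())
```

```
Binary screen evaluation
========================
N = 1013  (screen+ 433, screen- 580; outcome prevalence 0.2409)
2x2 table [TP FP / FN TN]: 166 267 / 78 502

Sensitivity                      0.6803
Specificity                      0.6528
Accuracy                         0.6594
Youden Index (J)                 0.3331
Number Needed to Diagnose (NND)  3.00
PPV                              0.3834
NPV                              0.8655
Predictive Summary Index (PSI)   0.2489
Number Needed to Predict (NNP)   4.02
CUI(+)                           0.2608 (very poor)
CUI(-)                           0.5650 (adequate)
Summary Utility Index (SUI)      0.8258

Odds ratio (woolf): 4.00 [2.94, 5.44]
Logistic fit: Wald chi2 78.2 (p <0.0001), AUC 0.667, Brier 0.168
Decision curve crossing (screen-guided vs Test-All): R* = 0.1345 (13.4%) = 1 - NPV
```

Reading: a screen-positive infant carries a 4-fold higher odds of a genetic
diagnosis, yet the screen's overall discrimination is modest (AUC 0.667)
and 13.4% of screen-negatives still harbour a diagnosis. The decision
curve therefore favours testing everyone whenever clinicians would act on
risks below ~13–14%, and screen-guided testing only above that threshold.

The same analysis is available from the shell:

```bash
screen-dca simulate --n 1013 --seed 7 --out cohort.csv
screen-dca report --input cohort.csv --out report.json
screen-dca dca --input cohort.csv --plot curve.png
```

## Layout

- `src/screendca/cohort.py` — data model, delimited-text I/O, complete-case
  filtering, contingency aggregation
- `src/screendca/metrics.py` — screening/clinical-utility metric family
- `src/screendca/association.py` — OR, χ²/Fisher, trend, logistic, scan
- `src/screendca/tetrachoric.py` — Φ₂ quadrature and latent correlation
- `src/screendca/dca.py` — net benefit, decision curves, crossing threshold
- `src/screendca/model.py` — `ScreeningModel` / `ScreeningResults`
- `src/screendca/simulate.py` — synthetic cohorts and count fixtures
- `src/screendca/pipeline.py`, `cli.py` — orchestration and `screen-dca`

See `docs/methods.md` for the statistical methods, modelling assumptions
and numerical choices.
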