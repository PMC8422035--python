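# skilldiag

Model comparison for diagnostic measurement of **continuous subskills**.

Reading-type cognitive subskills are usually conceived as continuous
traits, yet diagnostic score reports have traditionally come from
latent-class cognitive diagnosis models (CDMs) that force each subskill
into a binary mastery / non-mastery state. `skilldiag` implements the
full simulation machinery needed to quantify what that dichotomization
costs: it generates examinees with correlated continuous subskills,
calibrates three competing diagnostic models on the same response data,
and measures how accurately each one recovers the examinees' true
mastery states across the whole range of plausible mastery cut-offs.

## The models

All three models are confirmatory: a binary **Q-matrix** `q_jk` fixes
which of the K subskills each of the J items requires. The package
ships a 30-item, 3-subskill reading-comprehension instrument (Q-matrix
plus calibrated item parameters) as its reference fixture.

**Compensatory MIRT (3PL).** Continuous abilities θ ∈ R^K with

P(X_j = 1 | θ) = c_j + (1 − c_j) · logistic(a_j·θ + d_j),

slopes a_j ≥ 0 constrained to the Q-matrix pattern, intercept d_j,
lower asymptote (guessing) c_j. Estimated by marginal maximum
likelihood EM over a rectangular quadrature grid; persons are scored by
EAP, and Φ(θ̂) maps scores to the mastery-probability scale.

**Saturated G-DINA.** Binary attribute pattern α ∈ {0,1}^K; each item
carries one success probability per reduced pattern of its required
attributes. EM over the 2^K latent classes with a saturated structural
distribution; closed-form M-step.

**R-RUM.** P(X_j = 1 | α) = π\*_j · Π_k r\*_jk^(q_jk(1 − α_k)) — a
baseline success probability π\*_j discounted by r\*_jk for every
required-but-unmastered attribute.

## Classification accuracy

True mastery states come from thresholding Φ(θ_true) at a cut-off
point; MIRT states from thresholding Φ(EAP); CDM states are the MLE
attribute patterns (cut-off-invariant). Agreement is summarized by

- **SCCR_k** — proportion of (person, replication) cells whose
  estimated state on subskill k matches the true state,
- **PCCR** — proportion whose whole K-vector pattern matches,

pooled over persons and replications, for each of the 81 cut-offs
0.10, 0.11, …, 0.90. Model fit is compared by −2LL / AIC / BIC and the
limited-information M2 statistic on univariate and bivariate margins
with its RMSEA.

## Worked example

Simulate two replications of 1,500 examinees at subskill correlation
0.1, calibrate all three models, and inspect the cut-off 0.50 cell for
subskill 1:

```python
import skilldiag as sd
from skilldiag.experiment import StudyConfig, run_condition

config = StudyConfig(correlations=(0.1,), n_persons=1500,
                     n_replications=2, quad_points=11, base_seed=0)
result = run_condition(config, 0.1)
table = result.table
cell = table[(table.cutoff == 0.50) & (table.subskill == 1)]
print(cell[["model", "cutoff", "sccr", "pccr"]].to_string(index=False))
```

```
model  cutoff     sccr     pccr
 mirt     0.5 0.754000 0.436333
gdina     0.5 0.730000 0.407000
 rrum     0.5 0.728333 0.394000
```

MIRT classifies 75.4% of examinees correctly on subskill 1 at this
cut-off, a couple of points ahead of both latent-class models — the
continuous-trait model loses less information about examinees near the
cut-off. Its advantage widens as the subskill correlation grows,
because the EAP scores borrow strength across correlated dimensions.

The same pipeline is available from the shell:

```bash
skilldiag simulate --sc 0.3 --n 3000 --reps 25 --seed 0 --out sim/
skilldiag fit --model mirt --responses sim/responses_rep0.csv --m2 --out fit/
skilldiag study --preset desk --out study/
```

## Layout

| module | contents |
| --- | --- |
| `skilldiag.data_io` | Q-matrix / item-bank / response containers, CSV I/O, packaged instrument, parameter counting |
| `skilldiag.simulator` | equicorrelated ability draws, compensatory-3PL response generation |
| `skilldiag.mirt_engine` | MIRT EM calibration, EAP scoring, −2LL/AIC/BIC, M2/RMSEA |
| `skilldiag.cdm_engine` | G-DINA and R-RUM EM, posterior mastery probabilities, MLE/MAP classification |
| `skilldiag.classification` | Φ-transform, cut-off grid, SCCR/PCCR, histograms |
| `skilldiag.experiment` | condition/replication orchestration, aggregation, scatter export |
| `skilldiag.oracles` | brute-force oracles and toy cases backing the test suite |

See `docs/methods.md` for the statistical details and design choices.
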