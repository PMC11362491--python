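# dualrec

Dual-recollection multinomial processing-tree (MPT) modelling for
conjoint-recognition memory experiments.

## The problem

In a conjoint-recognition test, every item is probed with one of three
questions — *was it studied in context A?*, *was it studied in context B?*,
or *was it studied at all (A or B)?* — where the two contexts are episodic
tags such as important/unimportant or true/false. Raw yes-rates confound
genuine memory with guessing. The dual-recollection model separates them
into nine latent probabilities per person or group:

- `RC_A`, `RC_B` — **context recollection**: conscious retrieval of the
  study context attached to a target;
- `RT_A`, `RT_B` — **target recollection**: retrieval of the item itself,
  independent of its context tag;
- `F_A`, `F_B` — **familiarity**: an automatic old-signal that supports
  only the "A or B?" probe;
- `b_A`, `b_B`, `b_AB` — probe-specific yes-guessing biases.

Each (probe, item-class) cell is a binary processing tree. For a target
studied in context *c* with probe bias *b*:

```
consistent probe    P(yes) = RC_c + (1-RC_c)RT_c + (1-RC_c)(1-RT_c) b
inconsistent probe  P(yes) = (1-RC_c)RT_c + (1-RC_c)(1-RT_c) b
old ("A or B?")     P(yes) = RC_c + (1-RC_c)RT_c + (1-RC_c)(1-RT_c)F_c
                             + (1-RC_c)(1-RT_c)(1-F_c) b_AB
distractor          P(yes) = b   (bias of the probe alone)
```

Counts are independent binomials per cell. The hierarchical (latent-trait)
extension places participant *i*'s parameters at `theta_i = Phi(mu + delta_i)`
with `delta_i ~ MVN(0, Sigma)` on the probit scale, so individual
heterogeneity is estimated rather than ignored.

The package is aimed at memory researchers running conjoint-recognition /
value-directed-remembering studies who want the full analysis chain —
model-based estimates, credible-interval difference tests, posterior
predictive fit checks, and the classical descriptive statistics — plus a
synthetic-participant generator so every stage can be validated without
collecting data.

## Worked example

```python
import dualrec as dr
from dualrec.mcmc import McmcConfig

config = dr.experiment1_preset(seed=11)      # 48 participants, 9 cells
thetas, counts = dr.simulate_experiment(config)

model = dr.DualRecollectionModel(counts, config.design)
res = model.fit_bayes(mcmc=McmcConfig(chains=2, draws=1000, burn=600), seed=3)
print(res.summary().round(3))
print(res.difference("RC_A", "RC_B"))
print(res.difference("RT_A", "RT_B"))
```

prints

```
       mean     sd  bci_low  bci_high   rhat
RC_A  0.641  0.040    0.562     0.718  1.001
RC_B  0.305  0.050    0.208     0.399  1.007
RT_A  0.510  0.059    0.390     0.623  1.012
RT_B  0.295  0.036    0.229     0.371  1.014
F_A   0.160  0.105    0.009     0.399  1.008
F_B   0.093  0.061    0.005     0.221  1.013
b_A   0.012  0.005    0.004     0.024  1.002
b_B   0.060  0.013    0.036     0.088  1.005
b_AB  0.016  0.006    0.007     0.030  1.009
dRC <DifferenceSummary delta=+0.335, BCI=[0.196, 0.467], excludes_zero=True>
dRT <DifferenceSummary delta=+0.215, BCI=[0.083, 0.341], excludes_zero=True>
```

The generating group means were (.62, .35, .52, .26, .22, .10, .01, .05,
.02): every posterior mean lands close to its truth, all chains converge
(Rhat ≤ 1.05), and both recollection contrasts `ΔRC = RC_A − RC_B` and
`ΔRT = RT_A − RT_B` exclude zero — context and target recollection are
credibly higher for the prioritized context, exactly the structure the
generator planted. `res.ppc()` returns posterior-predictive p values for
the mean (T1) and covariance (T2) structure of the individual cell
frequencies; mid-range values (here ≈ 0.5) indicate a satisfactory fit.

A command-line pipeline wraps the same machinery:

```bash
dualrec simulate --preset exp1 --seed 7 --out run/
dualrec fit --counts run/counts.csv --preset exp1 --out run/fit/
dualrec compare --counts g1.csv --counts2 g2.csv --preset true_prioritized \
    --preset2 false_prioritized --out run/cmp/
dualrec recover --preset exp1 --reps 20 --out run/recovery/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main computation from scratch: it simulates the 48-participant
within-subject design at the published operating point, fits the
hierarchical model with 4 chains, runs the ΔRC/ΔRT difference tests, the
T1/T2 posterior predictive checks and the descriptive CAR statistics, and
writes its JSON output to `--out`. All randomness derives from `--seed`.
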