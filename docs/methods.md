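# Methods

## Measurement model

The dual-recollection model assigns each (probe, item-class) cell of a
conjoint-recognition test a binary processing tree over nine parameters
(`RC_A, RC_B, RT_A, RT_B, F_A, F_B, b_A, b_B, b_AB`, all probabilities).
Context recollection acts first: on a consistent context probe it forces
acceptance, on an inconsistent probe rejection. Target recollection acts
when context recollection fails and always produces acceptance.
Familiarity enters only the old ("A or B?") probe, after both recollection
processes fail. When no memory process resolves the trial, the probe's
guessing bias produces a yes with probability `b`. Distractor trees contain
only the bias, for every probe; in designs that split distractors into two
context-labelled classes the two classes therefore share identical
probabilities and are kept as separate cells only so their observed
frequencies can be inspected separately (12 cells instead of 9).

Cell counts are modelled as independent binomials. Within likelihood
evaluation, cell probabilities are clamped to `[1e-9, 1 - 1e-9]`; this
keeps logs finite at the boundary without moving interior optima.

## Moment estimator (the algebraic oracle)

The trees invert in closed form, which gives an estimator that is fully
independent of both the optimizer and the MCMC code. Biases are read off
the distractor cells (averaged over classes where there are two). Writing
`u = 1 - RC_c`, `v = u * RT_c`, `w = u(1 - RT_c)` per context:

```
w = (1 - p_consistent) / (1 - b_consistent)
v = p_inconsistent - w * b_inconsistent
u = v + w,   RC_c = 1 - u,   RT_c = v / u
F_c = 1 - (1 - p_old) / (w (1 - b_AB))
```

The system is exact even when `b_A != b_B` — no numerical fallback is
needed. Solutions outside `[0, 1]` are clamped and flagged
(`out_of_range`); unidentified cases (`u = 0`: RT undefined; `w = 0`: F
undefined) are flagged as `degenerate` rather than silently clamped. A
perfect consistent-probe rate together with *nonzero* inconsistent
acceptance cannot occur as an algebraic contradiction: `u = p_inc +
w(1 - b_inc)` is positive whenever `p_inc > 0`, so such patterns resolve to
interior estimates instead; the degenerate flags cover the reachable cases.

## Aggregate maximum likelihood

`DualRecollectionModel.fit()` maximizes the pooled binomial likelihood with
L-BFGS-B from the moment estimate of the pooled rates; standard errors come
from the finite-difference observed information. Estimates within `1e-5` of
0 or 1 are reported as boundary solutions. The MLE agrees with the moment
estimator to `1e-3` at cell sizes of `1e5` and recovers generating
parameters within 0.01 from `1e4` homogeneous participants (the familiarity
parameters carry a binomial SE of ~0.008 at that size, so the test suite
averages five simulations to keep the Monte-Carlo error well below the
tolerance).

## Hierarchical latent-trait model

Participant `i`'s parameter vector is `theta_i = Phi(mu + delta_i)`
elementwise with `delta_i ~ MVN(0, Sigma)`; the probit transform (not
logit) matches the latent-trait tradition for hierarchical MPTs. Priors:
`mu_s ~ N(0, 1)` independently, which is uniform on the probability scale
marginally, and `Sigma ~ Inverse-Wishart(df = 11, scale = I)`, weakly
informative for nine parameters. Group-level parameters are reported as
`Phi(mu)` per draw.

The sampler is Metropolis-within-Gibbs:

1. each of the nine probit columns of the participant effects gets a
   vectorized random-walk Metropolis update across all participants,
   re-evaluating only the tree cells that involve that parameter; step
   sizes adapt per participant x parameter during burn-in toward ~44%
   acceptance;
2. an interweaving (ASIS) step proposes a joint shift of `mu_s` and all
   participants' `alpha_is` — the non-centered update. Without it the
   weakly informed familiarity parameters mix an order of magnitude more
   slowly (split-Rhat ~1.6 at 1000 draws; ~1.01 with it);
3. `mu | alpha, Sigma` and `Sigma | alpha, mu` are conjugate draws
   (multivariate normal, inverse-Wishart).

Chains are seeded from independent `SeedSequence` children of one master
seed, so runs are bit-reproducible. Convergence is summarized by split-Rhat
(via ArviZ) on the probit group means with a 1.05 threshold; non-convergence
is flagged on the results object and fails the CLI with a nonzero exit, but
never silently alters output. Defaults are 4 chains, 2000 retained draws,
1000 burn-in; the seeded replication studies in the test suite use 2 chains
with 800/500 to fit a CI time budget — a deliberate compute scaling, chosen
once, that slightly widens Monte-Carlo error but does not change any model
assumption.

## Difference tests

Within-group contrasts (e.g. `dRC = RC_A - RC_B`) are computed per draw on
the probability-scale group means and summarized by the posterior mean and
the equal-tailed 95% credible interval; "difference present" means the
interval excludes zero. Between-group contrasts pair draws from two
independently fitted posteriors after a fixed-seed permutation (any pairing
of independent samples is valid; fixing it makes runs reproducible) and add
`p_b = P(delta < 0) + 0.5 P(delta = 0)`, the posterior mass at or below
zero — near 0 or 1 it signals a directionally consistent group difference,
and it equals 0.5 exactly when the two posteriors are identical.

## Posterior predictive checks

For each retained draw (a subsample of `n_rep >= 100`), the
participant-level parameters produce expected cell frequencies and one
replicated dataset. T1 is a Pearson-type discrepancy on the per-cell mean
frequencies; T2 is the sum of squared deviations between the
across-participant covariance matrix of cell frequencies and the
model-implied covariance (spread of expectations plus mean binomial
variance on the diagonal). The reported ppp is the fraction of draws whose
replicated discrepancy is at least the observed one. On well-specified
simulated data both ppp values fall inside [0.05, 0.95] in ≥ 90% of seeded
replications; inflating one cell's observed frequencies drives T1's ppp
down, which is the direction a misfit should move it. The exact T1/T2 forms
are documented constants of this package; other choices in the literature
differ in detail, so second-decimal agreement with any particular published
ppp value is not expected.

## Synthetic data generator

The generator emulates the hierarchy the analysis assumes — probit-normal
individual differences around group means, binomial counts at the tree
probabilities — with two design presets:

- within-subject value manipulation: 48 participants, 9 cells; 36 targets
  (6 per target cell: 36 / 2 contexts / 3 probes) and 36 distractors (12
  per distractor cell); generating means (.62, .35, .52, .26, .22, .10,
  .01, .05, .02);
- between-subject truth/falsity prioritization: 12 cells of 6 trials (18
  items per class / 3 probes), 36 participants (true-prioritized, means
  .75/.51, .33/.20, .35/.22, b = .05/.09/.03) or 38 (false-prioritized,
  truth-context means .50/.31/.17, falsity .59/.30/.14, b = .09/.02/.03).

The default random-effect covariance is diagonal with probit-scale SD 0.4
per parameter — no published covariance estimates exist to copy, and 0.4
yields visible but moderate heterogeneity (e.g. a group mean of .62 spreads
individuals over roughly .3–.85). It is a config field, not a constant.
Counterbalancing lists and buffer items are not simulated: the model
operates on cell counts, and counterbalancing only balances item
assignment. Consequently a green simulation-based test establishes that
the pipeline recovers the hierarchy it assumes; it cannot speak to
item-level effects, sequential dependencies, response times or real
participants' deviations from probit-normal heterogeneity.

## Descriptive statistics

Corrected acceptance rates are hit rate minus false-alarm rate on the same
probe (same-context distractor class in 12-cell designs); zero-trial cells
yield flagged missing values. The paired t (Cohen's d = mean/SD of
differences), Wilcoxon signed-rank (W = positive-rank sum, zeros dropped,
midranks for ties; rank-biserial `r_rb = (W+ - W-)/(W+ + W-)`; exact p for
n ≤ 25 without ties, else continuity-corrected normal) and the 2x2 mixed
ANOVA follow the conventions of standard analysis software: the ANOVA uses
the exact subject-means / difference-scores decomposition with unweighted
(Type-III) cell means for unequal group sizes, and partial eta squared
`SS_effect / (SS_effect + SS_error)`, which for one-df effects equals
`F / (F + df_error)`. All p values are two-tailed. The arcsine
variance-stabilizing transform is `asin(sqrt(p))`; CARs are first shifted
by `(car + 1)/2` since they can be negative (the shift convention is this
package's choice and is monotone, so it cannot change rank-based
conclusions).

## Known limitations

- Familiarity is estimated from a single branch of the old-probe tree,
  below both recollection processes; when recollection is high its
  posterior is wide and noticeably prior-influenced at realistic sample
  sizes. Headline conclusions should not rest on F contrasts.
- The latent-trait model assumes multivariate-normal probit effects; no
  beta-MPT or fixed-effects alternative is provided.
- Exactly two study contexts are supported; no Remember/Know or
  source-monitoring variants.
- Between-group `p_b` relies on independent fits; it is not a posterior
  under a joint hierarchical model of both groups.
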