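# Methods

## Data model

The unit of observation is one coded continuation: a participant completes
a two-sentence passage whose first sentence names two referents (NP1, the
surface subject; NP2, the surface non-subject), and coders record which
referent was mentioned first (`NP1`, `NP2`, `BOTH`, `UNCLEAR`, `OTHER`),
with which referring form (`NAME`, `OVERT_PRONOUN`, `NULL_PRONOUN`,
`OTHER_FORM`), and optionally under which coherence relation
(`EXPLANATION`, `RESULT`, `ELABORATION`, `OCCASION`, `OTHER_REL`).
Conditions cross verb type (IC1 subject-biased vs IC2 object-biased
implicit-causality verbs), prompt type (`FREE` vs `PRONOUN`), and syntactic
construction (`CANONICAL` active, `BA` active, `BEI` passive; under `BEI`
the surface subject NP1 is the logical object).

Only continuations with referent NP1/NP2 and an analyzable form are kept.
A record failing on both the referent and the form is tallied once, under
its referent reason — the two exclusion families are reported separately
and a precedence had to be fixed; referent-first is our convention.
Pronoun-prompt records always carry `form = OVERT_PRONOUN`: the prompt
supplies the pronoun, so form is not a participant choice there, and
ingestion enforces this rather than trusting the column.

## Estimation

Per (item, condition) cell of the free-prompt data, with V = 2 candidate
referents and W = 3 analyzable forms:

    P^(NPj)      = (Count(NPj) + W) / (Count(NP1) + Count(NP2) + V*W)
    P^(ta | NPj) = (Count(NPj and ta) + 1) / (Count(NPj) + W)

i.e. one pseudo-count per logically possible (referent, form) combination.
Both estimates are strictly inside (0, 1) for any counts, which keeps every
downstream prediction defined and every cross entropy finite.  Observed
pronoun-prompt interpretation proportions are left **unsmoothed**: they are
the behavioral target, not a model input, so p_obs may be exactly 0 or 1.

Items present on only one side (free-prompt estimates without
pronoun-prompt observations, or vice versa) are dropped from model
evaluation only, with a logged warning; they still appear in the estimate
and prediction tables.

## Linking models and evaluation

Predictions for P(NP1 | ta): Bayesian posterior, Expectancy (the prior
itself), Mirror (normalized production likelihoods), and a counterfactual
Bayesian variant in which the prior of the matched item in an alternate
construction — pairing key (experiment, item, verb type) — replaces the
item's own prior, used to separate prior effects of passivization from its
likelihood effects.

Per model, over the common item set:

- **MSE** — mean of (p_i − p̂_i)²;
- **ACE** — mean of −[p_i log₂ p̂_i + (1 − p_i) log₂(1 − p̂_i)] in bits.
  The negation makes lower-is-better, matching how such tables are read;
  by Gibbs' inequality ACE is bounded below by the mean binary entropy of
  the observed proportions, attained exactly at perfect calibration (it is
  zero only when observed proportions are themselves degenerate);
- **R²** — the squared Pearson correlation between observed and predicted
  vectors, *not* 1 − SS_res/SS_tot against the identity line.  The
  correlation form is deliberately calibration-blind — a model can score
  R² = 1 while systematically off — which is why it is reported together
  with MSE/ACE rather than instead of them.  It is undefined (NaN, with a
  warning) under zero variance or fewer than 3 items.

Model pairs are compared with classical two-sided paired t-tests on the
by-item squared-error and cross-entropy vectors (df = n_items − 1); items
are equally weighted regardless of their number of observations.
Zero-variance difference vectors yield a NaN statistic rather than an
error.

## Coherence mediation analyses

For coherence-coded free-prompt data, three descriptive tables per
condition, restricted by default to Explanation and Result (other
relations are too rare to analyze; the restricted set renormalizes):
the relation distribution, P(NP1 | relation), and P(relation | next
mention).  The mediation logic: if a construction manipulation moves next
mention *only* through coherence, its effect must appear in the relation
distribution and vanish in the relation-conditional next-mention rates.
Cells with zero denominator are omitted, never reported as 0/0.
Pronoun-prompt coherence codes are ignored here.

## The simulator

`generate_experiment` realizes the generative process the analyses assume.
Per item: a latent θ = P(next mention = NP1) drawn from
Beta(mean·κ, (1−mean)·κ); free-prompt referents ~ Bernoulli(θ); forms by
surface role only — pronominalize with P(pronoun | NPj), then overt vs
null; unanalyzable codes injected at configured rates; pronoun-prompt
referents drawn from a configurable responder's interpretation bias
computed from the *true* θ and production parameters (Bayesian posterior
by default, Expectancy or Mirror as alternatives).  Making the normative
posterior the default ground truth turns "the Bayesian linking model wins
on simulated data" into a falsifiable end-to-end property of the pipeline
rather than an assumption.

In **mediated mode** the free-prompt path is: relation ~ construction- and
verb-type-specific mixture, then referent ~ P(NP1 | relation, verb type),
which is construction-free.  Item-level variation enters as a logit-scale
tilt (sd `item_tilt_sd`, default 0.5) on the relation-conditional
probabilities, drawn once per (item, verb type) and shared across
constructions.  Construction therefore moves next mention exclusively
through the relation mixture — the mediation signature is exact in the
generator, and sampling noise is the only reason the conditional tables
can show a construction gap.

Determinism: every (item, condition, stage) cell gets its own
`numpy.random.Generator` seeded by `SeedSequence([seed, crc32(labels)…])`,
so output is byte-stable for a fixed config and adding items never
reshuffles existing ones.

### Calibrated defaults and what they rest on

`paper_calibrated_config(1 | 2 | 3)` emulates a three-experiment design:
36 items (16 IC1 + 20 IC2) × 50 participants per prompt condition;
experiment 1 canonical-active only (explanation-style continuations,
coherence uncoded), experiment 2 adds the `BEI` passive, experiment 3 the
`BA` active, both in mediated mode.

| parameter | value | status |
|---|---|---|
| IC1 / IC2 prior mean | 0.777 / 0.117 | published free-prompt NP1 rates |
| prior concentration κ | 30 | assumption: norming-selected verbs cluster around the class mean (sd ≈ 0.075 at the IC1 mean) |
| P(pronoun \| NP1) / P(pronoun \| NP2) | 0.60 / 0.15 | assumption: the reported large grammatical-role production asymmetry, at a magnitude consistent with the reported prior-to-posterior interpretation shift |
| overt share among pronouns, NP1 / NP2 | 0.825 / 0.915 | published per-condition shares (86/90/79/93%), averaged over verb types |
| exclusion rates BOTH / UNCLEAR / OTHER / OTHER_FORM | 0.008 / 0.038 / 0.027 / 0.010 | published exclusion percentages |
| relation mixtures | bei: Result 0.35 vs canonical 0.20; ba: Explanation 0.65 vs canonical 0.55 | directions published (passives elicit more Results, ba more Explanations); magnitudes assumed |
| P(NP1 \| relation, verb type) | Explanation 0.85 / Result 0.15 (IC1); everything object-biased (IC2) | assumption, consistent with reported relation-conditional biases |

Production is verb-type-independent by default, encoding the
strong-hypothesis null (verb semantics affects the prior only); the
`production` mapping is per surface role, so violating that null for power
analyses is a config edit, not a code change.

### What the simulator does not emulate

Participant-level random effects (every participant shares the condition
parameters); coder disagreement and drift in the exclusion categories;
list effects, item repetition and fatigue; any dependence of production on
topichood or construction.  Passing tests therefore certify the pipeline's
correctness and its behavior under the assumed generative structure — not
that real Mandarin completion data satisfies that structure.

## Numerical and design choices

- Cross entropy uses the convention 0·log₂0 = 0 and returns `inf` (never
  raises) for the genuinely infinite cases, which smoothing makes
  unreachable in the standard pipeline.
- Estimation treats (item, condition) as the unit: the same item id under
  two verb types or constructions yields separate cells, never pooled.
- Problem sizes in the test suite: the model-comparison pattern is checked
  at the study scale (36 items × 50 participants per prompt, 20 seeds);
  parameter recovery at 2,000 participants per cell; mediation at 200.
  Recovery checks allow at most one of 36 items outside ±3 binomial SEs —
  a Bonferroni-style allowance, since a strict all-items 3-sigma test at
  36 items has a ~10% false-alarm rate by construction.  Condition-mean
  checks use by-item (cluster) standard errors, because item-level theta
  variation makes pooled binomial SEs anti-conservative for comparing
  against a configured mean.

## Known limitations

- Only the two-referent, overt-pronoun case is modeled; no linking model
  is built for names or null pronouns (null pronouns participate in
  smoothing as one of the W = 3 form slots).
- The counterfactual-prior model requires a complete pairing; unmatched
  items are an error rather than silently skipped.
- R² is reported as missing for degenerate item sets instead of being
  clamped, so downstream consumers must tolerate NaN.
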