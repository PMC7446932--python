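# talink

Linking models for overt-pronoun interpretation in Mandarin
passage-completion experiments.

## The problem

When a Mandarin speaker reads *Meihui dadong-le Jieyi. Ta …* ("Meihui
touched Jieyi. She …"), who does *ta* refer to?  Passage-completion
experiments answer this empirically: participants complete a second
sentence either freely (the **free prompt**) or after a supplied overt
pronoun (the **pronoun prompt**).  Free-prompt continuations, once coded
for the first-mentioned referent and its referring form, estimate two
quantities per experimental item:

- the **next-mention prior** P(referent) — who gets talked about next,
  regardless of form;
- the **production likelihood** P('ta' | referent) — how likely a speaker
  is to use the overt pronoun for that referent.

Pronoun-prompt continuations measure the **interpretation bias**
P(referent | 'ta') directly.  Three linking models connect the two sides:

- **Bayesian**: P(NP1 | ta) = P(ta | NP1) P(NP1) / Σⱼ P(ta | NPⱼ) P(NPⱼ)
- **Expectancy**: P(NP1 | ta) ← P(NP1)
- **Mirror**: P(NP1 | ta) ← P(ta | NP1) / Σⱼ P(ta | NPⱼ)

`talink` implements the full analysis pipeline for coded datasets of this
kind — exclusion filtering, additively smoothed per-item estimation
(V = 2 referents, W = 3 forms), model predictions including a
counterfactual-prior variant for voice manipulations, item-by-item
evaluation (R², MSE, average cross entropy in bits, paired by-item
t-tests), coherence-relation mediation tables — plus a seeded generative
simulator of the experiments, so the whole pipeline runs and is testable
with no external data.  It is aimed at computational psycholinguists who
want to reanalyze coded completion data or run design/power explorations
in silico.

## Worked example

Simulate a 36-item, 50-participants-per-prompt experiment calibrated to
published free-prompt rates (77.7% NP1 next-mentions for subject-biased
IC-1 verbs, 11.7% for object-biased IC-2 verbs), with pronoun-prompt
behavior generated by the normative Bayesian posterior; then analyze it:

```python
import json
from talink.simulate import paper_calibrated_config, config_to_dict
cfg = paper_calibrated_config(1, seed=7)
open("expt1.json", "w").write(json.dumps(config_to_dict(cfg)))
```

```bash
talink simulate --config expt1.json --out sim/
talink analyze  --data sim/dataset.csv --out analysis/
talink report   --in analysis/
```

prints

```
Model evaluation
================

r_squared (higher is better; best first): EXPECTANCY, BAYESIAN, MIRROR
            EXPECTANCY  0.9402
              BAYESIAN  0.8431
                MIRROR  0.0116
mse (lower is better; best first): BAYESIAN, EXPECTANCY, MIRROR
              BAYESIAN  0.0160
            EXPECTANCY  0.0260
                MIRROR  0.1215
ace (lower is better; best first): BAYESIAN, EXPECTANCY, MIRROR
              BAYESIAN  0.7080
            EXPECTANCY  0.7657
                MIRROR  1.0697

Best-model tally across metrics:
    BAYESIAN: best on 2 of 3 metrics
    EXPECTANCY: best on 1 of 3 metrics

Paired by-item t-tests:
    BAYESIAN vs EXPECTANCY on squared_error: t(35) = -1.716, p = 0.09508
    BAYESIAN vs EXPECTANCY on cross_entropy: t(35) = -2.777, p = 0.008751
    BAYESIAN vs MIRROR on squared_error: t(35) = -6.570, p = 1.381e-07
    BAYESIAN vs MIRROR on cross_entropy: t(35) = -6.675, p = 1.009e-07
```

Because the simulated comprehender really is Bayesian, the Bayesian
linking model attains the lowest MSE and ACE.  The Expectancy model still
correlates almost perfectly with behavior (R² 0.94) while being
mis-calibrated — it lacks the production-bias boost toward NP1, so it
systematically underpredicts NP1 interpretations.  The Mirror model
predicts nearly the same value for every item (it lacks the prior), which
destroys its R².  `analysis/` additionally contains the exclusion report,
per-item estimates and predictions, condition-proportion tables,
observed-vs-predicted scatter data, and a run manifest.

The same `analyze` command accepts any externally coded dataset in the
documented CSV schema (`experiment, participant_id, item_id, verb_type,
prompt_type, construction, referent, form, coherence`).

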