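"""Run a QUEST contrast staircase against a simulated observer.

Builds a 50-trial adaptive staircase for a 2AFC orientation task, drives it
with a Weibull observer whose true contrast threshold is 0.15 Michelson,
and reads out the posterior-mean threshold estimate.
"""

import numpy as np

from gazebias.quest import (WeibullShape, attentional_imbalance,
                            quest_estimate, quest_init, quest_next,
                            quest_update, weibull_p_correct)

rng = np.random.default_rng(0)
shape = WeibullShape()          # slope 3.5, guess 0.5 (2AFC), lapse 0.02
true_threshold = 0.15

state = quest_init(prior_mean=0.2, prior_sd=0.3, clamp=(0.01, 0.9))
for trial in range(50):
    contrast = quest_next(state)
    p = float(weibull_p_correct(np.log10(contrast),
                                np.log10(true_threshold), shape))
    state = quest_update(state, contrast, bool(rng.random() < p))

est = quest_estimate(state)
print(f"true threshold: {true_threshold:.3f} Michelson")
print(f"posterior-mean estimate after 50 trials: {est:.3f}")
print(f"imbalance if the other location measured 0.18: "
      f"{attentional_imbalance(0.18, est):+.3f}")
# The estimate should land within ~0.02 of the true threshold; a positive
# imbalance means worse contrast sensitivity at the low-value location.
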