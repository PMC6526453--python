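"""The diffusion-model mathematics: choice probabilities, defective CDFs,
and agreement between the trial simulator and the analytic distribution.

A word decision is a noisy evidence accumulation between a "nonword" (lower)
and a "word" (upper) boundary. The signed-RT convention puts word responses
on the positive axis and negated nonword-response times on the negative
axis, so one curve describes choices and latencies jointly.
"""

import numpy as np

from pendiff import choice_probability, predicted_signed_cdf, simulate_trials
from pendiff.cohort import YOUNGER_MEANS

# probability of a (correct) word response at the younger-adult means
p_word = choice_probability(YOUNGER_MEANS.v_word, YOUNGER_MEANS.a,
                            YOUNGER_MEANS.zr_word)
print(f"P(word response | word stimulus, mean drift) = {p_word:.4f}")

# simulate 20,000 word trials and compare the empirical signed CDF with the
# quadrature-marginalized analytic prediction
rng = np.random.default_rng(1)
up, rt = simulate_trials(YOUNGER_MEANS, "word", 20_000, rng)
signed = np.sort(np.where(up, rt, -rt))
G = predicted_signed_cdf(YOUNGER_MEANS, "word", signed)
ecdf = np.arange(1, signed.size + 1) / signed.size
D = np.max(np.abs(ecdf - G))
print(f"simulated accuracy            = {up.mean():.4f}")
print(f"sup |ECDF - analytic CDF|     = {D:.4f}")
# D is at the Monte-Carlo noise level (~1/sqrt(n)): the simulator and the
# analytic first-passage formulas describe the same process.
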