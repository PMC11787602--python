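"""Fit the logistic psychometric function to one observer's responses.

Simulates 100 two-interval trials per comparison intensity from a logistic
observer with PSE 1.85 N and JND 0.22 N (an attenuated percept of the 2 N
test force), rebins the measured comparison forces to the canonical seven
intensities, fits the two-parameter logistic by maximum likelihood and
reports PSE, JND and McFadden's R².
"""

import numpy as np
import pandas as pd

from reachatten import fit_psychometric, response_table
from reachatten.synthetic_data import p_comparison_stronger

CANON = (1.0, 1.5, 1.75, 2.0, 2.25, 2.5, 3.0)
TRUE_PSE, TRUE_JND = 1.85, 0.22

rng = np.random.default_rng(3)
comparisons = np.repeat(CANON, 100) + rng.normal(0, 0.03, 700)  # actuator noise
p = p_comparison_stronger(comparisons, TRUE_PSE, TRUE_JND)
trials = pd.DataFrame(
    {
        "comparison_measured_n": comparisons,
        "response": np.where(
            rng.random(700) < p, "comparison_stronger", "test_stronger"
        ),
    }
)

tab = response_table(trials, CANON)
print(tab.to_string(index=False))

fit = fit_psychometric(tab)
print(f"\nbeta0 = {fit.beta0:.2f}, beta1 = {fit.beta1:.2f}  (converged: {fit.converged})")
print(f"PSE = {fit.pse:.3f} N   (truth {TRUE_PSE}; perceived intensity of the test force)")
print(f"JND = {fit.jnd:.3f} N   (truth {TRUE_JND}; discrimination threshold)")
print(f"McFadden R2 = {fit.mcfadden_r2:.3f}")
print(
    "\nA PSE below the 2 N test force means the test force felt weaker than\n"
    "it was: the observer needed a weaker comparison to call the two equal."
)
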