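"""Where does outcrossing pay for itself?

Evaluates the androdioecy maintenance condition alpha*(1-sigma) >
2*beta*(1-delta) and the rare-male growth factor of the male
maintenance recursion.  Males (hence outcrossing) persist only when the
compound outcross-fitness alpha exceeds the two-fold cost of males.
"""

from selftrans import (
    androdioecy_maintenance_condition,
    estimate_alpha_from_male_frequencies,
    male_maintenance_step,
    rare_male_growth_factor,
)

for alpha in (1.0, 1.41, 1.76, 2.0, 2.4):
    maintained = androdioecy_maintenance_condition(alpha)
    growth = rare_male_growth_factor(alpha)
    print(
        f"alpha = {alpha:4.2f}: rare-male growth factor {growth:.3f} "
        f"-> males {'maintained' if maintained else 'lost'}"
    )

# The lab-adapted population's own outcross-fitness, from its male
# frequencies one generation apart in high salt (0.45 -> 0.31):
m0, m1 = 0.4526, male_maintenance_step(0.4526, 1.37)
alpha_hat = estimate_alpha_from_male_frequencies(m0, m1)
print(f"\nmale frequencies {m0:.3f} -> {m1:.3f} imply alpha = {alpha_hat:.2f}")
print("below 2: outcrossing does not offset the cost of males in high salt")
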