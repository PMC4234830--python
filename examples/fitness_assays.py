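"""The study's fitness estimators on synthetic assay tables.

Transition fitness s (slope of the log allele ratio over generations),
competitive fitness w against a GFP tester with the heterozygote
correction and block centring, and male fitness w_m from mating-plate
progeny counts with the QC filters applied.
"""

import numpy as np

from selftrans import (
    block_center_and_delta,
    competition_fitness,
    male_fitness,
    qc_filter_male_plates,
    transition_fitness,
)
from selftrans.synth import gen_competition_dataset, gen_male_fitness_dataset

# transition fitness from clamped allele counts (two-point illustration:
# undetected at gen 0 in 96 alleles -> 1/97; fixed at gen 10 -> 96/97)
s, se = transition_fitness([(0, 48, 96), (10, 96, 96)])
print(f"transition fitness from 48/96 -> 96/96 over 10 generations: s = {s:.3f}")

records, truth = gen_competition_dataset(true_w=0.5, seed=11)
estimates = block_center_and_delta(
    [competition_fitness(r) for r in records], "ANC"
)
w_t = np.array([e.w_t for e in estimates if e.population_id == "EXP"])
print(
    f"competitive fitness: mean w_t = {w_t.mean():.3f} +/- "
    f"{w_t.std(ddof=1) / np.sqrt(w_t.size):.3f} (generating value {truth.true_w})"
)

plates, m_truth = gen_male_fitness_dataset(true_w_m=1.1, qc_violation_rate=0.2, seed=12)
kept, tally = qc_filter_male_plates(plates)
w_m = np.array([male_fitness(r) for r in kept])
print(
    f"male fitness: mean w_m = {w_m.mean():.3f} over {len(kept)} plates "
    f"(generating value {m_truth.true_w_m}; rejected {tally})"
)
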