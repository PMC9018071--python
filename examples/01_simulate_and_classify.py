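"""Simulate a mixed cohort and classify per-cell ATP dynamics.

Generates 200 synthetic cells (65% stable, 35% carrying a deep ATP dip or an
irreversible shift), runs the fixed-threshold classifier, and compares the
recovered class fractions with the generator's ground truth.
"""

from collections import Counter

from queenflux import SyntheticConfig, cohort_classify, gen_cohort
from queenflux.config import CohortMix

config = SyntheticConfig(
    n_cells=200,
    mix=CohortMix(stable=0.65, dip=0.25, shallow_dip=0.0, shift=0.10),
)
cohort = gen_cohort(config, seed=1)

fractions, labels, events = cohort_classify(cohort.ratio_traces, doubling_time_min=288.0)
truth_counts = Counter(c.label for c in cohort.truth.cells)

print("classified fractions:", {k: round(v, 3) for k, v in fractions.items()})
print("ground-truth counts: ", dict(truth_counts))
print(f"{len(events)} depletion events detected; each row gives onset, depth "
      "(ratio units) and duration (min)")
print(events.head().to_string(index=False))
# A dip is a recovered decrease > 0.5 ratio units spanning > 2 frames; a shift
# never recovers.  Fractions should match the generated mixture to within
# binomial sampling noise.
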