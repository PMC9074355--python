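"""Cohort scoring: cumulative percentages, median cut-offs, transitions.

Emulates a scored cohort (both the visual-assessment oracle and the
digital arm), derives the St. Gallen median +/- 10 pp cut-offs from
each method's own 500-cell median, and shows how cases reclassify
between 100 and 500 counted cells.
"""

import numpy as np

import ki67flow as kf

records = kf.simulate_cohort(kf.CohortConfig(n_patients=100, seed=2))
va, dia = kf.simulate_case_scores(records, seed=3)

for method, scores in (("VA", va), ("DIA", dia)):
    medians = [float(np.median([s.cumulative_at(k) for s in scores]))
               for k in range(1, 6)]
    print(f"{method} cumulative medians (100..500 cells): "
          + ", ".join(f"{m:.1f}" for m in medians))
    scheme = kf.derive_cutoffs(kf.cohort_median(scores, 5), method)
    print(f"  {method}500 median {scheme.median_pct:.1f}% -> cut-offs: "
          f"Low < {scheme.low_below:.1f}, High > {scheme.high_above:.1f}")
    tt = kf.transition_table(scores, scheme, k_from=1, k_to=5)
    print(f"  categories at 100 cells: {tt.start_counts}")
    print(f"  categories at 500 cells: {tt.end_counts}")

# Digital counting starts in the hottest 100 cells, so its medians fall
# as counting proceeds and High cases at 100 cells shrink by 500 cells;
# the emulated visual arm moves much less.
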