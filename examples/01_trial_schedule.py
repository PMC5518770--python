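"""Generate the task's trial schedule and the event-regressor bookkeeping.

Builds the published per-set trial structure (48 trials of 1-3 items, two
thirds probed), enumerates every displayed item, and combines same-label
occurrences in threes into event regressors.  The combination must arrive at
42 presentation + 27 recognition regressors - the 69 beta images each
participant's GLM stage later produces.
"""

from collections import Counter

from seqpos import combine_occurrences, enumerate_occurrences, \
    replicate_table_design

design = replicate_table_design(seed=1)
print(f"trials: {design.n_trials}, lengths: {dict(sorted(design.length_counts.items()))}")
print(f"probed: {sum(t.has_recognition for t in design.trials)} "
      f"({design.probed_fraction:.0%}), run length: {design.duration_s:.0f} s "
      f"({design.n_volumes} volumes at TR {design.tr_s} s)")

occurrences = enumerate_occurrences(design)
per_phase = Counter(o.phase for o in occurrences if o.valid)
print(f"valid item occurrences: {dict(per_phase)}")

regressors = combine_occurrences(occurrences, seed=1)
print(f"event regressors after n=3 combination: {regressors.counts_by_phase} "
      f"-> {len(regressors)} beta images per participant")
# Each regressor averages up to three same-labelled items spread across the
# run; 69 regressors is the count the estimation stage must reproduce.
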