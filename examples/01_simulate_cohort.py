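"""Generate a small synthetic cohort with planted brain-state structure.

Each subject gets a 120-frame resting scan and a 225-frame n-back task scan
(nine 25-frame blocks cycling 0-back/1-back/2-back) of 50-region BOLD built
from five planted coactivation states, plus covariates (age, sex,
handedness, intracranial volume, mean framewise displacement, per-block d').
"""

import numpy as np

import brainstates as bs

cohort = bs.generate_cohort(bs.CohortConfig(n_subjects=8), seed=0)

rest = [s for s in cohort.scans if s.condition == "rest"]
task = [s for s in cohort.scans if s.condition == "nback"]
print(f"subjects: {len(rest)}")
print(f"rest scans:  {rest[0].data.shape} (frames x regions), TR {rest[0].tr} s")
print(f"task scans:  {task[0].data.shape}, blocks {sorted(set(task[0].block_labels))}")
print(f"planted states: {cohort.truth.planted_centroids.shape[0]}, "
      f"mean dwell {cohort.truth.dwell} frames")
print("planted rest jump matrix (row-stochastic, zero diagonal):")
print(np.round(cohort.truth.rest_tp, 2))
print("\ncovariates:")
print(cohort.covariates.head(3).round(2).to_string(index=False))
# The jump matrix gives the probability of each *new* state after leaving a
# state; the scans are what the clustering stage consumes.
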