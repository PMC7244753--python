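"""Cluster concatenated BOLD frames into brain states and name them.

Frames from all subjects are z-scored per region within each scan,
concatenated, and clustered with k-means under correlation distance
(best of 20 restarts). States are named after the resting-state system
their dominant positive or negative component aligns with.
"""

import brainstates as bs

cohort = bs.generate_cohort(bs.CohortConfig(n_subjects=20), seed=0)
X, index = bs.concatenate_scans(cohort.scans)
print(f"group matrix: {X.shape[0]} frames x {X.shape[1]} regions")

model = bs.fit_kmeans(X, k=5, n_reps=20, seed=1)
names, alignment = bs.name_states(model.centroids, cohort.parcellation)
model.names = names
print(f"k = 5 states: {', '.join(names)}")
print(f"variance explained: {model.variance_explained:.3f}")

elbow = bs.elbow_scan(X, range(2, 9), n_reps=5, seed=2)
print("\nvariance explained by k (gain = increase per unit k):")
print(elbow.round(4).to_string(index=False))
# The gain drops below 1% beyond the planted k = 5: the elbow identifies the
# planted number of states. Each state name marks the system whose regions
# are coherently above (+) or below (-) their mean in that state.
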