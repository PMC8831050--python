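"""Generate a synthetic telemonitoring dataset with planted clusters.

Each subject belongs to one of three latent patient groups; all of a
subject's recordings share that group.  Voice features are correlated
within a group, and the two UPDRS targets are group-specific nonlinear
functions of the features plus noise.
"""

import numpy as np

from updrs import SyntheticConfig, generate

cfg = SyntheticConfig(n_subjects=12, recordings_per_subject=25, n_clusters=3,
                      cluster_separation=6.0, feature_correlation=0.5,
                      target_noise_sd=2.0, seed=1)
table, truth, params = generate(cfg)

print(f"rows: {table.n_rows}, features: {table.n_features}")
print(f"cluster sizes: {np.bincount(truth.labels)}")
print(f"motor UPDRS range: [{table.motor_updrs.min():.1f}, {table.motor_updrs.max():.1f}]")
print(f"total UPDRS range: [{table.total_updrs.min():.1f}, {table.total_updrs.max():.1f}]")
print(f"targets clipped to scale bounds: {params['n_clipped_targets']}")

# The cluster means are 6 within-cluster SDs apart, so the groups are
# well separated in feature space; the printed sizes are balanced
# because subjects are assigned to groups in rotation.
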