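# Full-pipeline demo for `updrs run --config examples/demo_run.yaml`.
# Mirrors the reference experimental setting at reduced scale: EM at
# k = 8, 10, 12, 13 and SOM maps 2x3, 2x4, 3x3, 3x4 on a 1,000-row
# synthetic dataset, with the reduced tuning grid.  Takes a few minutes;
# switch `grid: full` for the exhaustive 19 x 20 x 221 search.
synthetic:
  n_subjects: 40
  recordings_per_subject: 25
  n_clusters: 3
  cluster_separation: 6.0
  seed: 7
em_k: [8, 10, 12, 13]
som_maps: [[2, 3], [2, 4], [3, 3], [3, 4]]
methods: [voting, cspa, hgpa]
target_k: 8
mask_fraction: 0.1
fit:
  grid: fast
  seed: 7
som_epochs: 50
include_baselines: true
seed: 7
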