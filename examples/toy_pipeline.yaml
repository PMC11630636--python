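# Example pipeline configuration: rebuild a reduced permeation MSM for the
# bundled six-state model from simulated trajectories.
#
# Run with:  permkin -v pipeline examples/toy_pipeline.yaml -o out/
#
# Every stage prints the current it predicts (pA); with the amount of data
# below all checkpoints land within a few percent of the analytic 2.09 pA.

# Input: either a list of trajectory files under `trajectories:` (one state
# label per line, `# frame_interval_ns:` header) or a simulator block that
# generates them on the fly from a rate-matrix file ("toy" = bundled model).
simulator:
  rate_matrix: toy
  duration_ns: 60000.0      # per replica
  frame_interval_ns: 0.1    # sampling interval of the discretized output
  replicas: 2

# Lagtimes (ns) at which transition matrices are estimated and the reduced
# model is tested for Markovian behavior; must be multiples of the frame
# interval, strictly increasing.
lagtime_ladder_ns: [1.0, 30.0]

# Ordered lumping stages.  `ion_only` merges states that differ only in
# water placement; `explicit` applies a micro->macro map (inline or a
# two-column file); `spectral` clusters via the eigenvalue gap (give
# n_macro explicitly -- the gap suggestion is advisory).
lumping:
  - strategy: ion_only
  - strategy: explicit
    map:
      OOKKOK: WOKKOK
      KOKKOK: KOKKOK
      KOKKOO: KOKKOO
      KOKOOK: X
      KOOKOK: X
      OKOKOK: X

# Advisory thresholds: max elementwise Chapman-Kolmogorov deviation that
# still counts as Markovian, and the relative mismatch between the model
# current and the direct trajectory count that triggers the
# too-large-lagtime warning.
ck_threshold: 0.02
step2_mismatch_threshold: 0.10

# Rate-matrix fit: weight of the current-mismatch regularization and the
# number of seeded optimizer restarts.
fit_lambda: 1.0
fit_restarts: 5

# Root seed: simulation replicas use seed + replica index; the fit restarts
# derive from the same value.
seed: 5
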