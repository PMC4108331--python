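"""Topology recovery from relative abundances under measurement noise.

Corrupts compositional (relative-abundance) observations with multiplicative
log-normal measurement noise — the regime sequencing data lives in — and
tracks how sensitivity and specificity of the inferred topology respond.
Scaled down (2 communities, 2 thresholds) to run in ~30 s.
"""

from limits.benchmark import noise_robustness_benchmark

sweep = noise_robustness_benchmark(
    n_matrices=2,
    noise_levels=(0.0, 0.05, 0.10),
    thresholds=(0.01, 0.05),
    n_bootstrap=25,
    seed=0,
)

table = sweep.groupby(["noise", "threshold"])[["sensitivity", "specificity"]].mean()
print(table.round(2))

# Specificity stays high at every noise level (the median aggregation rarely
# keeps a spurious edge), while sensitivity decays as measurement noise
# drowns the per-edge signal — missed edges, not invented ones, are the
# dominant failure mode under noise.
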