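"""Compare enhancement-integrated pipelines on a common phantom set.

Every method segments the identical seeded phantoms; the summary holds
per-method average sensitivity / accuracy / specificity, mirroring how
vessel-segmentation papers tabulate per-database averages.
"""

from gaborvessel import ExperimentConfig, PhantomConfig, PsoConfig, SegmentationConfig, run_experiment

config = ExperimentConfig(
    n_images=4,
    methods=("none", "gcadw", "usm", "pso_usm"),
    phantom=PhantomConfig(),
    segmentation=SegmentationConfig(pso=PsoConfig(max_iterations=20, swarm_size=15)),
    out_dir="scratch/comparison",
    seed=0,
)
summary = run_experiment(config)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("Per-image tables were written to scratch/comparison/results_<method>.csv.")
print("On these high-contrast phantoms the plain Gabor baseline is already")
print("strong; the enhancement stages matter most when vessel contrast is")
print("weak relative to illumination drift, as in real fundus photographs.")
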