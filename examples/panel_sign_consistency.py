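"""Sign-consistency rates across outcome scales in a simulated panel study.

Simulates small multi-SNP panels with randomly directed true interaction
effects (half aligned with, half opposed to, the main effects), then
measures the sign-consistency rate among detected interactions on the
original, log-transformed and inverse-normal-transformed scales.
"""

from gxesign import PanelConfig, ShiftPolicy, make_transform, replicate_experiment

cfg = PanelConfig(n_samples=4000, n_snps=80, n_interacting=40)

for transform, label, shift in (
    (make_transform("log"), "log", ShiftPolicy("to_positive", margin=0.1)),
    ("int", "inverse normal", None),
):
    table = replicate_experiment(cfg, transform, shift=shift, n_reps=5,
                                 sigma2_grid=(0.5,), base_seed=11)
    row = table.iloc[0]
    print(f"{label:>15}: rate original {row.rate_original_mean:.3f}  ->  "
          f"rate transformed {row.rate_transformed_mean:.3f}   "
          f"(detections {row.n_detected_original_mean:.0f} -> "
          f"{row.n_detected_transformed_mean:.0f})")

print()
print("True interactions are directed at random, so the original-scale rate")
print("sits near 0.5.  The concave log pushes detected interactions toward")
print("a single sign relationship with the main effects; the rank-based")
print("inverse normal transformation, being non-convex, largely does not.")
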