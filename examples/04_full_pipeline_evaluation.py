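"""The full synthetic study: train, then compare post-processing arms.

Runs the packaged recovery experiment (200 training scenes, 50 clean
evaluation scenes; 10-15 minutes on one CPU core) and prints the
false-positive and retention numbers per arm.
"""

from hyperfod.experiments import RecoveryConfig, run_synthetic_recovery

result = run_synthetic_recovery(RecoveryConfig(seed=1))

print(f"held-out mIoU over present classes: {result.holdout_miou:.3f}")
print()
print(f"{'arm':>15}  {'FP images':>9}  {'FP pixels':>9}")
for arm in ("raw", "erosion", "rules", "rules+erosion"):
    print(f"{arm:>15}  {result.fp_images[arm]:>9d}  {result.fp_pixels[arm]:>9d}")
print()
print(
    f"ground-truth blobs with a 3x3 core still detected after rules+erosion: "
    f"{result.tp_core_blobs_detected}/{result.tp_core_blobs_total} "
    f"({100 * result.tp_core_retention:.1f}%)"
)
print()
print("The raw model alarms on clean product (hard fat speckles mimic PEHD")
print("around 1222 nm); the spectral rules plus 3x3 erosion remove every such")
print("false positive while keeping the true contaminants that have a 3x3 core.")
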