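"""Generate synthetic methylomes for each species-style preset and compare
the estimated global methylation level against the closed-form expectation.

Each preset emulates one architecture: mosaic domains (anemone, urchin-like
deuterostome), sparse mosaic (bee), intermediate (chicken) or global
methylation with unmethylated CpG islands (fish, mammal). The last column
is the species-level value the preset is calibrated to.
"""
import methreprog as mr

PAPER_LEVELS = {
    "anemone_mosaic": 0.11,
    "bee_sparse": 0.01,
    "deutero_mosaic": 0.27,
    "chicken_intermediate": 0.42,
    "fish_global": 0.795,
    "mammal_global": 0.795,
}

print(f"{'preset':<22} {'estimated':>9} {'closed-form':>11} {'calibrated to':>13}")
for preset, paper in PAPER_LEVELS.items():
    spec = mr.make_spec(preset, seed=1)
    truth = mr.assign_truth(spec)
    sperm = mr.simulate_counts(truth, spec, "sperm")
    est = mr.global_ml(sperm, min_cov=5).site_mean
    exp = mr.expected_global_ml(spec, observed=True)
    print(f"{preset:<22} {est:9.4f} {exp:11.4f} {paper:13.2f}")

print(
    "\nEstimates track the closed form within sampling noise; small offsets"
    "\ncome from the designed gene-set overlays and the read error model."
)
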