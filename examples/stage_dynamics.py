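"""Across-stage methylome dynamics per preset: per-stage global levels,
the qualitative dynamics class (none / minor / moderate / dramatic), the
genome-wide demethylation flag, and gamete divergence along the
evolutionary series.
"""
import methreprog as mr

for preset in ["anemone_mosaic", "deutero_mosaic", "fish_global", "mammal_global"]:
    spec = mr.make_spec(preset, seed=1)
    truth = mr.assign_truth(spec)
    tables = {s: mr.simulate_counts(truth, spec, s) for s in spec.stages}
    mls = [(s, mr.global_ml(tables[s], min_cov=5).site_mean) for s in spec.stages]
    dyn = mr.classify_dynamics(mls)
    _, bin_delta = mr.sperm_oocyte_divergence(tables["sperm"], tables["oocyte"])
    trail = " -> ".join(f"{s}:{v:.2f}" for s, v in mls)
    print(f"{preset:<22} {trail}")
    print(f"{'':<22} class={dyn.dynamics_class}  demethylation={dyn.demethylation_flag}"
          f"  gamete divergence (1 kb bins)={bin_delta:.3f}\n")

print("Divergence increases monotonically through the series, the mammal-style"
      "\ntrajectory alone shows genome-wide demethylation at the ICM-like stage.")
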