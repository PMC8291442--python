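"""Positional structure on a fish-style (globally methylated) methylome:
the promoter hypomethylation dip around TSSs and mosaic-domain
segmentation of an anemone-style methylome.
"""
import numpy as np

import methreprog as mr

fish_spec = mr.make_spec("fish_global", seed=1)
fish_truth = mr.assign_truth(fish_spec)
fish = mr.simulate_counts(fish_truth, fish_spec, "sperm")

profile = mr.tss_metaprofile(fish, fish_truth.annotation, flank=6000, bin_bp=100)
center = np.nanmean(profile.mean_ml[55:65])
flanks = np.nanmean(np.r_[profile.mean_ml[:10], profile.mean_ml[-10:]])
print(f"TSS metaprofile ({profile.n_bins} bins of {profile.bin_bp} bp):")
print(f"  mean ML at TSS +-500 bp: {center:.3f}")
print(f"  mean ML at outer flanks: {flanks:.3f}   (promoter dip)")

spec = mr.make_spec("anemone_mosaic", seed=1)
truth = mr.assign_truth(spec)
sperm = mr.simulate_counts(truth, spec, "sperm")
domains = mr.segment_domains(sperm, smooth_w=5, state_threshold=0.5)
meth = domains[domains.state == "methylated"]
print(f"\nmosaic segmentation of the anemone-style methylome:")
print(f"  {len(domains)} domains, {len(meth)} methylated")
print(f"  methylated domains: mean ML {meth.mean_ml.mean():.3f}, "
      f"median size {int(meth.n_cpgs.median())} CpGs")
print(f"  fraction of CpGs in methylated domains: "
      f"{meth.n_cpgs.sum() / domains.n_cpgs.sum():.3f}  (designed: 0.115)")
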