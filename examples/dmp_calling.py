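"""Differentially methylated promoters between sperm and oocyte on a
deuterostome-style methylome carrying 200 designed DMPs (truth delta 0.85)
among ~1000 gene promoters, and their recovery by the Fisher + BH caller.
"""
import methreprog as mr

spec = mr.make_spec("deutero_mosaic", seed=1, n_genes=1000, n_dmps=200)
truth = mr.assign_truth(spec)
sperm = mr.simulate_counts(truth, spec, "sperm")
oocyte = mr.simulate_counts(truth, spec, "oocyte")

dmps = mr.call_dmps(sperm, oocyte, truth.annotation.promoters,
                    min_cov=5, min_cpgs=3, delta_min=0.2, alpha=0.05)
called = set(dmps.loc[dmps.status != "ns", "gene_id"])
designed = set(truth.designed_dmps.gene_id)

print(f"promoters tested: {len(dmps)}")
print(f"DMPs called:      {len(called)} "
      f"(hyper in sperm: {(dmps.status == 'hyper_in_a').sum()}, "
      f"hypo in sperm: {(dmps.status == 'hypo_in_a').sum()})")
print(f"recall of designed DMPs: {len(called & designed) / len(designed):.3f}")
print(f"observed FDR:            {len(called - designed) / max(len(called), 1):.3f}")

matrix = mr.dmp_heatmap_matrix({"sperm": sperm, "oocyte": oocyte},
                               dmps, truth.annotation.promoters)
print(f"\nheatmap matrix: {matrix.shape[0]} promoters x {matrix.shape[1]} samples,"
      f" rows ordered by delta; first row: "
      f"{matrix.iloc[0].round(3).to_dict()}")
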