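"""Metagene DNase-sensitivity profiles and the cold-stress comparison.

Profiles active genes over 100 upstream-flank + 100 body + 100
downstream-flank bins, then quantifies the per-gene body-signal change
between cold and RT.
"""

import numpy as np

from coldchrom import SimConfig, generate_annotation, metagene_profile, sensitivity_change, simulate_dnase

cfg = SimConfig(seed=7)
ann, labels = generate_annotation(cfg)
rt = simulate_dnase(cfg, ann, labels, "RT", 1)
cold = simulate_dnase(cfg, ann, labels, "cold", 1)
active = [ann[g] for g in sorted(labels.active)]

for name, track in (("RT", rt), ("cold", cold)):
    mg = metagene_profile(track, active)
    prof = mg.mean_profile()
    print(f"{name}: peak bin {int(np.argmax(prof))} "
          f"(bins 80-99 = last 200 bp of the upstream flank), "
          f"mean body signal {prof[100:200].mean():.2f}")

table, summary = sensitivity_change(cold, rt, active)
print(f"gene-body log2(cold/RT): median {summary['median_log2_ratio']:.2f} "
      f"over {summary['n_genes']} active genes, "
      f"signed-rank p = {summary['p_signed_rank']:.2e}")
# The promoter hotspot puts the profile maximum just upstream of the
# TSS in both conditions; only cold elevates the gene-body bins.
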