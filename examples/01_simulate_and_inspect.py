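"""Simulate a study-like fibular landmark sample and inspect its structure.

Builds the procedural two-epiphysis template, draws 136 specimens in the
published design (ER 24F/23M, SAR 29F/43M, SA 10F/7M) with size dimorphism,
allometry, population offsets, and landmark noise, and prints what the
generator produced.
"""

import numpy as np

import fibmorph as fm

params = fm.default_params(seed=7, preset="study-like")
sample, truth = fm.simulate_sample(params)

print(f"specimens: {len(sample)}")
print(f"template: {sample.template.size} points, "
      f"{sample.template.role_counts()}")

lncs = truth.table.groupby("sex").true_lncs.mean()
print(f"mean lnCS by sex: F={lncs['F']:.3f}  M={lncs['M']:.3f} "
      f"(generating shift {params.lnCS_sex_shift})")
# Males are larger by ~0.08 log units, i.e. about 8% in centroid size,
# mirroring the size dimorphism the analysis is designed to detect.

cs = np.array([fm.centroid_size(c.coords) for c in sample.configurations])
print(f"centroid size range: {cs.min():.1f}-{cs.max():.1f} mm")
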