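"""Shape-space vs form-space PCA of a dimorphic sample.

Form space augments the Procrustes shape coordinates with ln(centroid
size): when dimorphism is mostly size-mediated, form PC1 absorbs it while
shape PCs barely separate the sexes.
"""

import fibmorph as fm

params = fm.default_params(seed=7)
params.n_per_group = {("ER", "F"): 25, ("ER", "M"): 25}
sample, _ = fm.simulate_sample(params)
gpa = fm.gpa_align([c.coords for c in sample.configurations])
sex = sample.labels_for("sex")

shape = fm.shape_pca(gpa)
form = fm.form_pca(gpa)
print("variance explained by PC1/PC2:")
print(f"  shape: {100 * shape.variance_fraction[0]:.2f}% / "
      f"{100 * shape.variance_fraction[1]:.2f}%")
print(f"  form:  {100 * form.variance_fraction[0]:.2f}% / "
      f"{100 * form.variance_fraction[1]:.2f}%")

for name, model in (("shape", shape), ("form", form)):
    m = model.scores[sex == "M", 0].mean()
    f = model.scores[sex == "F", 0].mean()
    print(f"  {name} PC1 mean score: M={m:+.4f}  F={f:+.4f}")
# By convention form PC1 is oriented so larger lnCS maps to positive
# scores: males plot on the positive side.

for res in fm.correlate_pc_cs(shape, gpa.centroid_sizes, [0, 1]):
    print(f"  shape PC{res.pc_index + 1} vs CS: r={res.r:+.3f} (p={res.p:.3g})")
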