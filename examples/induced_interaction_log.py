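"""A purely additive outcome shows a G×E effect after log-transformation.

Simulates one haploid variant (MAF 0.4) and a continuous exposure acting
additively on a Gaussian outcome, Y ~ N(10 + 4G + E, 1), then fits the
interaction regression on the raw and the log scale.
"""

from gxesign import apply_transform, fit_gxe, make_transform, simulate_single_snp

ds = simulate_single_snp(n=1000, maf=0.4, seed=1)

raw = fit_gxe(ds, 0)
ylog, _ = apply_transform(ds.phenotype, make_transform("log"))
logged = fit_gxe(ds.with_phenotype(ylog), 0)

print(f"raw scale : gamma = {raw.gamma:+.4f}  (p = {raw.p_gamma:.3g})")
print(f"log scale : gamma = {logged.gamma:+.4f}  (p = {logged.p_gamma:.3g})")
print()
print("The generating model has no interaction, and the raw-scale test is")
print("null; the log (monotone, concave) re-expression of the same data")
print("induces a significant interaction whose sign is opposite to the")
print("main genetic effect, as the product sign rule predicts for a")
print("concave map with a positive exposure effect.")
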