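"""The analytic product sign rule, and where it stops applying.

For a monotone map with globally signed second derivative, the induced
interaction sign is sgn(phi'') * sgn(alpha_phi) * sgn(beta_phi).  For
piecewise-convex maps such as the logistic, the sign is variant-specific
and only the numeric induced-coefficient oracle resolves it: here two
variants with same-sign main effects get opposite-sign interactions on a
logistic risk scale centered at 7.
"""

from gxesign import CellMeans, induced_coeffs, make_transform, predict_sign


def cells(p00, p10, p01, p11):
    keys = [(0, 0), (1, 0), (0, 1), (1, 1)]
    return CellMeans(P=dict(zip(keys, (p00, p10, p01, p11))),
                     counts={k: 1 for k in keys})


log = make_transform("log")
pred = predict_sign(log.curvature_sign, sign_alpha=+1, sign_beta=+1)
print(f"log, alpha>0, beta>0  ->  induced interaction sign {pred.predicted_sign:+d}")

logistic = make_transform("logistic", x0=7.0)
for name, cm in (("variant 1", cells(5.0, 8.0, 5.5, 8.5)),
                 ("variant 2", cells(5.7, 8.7, 6.7, 9.7))):
    ic = induced_coeffs(cm, logistic)
    print(f"{name}: beta_phi = {ic.beta_phi:+.7f}, gamma_phi = {ic.gamma_phi:+.7f}")

print()
print("Both variants have positive main effects on the risk scale, yet")
print("their induced interactions point in opposite directions — the")
print("logistic's curvature changes sign across the cell means, so no")
print("single sign relationship holds across variants.")
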