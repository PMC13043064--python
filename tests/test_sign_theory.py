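import math

import numpy as np
import pytest

from gxesign import (
    GxEDataset,
    NoiseSpec,
    classify_variants,
    dominance_check,
    fit_gxe,
    induced_coeffs,
    make_transform,
    predict_sign,
)

from conftest import make_cells

LOGISTIC_CELLS_A = make_cells(5.0, 8.0, 5.5, 8.5)
LOGISTIC_CELLS_B = make_cells(5.7, 8.7, 6.7, 9.7)


@pytest.mark.parametrize(
    "curv,sa,sb,expected",
    [
        (1, 1, 1, 1),
        (1, 1, -1, -1),
        (1, -1, 1, -1),
        (1, -1, -1, 1),
        (-1, 1, 1, -1),
        (-1, 1, -1, 1),
        (-1, -1, 1, 1),
        (-1, -1, -1, -1),
        (0, 1, 1, 0),
        (0, -1, 1, 0),
        (1, 0, 1, 0),
        (-1, 1, 0, 0),
    ],
)
def test_product_sign_rule(curv, sa, sb, expected):
    pred = predict_sign(curv, sa, sb)
    assert pred.predicted_sign == expected
    assert pred.method == "rule"


def test_product_rule_rejects_mixed_curvature():
    with pytest.raises(ValueError, match="mixed"):
        predict_sign("mixed", 1, 1)


def test_logistic_worked_example_noiseless():
    spec = make_transform("logistic", x0=7.0)
    a = induced_coeffs(LOGISTIC_CELLS_A, spec)
    assert a.beta_phi == pytest.approx(0.0632226, abs=1e-6)
    assert a.gamma_phi == pytest.approx(0.0232933, abs=1e-6)
    b = induced_coeffs(LOGISTIC_CELLS_B, spec)
    assert b.beta_phi == pytest.approx(0.2113925, abs=1e-6)
    assert b.gamma_phi == pytest.approx(-0.1199006, abs=1e-6)
    # same main-effect direction, opposite induced interaction directions
    assert a.beta_phi > 0 and b.beta_phi > 0
    assert a.gamma_phi > 0 > b.gamma_phi


def test_exp_with_normal_noise_matches_lognormal_closed_form():
    # E[exp(P + eps)] = exp(P + sd^2/2) for eps ~ N(0, sd^2)
    cm = make_cells(0.0, 1.0, 1.0, 2.0)
    ic = induced_coeffs(cm, make_transform("exp"), NoiseSpec("normal", 1.0),
                        quadrature_order=80)
    expected = math.exp(0.5) * (math.exp(2) - 2 * math.e + 1)
    assert ic.gamma_phi == pytest.approx(expected, abs=1e-8)
    assert ic.beta_phi == pytest.approx(math.exp(0.5) * (math.e - 1), abs=1e-8)


def test_quadrature_converges_when_doubling_order():
    cm = make_cells(4.0, 6.0, 5.0, 7.0)
    noise = NoiseSpec("normal", 2.0)
    # smooth fast-decaying maps converge by order ~60; the saturating tanh
    # needs higher order at this noise level
    for spec, lo, hi in ((make_transform("exp"), 60, 120),
                         (make_transform("logistic", x0=5.0), 60, 120),
                         (make_transform("tanh"), 150, 300)):
        a = induced_coeffs(cm, spec, noise, quadrature_order=lo)
        b = induced_coeffs(cm, spec, noise, quadrature_order=hi)
        assert b.gamma_phi == pytest.approx(a.gamma_phi, abs=1e-8)
    with pytest.raises(ValueError, match="quadrature_order"):
        induced_coeffs(cm, make_transform("exp"), noise, quadrature_order=400)


def test_oracle_domain_check_covers_noise_support():
    cm = make_cells(1.0, 2.0, 1.5, 2.5)
    with pytest.raises(ValueError, match="domain"):
        induced_coeffs(cm, make_transform("log"), NoiseSpec("normal", 1.0))


def test_classify_variants_logistic_pair_and_identity():
    spec = make_transform("logistic", x0=7.0)
    preds = classify_variants([LOGISTIC_CELLS_A, LOGISTIC_CELLS_B], spec)
    assert [p.predicted_sign for p in preds] == [1, -1]
    assert all(p.method == "numeric_oracle" for p in preds)

    ident = classify_variants([LOGISTIC_CELLS_A], make_transform("identity"))
    assert ident[0].predicted_sign == "indeterminate"

    # globally convex map: the same two variants get the same induced sign
    exp_preds = classify_variants([LOGISTIC_CELLS_A, LOGISTIC_CELLS_B],
                                  make_transform("exp"))
    assert exp_preds[0].predicted_sign == exp_preds[1].predicted_sign == 1


def _null_cells(rng, sign_alpha, sign_beta, base=10.0):
    """Random cell means with gamma=0 on the original scale and given signs."""
    alpha = sign_alpha * rng.uniform(0.2, 2.0)
    beta = sign_beta * rng.uniform(0.2, 2.0)
    mu = base + rng.uniform(-1.0, 1.0)
    return make_cells(mu, mu + alpha, mu + beta, mu + alpha + beta)


@pytest.mark.parametrize("name,curv", [("exp", 1), ("log", -1), ("sqrt", -1),
                                       ("square", 1), ("neg_exp", 1), ("neg_square", -1)])
def test_oracle_sign_equals_rule_on_null_cell_means(name, curv, rng):
    # Exhaustive over sign combinations x random null configurations; the
    # rule uses the signs of the *induced* alpha_phi/beta_phi.
    spec = make_transform(name)
    noise = NoiseSpec("normal", 0.5)
    for sa in (-1, 1):
        for sb in (-1, 1):
            for _ in range(30):
                cm = _null_cells(rng, sa, sb)
                ic = induced_coeffs(cm, spec, noise)
                rule = predict_sign(
                    spec.curvature_sign,
                    int(np.sign(ic.alpha_phi)),
                    int(np.sign(ic.beta_phi)),
                )
                assert np.sign(ic.gamma_phi) == rule.predicted_sign


def test_large_sample_fit_matches_numeric_oracle(rng):
    # simulate a null additive panel, transform, fit; compare gamma with the
    # oracle's prediction within Monte Carlo error
    n = 100_000
    mu, alpha, beta, sd = 10.0, 1.0, 0.8, 0.5
    E = (rng.random(n) < 0.5).astype(float)
    G = (rng.random(n) < 0.4).astype(np.int8)
    y = mu + alpha * E + beta * G + rng.normal(0, sd, n)
    spec = make_transform("log")
    ds = GxEDataset(G[:, None], E, np.log(y), ploidy=1)
    fit = fit_gxe(ds, 0)
    cm = make_cells(mu, mu + alpha, mu + beta, mu + alpha + beta)
    ic = induced_coeffs(cm, spec, NoiseSpec("normal", sd))
    assert abs(fit.gamma - ic.gamma_phi) < 3 * fit.se_gamma
    assert np.sign(fit.gamma) == -np.sign(fit.beta)  # log: convex up, alpha>0


def test_diploid_hwe_panel_obeys_sign_rule(rng):
    # HWE diploid genotypes, additive null truth, exp transform (convex
    # down, alpha > 0): fitted interaction signs align with the main
    # genetic effects for strongly estimated main effects
    n, m = 100_000, 30
    mafs = rng.uniform(0.1, 0.5, m)
    X = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    E = (rng.random(n) < 0.5).astype(float)
    betas = rng.uniform(0.15, 0.4, m) * rng.choice([-1.0, 1.0], m)
    y = 0.2 + 1.0 * E + X @ betas + rng.normal(0, 0.5, n)
    ds = GxEDataset(X, E, np.exp(y), ploidy=2)
    violations = checked = 0
    for j in range(m):
        fit = fit_gxe(ds, j)
        if abs(fit.beta) / fit.se_beta > 4:
            checked += 1
            if np.sign(fit.gamma) != np.sign(fit.beta):
                violations += 1
    assert checked >= 10
    assert violations / checked <= 0.01


def test_dominance_check_independent_ge_has_null_correlation_term():
    spec = make_transform("exp")
    report = dominance_check(alpha=0.2, beta=0.2, spec=spec,
                             noise=NoiseSpec("normal", 0.5), rho=0.0,
                             n=20_000, reps=30, seed=11)
    assert abs(report["correlation_term"]) < 4 * report["mc_se_gamma_phi"] + 1e-3
    assert report["sign_rule_agreement"] >= 0.95


def test_dominance_check_small_correlation_strong_curvature():
    spec = make_transform("exp")
    report = dominance_check(alpha=1.0, beta=1.0, spec=spec,
                             noise=NoiseSpec("normal", 0.5), rho=0.05,
                             n=20_000, reps=20, seed=12)
    assert report["sign_rule_agreement"] > 0.9


def test_dominance_check_null_alpha_has_null_transformation_term():
    report = dominance_check(alpha=0.0, beta=1.0, spec=make_transform("exp"),
                             noise=NoiseSpec("normal", 0.5), rho=0.0,
                             n=5_000, reps=5, seed=13)
    assert report["transformation_term"] == 0.0


def test_dominance_check_rejects_infeasible_correlation():
    with pytest.raises(ValueError, match="infeasible"):
        dominance_check(alpha=1.0, beta=1.0, spec=make_transform("exp"),
                       noise=NoiseSpec("normal", 0.5), rho=0.9,
                       n=100, reps=1, seed=0, maf=0.05, exposure_prev=0.95)
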