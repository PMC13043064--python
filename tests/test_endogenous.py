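import numpy as np
import pandas as pd
import pytest

from gxesign import (
    EndogenousModel,
    FitTable,
    expected_effects,
    fit_all,
    mills_lambda,
    opposite_sign_check,
    simulate_endogenous,
)
from gxesign.regress import FIT_COLUMNS


def test_mills_lambda_reference_values():
    assert mills_lambda(0.0) == pytest.approx(np.sqrt(2 / np.pi), abs=1e-7)
    assert mills_lambda(1.0) < mills_lambda(0.0)
    # deep left tail: lambda(x) ~ -x + 1/(-x); stable, no overflow
    assert mills_lambda(-30.0) == pytest.approx(30.0332597, abs=1e-3)
    assert np.isfinite(mills_lambda(-40.0))


def test_mills_lambda_is_decreasing_and_strictly_convex():
    x = np.linspace(-40, 10, 2001)
    lam = mills_lambda(x)
    assert np.all(np.diff(lam) < 0)
    second = lam[:-2] - 2 * lam[1:-1] + lam[2:]
    assert np.all(second > 0)


def test_expected_effects_worked_example():
    # single variant, unit noise: P0 = 2, P1 = 1.5
    model = EndogenousModel(betas=[0.5], mafs=[0.3], threshold=2.0,
                            treatment_effect=-1.0)
    e = expected_effects(model, 0)
    assert e.P0 == pytest.approx(2.0)
    assert e.P1 == pytest.approx(1.5)
    assert e.expected_beta == pytest.approx(0.4164581, abs=1e-6)
    assert e.expected_gamma == pytest.approx(-0.3509965, abs=1e-6)
    assert e.opposite_signs


def test_expected_effects_degenerate_and_antisymmetric_cases():
    null = EndogenousModel(betas=[0.0], mafs=[0.3], threshold=2.0, treatment_effect=1.0)
    e = expected_effects(null, 0)
    assert e.expected_beta == 0.0 and e.expected_gamma == 0.0

    pos = EndogenousModel(betas=[0.5], mafs=[0.5], threshold=2.0, treatment_effect=1.0)
    neg = EndogenousModel(betas=[-0.5], mafs=[0.5], threshold=1.5, treatment_effect=1.0)
    ep = expected_effects(pos, 0)
    # swapping mu_j0 <-> mu_j1 == negating beta with threshold shifted by beta
    en = expected_effects(neg, 0)
    assert np.sign(en.expected_beta) == -np.sign(ep.expected_beta)
    assert np.sign(en.expected_gamma) == -np.sign(ep.expected_gamma)


def test_expected_effects_requires_means_below_threshold():
    model = EndogenousModel(betas=[1.0], mafs=[0.5], threshold=0.5, treatment_effect=1.0)
    with pytest.raises(ValueError, match="below threshold"):
        expected_effects(model, 0)


def test_opposite_sign_relation_over_parameter_grid():
    # sgn(E[gamma]) = -sgn(E[beta]) whenever both conditional means < t
    rng = np.random.default_rng(1)
    checked = 0
    while checked < 1000:
        beta = rng.uniform(-1.5, 1.5)
        if beta == 0:
            continue
        t = rng.uniform(0.5, 4.0)
        if max(0.0, beta) >= t:
            continue
        model = EndogenousModel(betas=[beta], mafs=[rng.uniform(0.05, 0.95)],
                                threshold=t, treatment_effect=rng.normal())
        e = expected_effects(model, 0)
        assert e.expected_beta * e.expected_gamma < 0
        checked += 1


def test_below_threshold_direction_preserves_opposite_sign_relation():
    rng = np.random.default_rng(2)
    for _ in range(200):
        beta = rng.uniform(0.05, 1.0) * rng.choice([-1, 1])
        t = -rng.uniform(0.5, 3.0)
        if min(0.0, beta) <= t:
            continue
        model = EndogenousModel(betas=[beta], mafs=[0.4], threshold=t,
                                treatment_effect=1.0, direction="below")
        e = expected_effects(model, 0)
        assert e.expected_beta * e.expected_gamma < 0


def test_simulator_determinism_and_limit_cases():
    model = EndogenousModel(betas=[0.2, -0.1], mafs=[0.3, 0.4], threshold=1.5,
                            treatment_effect=-1.0)
    a = simulate_endogenous(model, 500, seed=9)
    b = simulate_endogenous(model, 500, seed=9)
    assert np.array_equal(a.genotypes, b.genotypes)
    assert np.array_equal(a.phenotype, b.phenotype)

    null_alpha = EndogenousModel(betas=[0.2], mafs=[0.3], threshold=1.0,
                                 treatment_effect=0.0)
    ds = simulate_endogenous(null_alpha, 500, seed=3)
    assert np.array_equal(ds.phenotype, ds.truth["latent_phenotype"])

    low_t = EndogenousModel(betas=[0.2], mafs=[0.3], threshold=-50.0,
                            treatment_effect=1.0)
    ds = simulate_endogenous(low_t, 500, seed=3)
    assert np.all(ds.exposure == 1.0)


def test_treatment_prevalence_matches_latent_gaussian_tail():
    from scipy import stats

    rng = np.random.default_rng(4)
    betas = rng.normal(0, 0.15, 30)
    mafs = rng.uniform(0.2, 0.5, 30)
    model = EndogenousModel(betas=betas, mafs=mafs, threshold=1.5,
                            treatment_effect=-1.0)
    ds = simulate_endogenous(model, 100_000, seed=5)
    mu = float(betas @ mafs)
    s = np.sqrt(1.0 + np.sum(betas**2 * mafs * (1 - mafs)))
    expected = 1 - stats.norm.cdf((1.5 - mu) / s)
    assert ds.exposure.mean() == pytest.approx(expected, abs=3 * np.sqrt(expected / 100_000) + 0.003)


def test_fitted_effects_match_analytic_expectations_at_scale():
    rng = np.random.default_rng(5)
    nv = 20
    mags = np.linspace(0.1, 0.3, nv)
    betas = mags * np.where(rng.random(nv) < 0.5, 1.0, -1.0)
    mafs = rng.uniform(0.2, 0.5, nv)
    model = EndogenousModel(betas=betas, mafs=mafs, threshold=1.5,
                            treatment_effect=-1.0)
    ds = simulate_endogenous(model, 200_000, seed=7)
    fits = fit_all(ds)
    for j in range(nv):
        e = expected_effects(model, j)
        row = fits.table.iloc[j]
        assert abs(row["beta_main"] - e.expected_beta) < 3 * row["se_main"]
        assert abs(row["gamma_int"] - e.expected_gamma) < 3 * row["se_int"]
    report = opposite_sign_check(fits, 0.05)
    assert report["n_significant"] > 0
    assert report["fraction_opposed"] == 1.0


def test_opposite_sign_check_counting_and_empty_selection():
    def table(rows):
        df = pd.DataFrame(rows, columns=["id", "beta_main", "gamma_int", "p_int"])
        df["mu"] = 0.0; df["alpha"] = 0.0; df["p_alpha"] = 1.0
        df["se_main"] = 1.0; df["p_main"] = 0.5; df["se_int"] = 1.0
        df["sigma2"] = 1.0; df["robust"] = False
        return FitTable(df[FIT_COLUMNS])

    rows = [(f"v{i}", 1.0, 1.0, 0.01) for i in range(3)] \
         + [(f"w{i}", 1.0, -1.0, 0.01) for i in range(7)]
    report = opposite_sign_check(table(rows), 0.05)
    assert report["n_significant"] == 10
    assert report["fraction_opposed"] == 0.7

    null_rows = [(f"n{i}", 1.0, 1.0, 0.9) for i in range(5)]
    empty = opposite_sign_check(table(null_rows), 0.05)
    assert empty["n_significant"] == 0
    assert np.isnan(empty["fraction_opposed"])


def test_model_validation():
    with pytest.raises(ValueError, match="allele frequencies"):
        EndogenousModel(betas=[0.1], mafs=[0.0], threshold=1.0, treatment_effect=1.0)
    with pytest.raises(ValueError, match="equal length"):
        EndogenousModel(betas=[0.1, 0.2], mafs=[0.3], threshold=1.0, treatment_effect=1.0)
    with pytest.raises(ValueError, match="direction"):
        EndogenousModel(betas=[0.1], mafs=[0.3], threshold=1.0,
                        treatment_effect=1.0, direction="sideways")
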