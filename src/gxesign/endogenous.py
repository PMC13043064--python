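"""Threshold-based endogenous treatment: analytic expectations and simulator.

Model: a polygenic phenotype Y = sum_i beta_i G_i + eps (haploid Bernoulli
variants, Gaussian noise) triggers a treatment E = 1{Y > t} that shifts the
observed outcome by a fixed amount: Y~ = Y + alpha*E.  Because exposure is
assigned by the phenotype itself, the (E, G) cell means of Y~ are truncated
normal means, expressible through the inverse Mills ratio
lambda(x) = phi(x)/Phi(x).  Writing P0 = t - E[Y | G_j = 0] and
P1 = t - E[Y | G_j = 1] (in noise-sd units), the expected single-variant
interaction regression coefficients are

    E[beta_j]  = lambda(P0) - lambda(P1) + P0 - P1,
    E[gamma_j] = lambda(-P1) - lambda(-P0) - (lambda(P0) - lambda(P1)),

and because lambda is strictly decreasing and convex these always have
*opposite* signs when both variant-conditional means sit below the
threshold: an endogenous treatment can only produce interactions opposed
to the main genetic effects.  Note the treatment effect alpha cancels from
both expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .regress import FitTable, GxEDataset

__all__ = [
    "EndogenousModel",
    "EndogenousExpectation",
    "mills_lambda",
    "expected_effects",
    "simulate_endogenous",
    "opposite_sign_check",
]


def mills_lambda(x):
    """Inverse Mills ratio lambda(x) = phi(x)/Phi(x) of the standard normal.

    Computed in log space (logpdf - logcdf) so it is stable far into the
    left tail, where the naive ratio overflows/underflows; lambda(x) ~ -x
    as x -> -inf.
    """
    x = np.asarray(x, dtype=float)
    out = np.exp(stats.norm.logpdf(x) - stats.norm.logcdf(x))
    return out if out.ndim else float(out)


@dataclass
class EndogenousModel:
    """Parameters of the threshold-treatment generating process.

    ``direction="above"`` treats when Y exceeds ``threshold`` (the model of
    the derivation); ``"below"`` treats when Y falls under it, implemented
    by the reflection Y -> -Y, t -> -t.  ``treatment_effect`` may have
    either sign (a treatment typically tapers the phenotype, alpha < 0); it
    does not enter the expected interaction coefficients.
    """

    betas: np.ndarray
    mafs: np.ndarray
    threshold: float
    treatment_effect: float
    noise_sd: float = 1.0
    direction: str = "above"

    def __post_init__(self):
        self.betas = np.atleast_1d(np.asarray(self.betas, dtype=float))
        self.mafs = np.atleast_1d(np.asarray(self.mafs, dtype=float))
        if self.betas.shape != self.mafs.shape:
            raise ValueError("betas and mafs must have equal length")
        if not np.all((self.mafs > 0) & (self.mafs < 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")

    @property
    def n_variants(self) -> int:
        return self.betas.size


@dataclass(frozen=True)
class EndogenousExpectation:
    P0: float
    P1: float
    lambda_P0: float
    lambda_P1: float
    lambda_mP0: float
    lambda_mP1: float
    expected_beta: float
    expected_gamma: float
    conditional_sd: float
    opposite_signs: bool


def _reflected(model: EndogenousModel) -> EndogenousModel:
    return EndogenousModel(
        betas=-model.betas, mafs=model.mafs, threshold=-model.threshold,
        treatment_effect=-model.treatment_effect, noise_sd=model.noise_sd,
        direction="above",
    )


def expected_effects(model: EndogenousModel, variant_index: int) -> EndogenousExpectation:
    """Expected interaction-regression coefficients for one variant.

    The polygenic background of the other variants is absorbed into the
    noise as a Gaussian, so the variant-conditional scale is
    ``s_j^2 = noise_sd^2 + sum_{i != j} beta_i^2 p_i (1 - p_i)``; with no
    background and unit noise this reduces to the plain unit-variance
    expressions.  Requires both variant-conditional means below the
    threshold (direction="above"); a single common variant large enough to
    push its carriers' mean past t violates the derivation's premise.
    """
    if model.direction == "below":
        e = expected_effects(_reflected(model), variant_index)
        return EndogenousExpectation(
            P0=e.P0, P1=e.P1, lambda_P0=e.lambda_P0, lambda_P1=e.lambda_P1,
            lambda_mP0=e.lambda_mP0, lambda_mP1=e.lambda_mP1,
            expected_beta=-e.expected_beta, expected_gamma=-e.expected_gamma,
            conditional_sd=e.conditional_sd, opposite_signs=e.opposite_signs,
        )
    j = variant_index
    betas, p = model.betas, model.mafs
    others = np.ones(model.n_variants, dtype=bool)
    others[j] = False
    mu_background = float(np.sum(betas[others] * p[others]))
    mu_j0 = mu_background
    mu_j1 = mu_background + float(betas[j])
    t = model.threshold
    if max(mu_j0, mu_j1) >= t:
        raise ValueError(
            f"variant {j}: conditional mean(s) ({mu_j0:g}, {mu_j1:g}) are not "
            f"below threshold t={t:g}; the derivation assumes both means "
            "smaller than t"
        )
    var_background = float(np.sum(betas[others] ** 2 * p[others] * (1 - p[others])))
    s = float(np.sqrt(model.noise_sd**2 + var_background))
    P0 = (t - mu_j0) / s
    P1 = (t - mu_j1) / s
    lp0, lp1 = mills_lambda(P0), mills_lambda(P1)
    lm0, lm1 = mills_lambda(-P0), mills_lambda(-P1)
    beta_hat = s * (lp0 - lp1 + P0 - P1)
    gamma_hat = s * (lm1 - lm0 - (lp0 - lp1))
    return EndogenousExpectation(
        P0=P0, P1=P1, lambda_P0=lp0, lambda_P1=lp1, lambda_mP0=lm0, lambda_mP1=lm1,
        expected_beta=beta_hat, expected_gamma=gamma_hat, conditional_sd=s,
        opposite_signs=bool(beta_hat * gamma_hat < 0 or beta_hat == gamma_hat == 0),
    )


def simulate_endogenous(model: EndogenousModel, n: int, seed: int) -> GxEDataset:
    """Simulate the threshold-treatment process.

    Haploid genotypes, Gaussian noise, deterministic treatment assignment
    from the latent phenotype; the observed outcome is the treated one.
    The latent phenotype and all model parameters are recorded in the
    truth block.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    G = (rng.random((n, model.n_variants)) < model.mafs).astype(np.int8)
    latent = G @ model.betas + rng.normal(0.0, model.noise_sd, n)
    if model.direction == "above":
        E = (latent > model.threshold).astype(float)
    else:
        E = (latent < model.threshold).astype(float)
    observed = latent + model.treatment_effect * E
    return GxEDataset(
        genotypes=G, exposure=E, phenotype=observed, ploidy=1,
        truth={
            "latent_phenotype": latent,
            "betas": model.betas.copy(), "mafs": model.mafs.copy(),
            "threshold": model.threshold, "treatment_effect": model.treatment_effect,
            "noise_sd": model.noise_sd, "direction": model.direction, "seed": seed,
        },
    )


def opposite_sign_check(fits: FitTable, p_threshold: float = 0.05) -> dict:
    """Fraction of significant interactions opposed in sign to their main effects.

    Among variants with interaction p-value below ``p_threshold``, counts
    those with sgn(gamma) = -sgn(beta).  An empty selection yields NaN
    fraction with zero counts rather than an error.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must lie in (0, 1]")
    t = fits.table
    sel = t[t["p_int"] < p_threshold]
    sel = sel[(sel["beta_main"] != 0) & (sel["gamma_int"] != 0)]
    n_sel = len(sel)
    n_opposed = int((np.sign(sel["gamma_int"]) == -np.sign(sel["beta_main"])).sum())
    return {
        "n_tested": len(t),
        "n_significant": n_sel,
        "n_opposed": n_opposed,
        "n_aligned": n_sel - n_opposed,
        "fraction_opposed": (n_opposed / n_sel) if n_sel else float("nan"),
        "p_threshold": p_threshold,
    }
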