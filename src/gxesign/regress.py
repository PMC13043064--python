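"""Single-variant G×E regression and its cell-mean representation.

The model fitted per variant is the standard interaction regression

    Y = mu + alpha*E + beta*G + gamma*G*E (+ covariates) + eps,

estimated by ordinary least squares (statsmodels), with optional
heteroskedasticity-consistent (HC1) standard errors and t-reference
p-values.  For a binary exposure and haploid genotype with all four
(E, G) cells populated the model is saturated, so the coefficients are
exactly the cell-mean contrasts

    mu = P00,  alpha = P10 - P00,  beta = P01 - P00,
    gamma = (P11 - P10) - (P01 - P00),

where ``P[a, b]`` is the empirical mean of Y in the (E=a, G=b) cell.
That identity is the geometric object the sign theory acts on, and
:func:`coeffs_from_cell_means` exposes it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GxEDataset",
    "CellMeans",
    "GxEFit",
    "FitTable",
    "fit_gxe",
    "fit_all",
    "cell_means",
    "coeffs_from_cell_means",
]

FIT_COLUMNS = [
    "id", "mu", "alpha", "p_alpha", "beta_main", "se_main", "p_main",
    "gamma_int", "se_int", "p_int", "sigma2", "robust",
]


@dataclass
class GxEDataset:
    """Genotype / exposure / phenotype panel for interaction testing.

    ``genotypes`` is samples × variants with entries in {0, 1} (haploid)
    or {0, 1, 2} (diploid dosage).  ``truth`` optionally records the
    generating parameters of a simulated panel (effect sizes, seeds),
    used only for bookkeeping and oracle checks, never by the fitters.
    """

    genotypes: np.ndarray
    exposure: np.ndarray
    phenotype: np.ndarray
    ploidy: int = 2
    covariates: np.ndarray | None = None
    variant_ids: list[str] | None = None
    sample_ids: list[str] | None = None
    truth: dict | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a samples x variants matrix")
        n, m = self.genotypes.shape
        if self.exposure.shape != (n,) or self.phenotype.shape != (n,):
            raise ValueError("exposure/phenotype length must match sample count")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        g = self.genotypes
        if not np.isfinite(self.exposure).all() or not np.isfinite(self.phenotype).all():
            raise ValueError("missing or non-finite exposure/phenotype entries")
        if g.size:
            if np.isnan(g.astype(float)).any():
                raise ValueError("missing genotype entries are not supported")
            if g.min() < 0 or g.max() > self.ploidy:
                raise ValueError(f"genotype entries outside 0..{self.ploidy}")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows must match sample count")
        if self.variant_ids is None:
            self.variant_ids = [f"snp{j}" for j in range(m)]
        if len(self.variant_ids) != m:
            raise ValueError("variant_ids length must match variant count")
        if len(set(self.variant_ids)) != m:
            raise ValueError("variant_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def exposure_is_binary(self) -> bool:
        return bool(np.isin(self.exposure, (0.0, 1.0)).all())

    def with_phenotype(self, phenotype: np.ndarray) -> "GxEDataset":
        """Copy of the panel with the outcome replaced (e.g. transformed)."""
        return GxEDataset(
            self.genotypes, self.exposure, phenotype, self.ploidy,
            self.covariates, list(self.variant_ids),
            None if self.sample_ids is None else list(self.sample_ids),
            self.truth,
        )


@dataclass(frozen=True)
class CellMeans:
    """Empirical conditional means P[a, b] = mean(Y | E=a, G=b) with counts."""

    P: dict
    counts: dict

    def __getitem__(self, key):
        return self.P[key]


@dataclass(frozen=True)
class GxEFit:
    variant_id: str
    mu: float
    alpha: float
    beta: float
    gamma: float
    se_mu: float
    se_alpha: float
    se_beta: float
    se_gamma: float
    p_alpha: float
    p_beta: float
    p_gamma: float
    sigma2: float
    robust: bool
    nobs: int


@dataclass
class FitTable:
    """Per-variant fit results as a tidy DataFrame (one row per variant)."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = {"id", "beta_main", "p_main", "gamma_int", "p_int"} - set(self.table.columns)
        if missing:
            raise ValueError(f"fit table missing required columns: {sorted(missing)}")
        if self.table["id"].duplicated().any():
            dups = self.table["id"][self.table["id"].duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dups}")

    def __len__(self):
        return len(self.table)

    @classmethod
    def from_fits(cls, fits: list[GxEFit]) -> "FitTable":
        rows = [
            (f.variant_id, f.mu, f.alpha, f.p_alpha, f.beta, f.se_beta, f.p_beta,
             f.gamma, f.se_gamma, f.p_gamma, f.sigma2, f.robust)
            for f in fits
        ]
        return cls(pd.DataFrame(rows, columns=FIT_COLUMNS))


class RankDeficientDesign(ValueError):
    """Design matrix for the interaction regression is rank deficient."""


def _design(data: GxEDataset, j: int, covariate_interactions: bool):
    G = data.genotypes[:, j].astype(float)
    E = data.exposure
    cols = [np.ones(data.n_samples), E, G, G * E]
    names = ["const", "E", "G", "GxE"]
    if data.covariates is not None:
        C = data.covariates.copy()
        # standardize non-binary covariates so covariate x E terms are scale-free
        for k in range(C.shape[1]):
            col = C[:, k]
            if not np.isin(col, (0.0, 1.0)).all():
                sd = col.std()
                C[:, k] = (col - col.mean()) / (sd if sd > 0 else 1.0)
            cols.append(C[:, k])
            names.append(f"C{k}")
        if covariate_interactions:
            for k in range(C.shape[1]):
                cols.append(C[:, k] * E)
                names.append(f"C{k}xE")
    X = np.column_stack(cols)
    return X, names


def _check_rank(X: np.ndarray, names: list[str], variant_id: str):
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # name the offending column for the common degeneracies
    for k, nm in enumerate(names[1:], start=1):
        if np.ptp(X[:, k]) == 0:
            label = {"G": "monomorphic variant", "E": "constant exposure"}.get(
                nm, f"constant column {nm}"
            )
            raise RankDeficientDesign(
                f"variant {variant_id!r}: design rank deficient ({label}: column {nm!r})"
            )
    raise RankDeficientDesign(
        f"variant {variant_id!r}: design rank deficient (collinear columns among {names})"
    )


def fit_gxe(
    data: GxEDataset,
    variant_index: int,
    robust: bool = False,
    covariate_interactions: bool = False,
) -> GxEFit:
    """OLS fit of Y ~ 1 + E + G + G*E (+ covariates) for one variant.

    ``robust`` switches to HC1 heteroskedasticity-consistent standard
    errors; p-values always use the t reference with residual degrees of
    freedom (sample sizes in tests can be small).
    """
    X, names = _design(data, variant_index, covariate_interactions)
    vid = data.variant_ids[variant_index]
    _check_rank(X, names, vid)
    res = sm.OLS(data.phenotype, X).fit(
        cov_type="HC1" if robust else "nonrobust", use_t=True
    )
    b, se, p = res.params, res.bse, res.pvalues
    return GxEFit(
        variant_id=vid,
        mu=float(b[0]), alpha=float(b[1]), beta=float(b[2]), gamma=float(b[3]),
        se_mu=float(se[0]), se_alpha=float(se[1]), se_beta=float(se[2]),
        se_gamma=float(se[3]),
        p_alpha=float(p[1]), p_beta=float(p[2]), p_gamma=float(p[3]),
        sigma2=float(res.mse_resid), robust=robust, nobs=int(res.nobs),
    )


def fit_all(
    data: GxEDataset, robust: bool = False, covariate_interactions: bool = False
) -> FitTable:
    """Fit every variant in deterministic (column) order.

    Per-variant failures are aggregated and raised together with their
    indices; an empty variant set yields an empty table.
    """
    fits, failures = [], []
    for j in range(data.n_variants):
        try:
            fits.append(fit_gxe(data, j, robust, covariate_interactions))
        except RankDeficientDesign as exc:
            failures.append((j, str(exc)))
    if failures:
        msgs = "; ".join(f"[{j}] {m}" for j, m in failures)
        raise RankDeficientDesign(f"{len(failures)} variant(s) failed: {msgs}")
    if not fits:
        return FitTable(pd.DataFrame(columns=FIT_COLUMNS))
    return FitTable.from_fits(fits)


def cell_means(data: GxEDataset, variant_index: int) -> CellMeans:
    """Empirical conditional means of Y per (E, G) cell for one variant.

    Requires a binary exposure and every cell populated (the cell-mean
    representation is undefined otherwise).
    """
    if not data.exposure_is_binary():
        raise ValueError("cell means require a binary (0/1) exposure")
    G = data.genotypes[:, variant_index]
    E = data.exposure.astype(int)
    P, counts, empty = {}, {}, []
    for a in (0, 1):
        for b in range(data.ploidy + 1):
            mask = (E == a) & (G == b)
            c = int(mask.sum())
            if c == 0:
                empty.append((a, b))
            else:
                P[(a, b)] = float(data.phenotype[mask].mean())
                counts[(a, b)] = c
    if empty:
        raise ValueError(f"empty (E, G) cells for variant {variant_index}: {empty}")
    return CellMeans(P=P, counts=counts)


def coeffs_from_cell_means(cm: CellMeans) -> tuple[float, float, float, float]:
    """Saturated-model coefficients from the four haploid cell means.

    Returns (mu, alpha, beta, gamma) via the exact identities; agrees with
    :func:`fit_gxe` to numerical precision for any cell imbalance because
    the saturated OLS fit interpolates cell means.
    """
    try:
        p00, p10, p01, p11 = cm.P[(0, 0)], cm.P[(1, 0)], cm.P[(0, 1)], cm.P[(1, 1)]
    except KeyError as exc:
        raise ValueError(f"missing cell {exc.args[0]} (haploid G, binary E required)") from None
    if set(cm.P) - {(0, 0), (1, 0), (0, 1), (1, 1)}:
        raise ValueError("cell-mean identities require haploid genotypes")
    return (p00, p10 - p00, p01 - p00, (p11 - p10) - (p01 - p00))
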