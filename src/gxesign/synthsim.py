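"""Synthetic genotype/exposure/phenotype generators for the simulation study.

Two generators mirror the study designs used throughout the package:

* :func:`simulate_single_snp` — a minimal one-variant panel with a purely
  additive outcome ``Y ~ N(10 + 4G + E, 1)`` (haploid variant, continuous
  standard-normal exposure).  On the raw scale the interaction test is
  null; after a log transform it is powered, the canonical demonstration
  of a scaling-induced G×E.

* :func:`simulate_panel` — the full multi-SNP design: n samples balanced
  over a binary exposure, independent diploid Hardy–Weinberg SNPs with
  MAF ~ U(0.05, 0.5), additive effects beta ~ N(0, 1), a subset of SNPs
  carrying true interaction effects whose magnitudes are N(0, sigma2_gxe)
  draws and whose signs are forced half aligned / half opposed relative
  to the main effects, and residual noise scaled per replicate so that
  the realized additive heritability among unexposed samples equals
  ``target_h2``.

:func:`simulate_correlated_ge` adds a designated SNP whose dosage shifts
the exposure probability to achieve a requested G-E correlation, and
:func:`replicate_experiment` runs the detection / sign-consistency
summary over replicates and a grid of interaction variances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .diagnose import sign_consistency_rate
from .regress import FitTable, GxEDataset, fit_all
from .transforms import ShiftPolicy, TransformSpec, apply_transform, inverse_normal_transform

__all__ = [
    "PanelConfig",
    "simulate_single_snp",
    "simulate_panel",
    "simulate_correlated_ge",
    "replicate_experiment",
    "child_seed",
]


@dataclass(frozen=True)
class PanelConfig:
    """Study-design parameters of the multi-SNP panel generator."""

    n_samples: int = 10_000
    n_snps: int = 200
    n_interacting: int = 100
    sigma2_gxe: float = 0.5
    target_h2: float = 0.5
    exposure_effect: float = 2.0
    maf_low: float = 0.05
    maf_high: float = 0.5
    ploidy: int = 2
    aligned_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_interacting > self.n_snps:
            raise ValueError("n_interacting cannot exceed n_snps")
        if not 0 < self.target_h2 < 1:
            raise ValueError("target_h2 must lie in (0, 1)")
        if not 0 < self.maf_low <= self.maf_high < 1:
            raise ValueError("need 0 < maf_low <= maf_high < 1")
        if self.sigma2_gxe < 0:
            raise ValueError("sigma2_gxe must be >= 0")
        if not 0 <= self.aligned_fraction <= 1:
            raise ValueError("aligned_fraction must lie in [0, 1]")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def simulate_single_snp(
    n: int = 1000,
    maf: float = 0.4,
    seed: int = 0,
    intercept: float = 10.0,
    beta: float = 4.0,
    exposure_effect: float = 1.0,
    noise_sd: float = 1.0,
) -> GxEDataset:
    """One haploid variant, continuous exposure, additive Gaussian outcome.

    Defaults generate ``Y ~ N(10 + 4G + E, 1)`` for 1,000 samples with
    MAF 0.4 and E standard normal.
    """
    if not 0 <= maf <= 1:
        raise ValueError("maf must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    G = (rng.random(n) < maf).astype(np.int8)
    E = rng.normal(0.0, 1.0, n)
    Y = rng.normal(intercept + beta * G + exposure_effect * E, noise_sd)
    return GxEDataset(
        genotypes=G[:, None], exposure=E, phenotype=Y, ploidy=1,
        truth={"intercept": intercept, "beta": beta, "exposure_effect": exposure_effect,
               "noise_sd": noise_sd, "maf": maf, "seed": seed},
    )


def _draw_genotypes(rng, n, mafs, ploidy):
    return rng.binomial(ploidy, mafs, size=(n, mafs.size)).astype(np.int8)


def _interaction_effects(rng, betas, config: PanelConfig):
    """Interaction effect vector with the aligned/opposed sign bookkeeping."""
    m = config.n_snps
    gammas = np.zeros(m)
    interacting = np.sort(rng.choice(m, size=config.n_interacting, replace=False))
    perm = rng.permutation(config.n_interacting)
    n_aligned = int(round(config.aligned_fraction * config.n_interacting))
    aligned_idx = np.sort(interacting[perm[:n_aligned]])
    opposed_idx = np.sort(interacting[perm[n_aligned:]])
    magnitudes = np.abs(rng.normal(0.0, np.sqrt(config.sigma2_gxe), config.n_interacting))
    mag = dict(zip(interacting[perm], magnitudes))
    base_sign = np.where(np.sign(betas) != 0, np.sign(betas), 1.0)
    for j in aligned_idx:
        gammas[j] = base_sign[j] * mag[j]
    for j in opposed_idx:
        gammas[j] = -base_sign[j] * mag[j]
    return gammas, interacting, aligned_idx, opposed_idx


def _assemble_panel(rng, config: PanelConfig, X, E, extra_truth=None):
    betas = rng.normal(0.0, 1.0, config.n_snps)
    gammas, interacting, aligned_idx, opposed_idx = _interaction_effects(rng, betas, config)
    # Express the phenotype in units of the unexposed-stratum sd: rescale the
    # additive and interaction effects jointly so the realized Var(X beta)
    # among E=0 equals target_h2, and set the noise variance to 1 - target_h2.
    # The exposure main effect is then measured in unexposed-sd units.
    scale = np.sqrt(config.target_h2 / np.var((X @ betas)[E == 0]))
    betas = betas * scale
    gammas = gammas * scale
    g_add = X @ betas
    g_int = (X * E[:, None]) @ gammas
    sigma_eps = float(np.sqrt(1.0 - config.target_h2))
    Y = config.exposure_effect * E + g_add + g_int + rng.normal(0.0, sigma_eps, config.n_samples)
    truth = {
        "betas": betas, "gammas": gammas, "interacting_idx": interacting,
        "aligned_idx": aligned_idx, "opposed_idx": opposed_idx,
        "sigma_eps": float(sigma_eps), "additive_values": g_add,
        "interaction_values": g_int, "config": config,
    }
    if extra_truth:
        truth.update(extra_truth)
    return GxEDataset(genotypes=X, exposure=E, phenotype=Y, ploidy=config.ploidy, truth=truth)


def simulate_panel(config: PanelConfig) -> GxEDataset:
    """Multi-SNP panel with randomly directed interaction effects.

    The outcome is ``Y ~ N(c*E + X beta + (X*E) gamma, sigma_eps^2)`` with
    a binary exposure balanced by design and ``sigma_eps`` chosen per
    replicate so that the realized Var(X beta) / Var(Y) among the E = 0
    subsample equals ``target_h2``.
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(config.maf_low, config.maf_high, config.n_snps)
    X = _draw_genotypes(rng, config.n_samples, mafs, config.ploidy)
    E = np.zeros(config.n_samples)
    E[config.n_samples // 2:] = 1.0
    return _assemble_panel(rng, config, X, E, {"mafs": mafs, "seed": config.seed})


def simulate_correlated_ge(config: PanelConfig, rho: float, seed: int | None = None) -> GxEDataset:
    """Panel whose first SNP is correlated with the (binary) exposure.

    The exposure probability is linear in the designated SNP's dosage,
    calibrated so corr(G_0, E) = rho; infeasible combinations of rho, MAF
    and exposure prevalence (probabilities leaving [0, 1]) raise.  The
    phenotype is additive-only (interaction effects disabled).
    """
    cfg = replace(config, sigma2_gxe=0.0, seed=config.seed if seed is None else seed)
    rng = np.random.default_rng(cfg.seed)
    mafs = rng.uniform(cfg.maf_low, cfg.maf_high, cfg.n_snps)
    X = _draw_genotypes(rng, cfg.n_samples, mafs, cfg.ploidy)
    p_e = 0.5
    g0 = X[:, 0].astype(float)
    p0 = mafs[0]
    var_g = cfg.ploidy * p0 * (1 - p0)
    slope = rho * np.sqrt(p_e * (1 - p_e) / var_g)
    probs_by_dosage = p_e + slope * (np.arange(cfg.ploidy + 1) - cfg.ploidy * p0)
    if np.any(probs_by_dosage < 0) or np.any(probs_by_dosage > 1):
        raise ValueError(
            f"rho={rho:g} infeasible for MAF {p0:.3f} and prevalence {p_e:g}: "
            f"per-dosage exposure probabilities {np.round(probs_by_dosage, 3)} leave [0, 1]"
        )
    E = (rng.random(cfg.n_samples) < (p_e + slope * (g0 - cfg.ploidy * p0))).astype(float)
    ds = _assemble_panel(rng, cfg, X, E, {"mafs": mafs, "seed": cfg.seed,
                                          "rho_target": rho, "index_snp": 0})
    ds.truth["rho_realized"] = float(np.corrcoef(g0, E)[0, 1])
    return ds


def child_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-replicate seed: SeedSequence([base, *indices]) folded to 31 bits."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


def _transformed_phenotype(y, transform, shift):
    if isinstance(transform, str):
        if transform in ("int", "inverse_normal"):
            return inverse_normal_transform(y), 0.0
        if transform == "identity":
            return y.copy(), 0.0
        if transform == "square_raw":
            # the practitioner's square: applied to the outcome as-is, with
            # no positivity shift; non-monotone wherever the data straddle 0
            return np.square(y), 0.0
        raise ValueError(f"unknown transform keyword {transform!r}")
    return apply_transform(y, transform, shift)


def replicate_experiment(
    config: PanelConfig,
    transform: TransformSpec | str,
    shift: ShiftPolicy | None = None,
    n_reps: int = 100,
    sigma2_grid: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 2.5),
    base_seed: int = 0,
    p_int_threshold: float = 0.05,
    p_main_threshold: float = 1.0,
) -> pd.DataFrame:
    """Detection counts and sign-consistency rates over replicates.

    For each interaction variance in ``sigma2_grid`` and each replicate:
    simulate a panel, fit all variants on the original and transformed
    scales, count interactions significant at ``p_int_threshold`` and
    compute the sign-consistency rate (proportion of significant
    interactions showing the more prevalent sign relationship with their
    main effects) on both scales.  ``transform`` may be a registry
    :class:`TransformSpec`, the keyword ``"int"`` for the rank-based
    inverse normal transformation, or ``"square_raw"`` for the square
    applied without a positivity shift.  Replicate seeds derive from
    ``base_seed`` via :func:`child_seed` so any single replicate can be
    regenerated independently.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    shift = shift if shift is not None else ShiftPolicy(mode="to_positive", margin=1.0)
    rows = []
    for si, s2 in enumerate(sigma2_grid):
        det_o, det_t, rate_o, rate_t = [], [], [], []
        for rep in range(n_reps):
            cfg = replace(config, sigma2_gxe=float(s2),
                          seed=child_seed(base_seed, si, rep))
            panel = simulate_panel(cfg)
            fits_o = fit_all(panel)
            yt, _ = _transformed_phenotype(panel.phenotype, transform, shift)
            fits_t = fit_all(panel.with_phenotype(yt))
            rep_o = sign_consistency_rate(fits_o, p_int_threshold, p_main_threshold)
            rep_t = sign_consistency_rate(fits_t, p_int_threshold, p_main_threshold)
            det_o.append(rep_o.n_selected)
            det_t.append(rep_t.n_selected)
            if rep_o.rate is not None:
                rate_o.append(rep_o.rate)
            if rep_t.rate is not None:
                rate_t.append(rep_t.rate)
        rows.append({
            "sigma2_gxe": float(s2),
            "n_detected_original_mean": float(np.mean(det_o)),
            "n_detected_original_sd": float(np.std(det_o, ddof=1)) if n_reps > 1 else float("nan"),
            "n_detected_transformed_mean": float(np.mean(det_t)),
            "n_detected_transformed_sd": float(np.std(det_t, ddof=1)) if n_reps > 1 else float("nan"),
            "rate_original_mean": float(np.mean(rate_o)) if rate_o else float("nan"),
            "rate_original_sd": float(np.std(rate_o, ddof=1)) if len(rate_o) > 1 else float("nan"),
            "rate_transformed_mean": float(np.mean(rate_t)) if rate_t else float("nan"),
            "rate_transformed_sd": float(np.std(rate_t, ddof=1)) if len(rate_t) > 1 else float("nan"),
            "n_reps": n_reps,
        })
    return pd.DataFrame(rows)
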