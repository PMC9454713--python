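"""Derived genetic parameters of the direct + social model.

With direct genetic variance σ²aD, social genetic variance σ²aS, their
covariance σaDaS and average pen size n, the quantities reported per
population are

    σ²TBV = σ²aD + 2(n−1) σaDaS + (n−1)² σ²aS      total heritable variance
    TBV_i = aD_i + (n−1) aS_i                       individual total breeding value
    σ²p   = σ²aD + (n−1) σ²aS + σ²d + σ²l + σ²e     phenotypic variance
    T²    = σ²TBV / σ²p                             total heritability
    h²    = σ²aD / σ²p                              direct heritability

Note the asymmetry: σ²p as defined above carries no covariance term while
σ²TBV does, so T² can exceed the naive sum of variance ratios when σaDaS>0.
Both formulas are implemented exactly as defined; report tables flag n
explicitly since every quantity except h² depends on it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "tbv_variance",
    "individual_tbv",
    "phenotypic_variance",
    "total_heritability",
    "direct_heritability",
    "genetic_correlations",
    "population_report",
]


def _check_n(n: float) -> None:
    if n <= 1:
        raise ValueError(f"average pen size must exceed 1 (got {n})")


def tbv_variance(
    sigma2_aD: float, sigma2_aS: float, cov_aD_aS: float, n: float
) -> float:
    """Total heritable variance σ²aD + 2(n−1)σaDaS + (n−1)²σ²aS."""
    _check_n(n)
    return sigma2_aD + 2.0 * (n - 1.0) * cov_aD_aS + (n - 1.0) ** 2 * sigma2_aS


def individual_tbv(aD_i, aS_i, n: float):
    """Individual total breeding value aD + (n−1) aS."""
    _check_n(n)
    return np.asarray(aD_i) + (n - 1.0) * np.asarray(aS_i)


def phenotypic_variance(
    sigma2_aD: float,
    sigma2_aS: float,
    sigma2_d: float,
    sigma2_l: float,
    sigma2_e: float,
    n: float,
) -> float:
    """Phenotypic variance σ²aD + (n−1)σ²aS + σ²d + σ²l + σ²e (no covariance term)."""
    _check_n(n)
    if min(sigma2_aD, sigma2_aS, sigma2_d, sigma2_l, sigma2_e) < 0:
        raise ValueError("variances must be non-negative")
    return sigma2_aD + (n - 1.0) * sigma2_aS + sigma2_d + sigma2_l + sigma2_e


def total_heritability(sigma2_TBV: float, sigma2_p: float) -> float:
    """T² = σ²TBV / σ²p."""
    if sigma2_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return sigma2_TBV / sigma2_p


def direct_heritability(sigma2_aD: float, sigma2_p: float) -> float:
    """h² = σ²aD / σ²p."""
    if sigma2_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return sigma2_aD / sigma2_p


def genetic_correlations(G0: np.ndarray) -> np.ndarray:
    """Covariance-to-correlation: r_ij = G0_ij / sqrt(G0_ii G0_jj)."""
    G0 = np.asarray(G0, dtype=float)
    d = np.diag(G0)
    if np.any(d <= 0):
        raise ValueError("zero or negative variance on the diagonal of G0")
    s = np.sqrt(d)
    return G0 / np.outer(s, s)


def population_report(
    sigma2_aD: float,
    sigma2_aS: float,
    cov_aD_aS: float,
    sigma2_d: float,
    sigma2_l: float,
    sigma2_e: float,
    n: float,
) -> dict:
    """All derived parameters for one population, with n echoed.

    Ratios are reported raw; round to 2 decimals (and variances to
    integers) for a publication-style table.
    """
    s2p = phenotypic_variance(sigma2_aD, sigma2_aS, sigma2_d, sigma2_l, sigma2_e, n)
    s2tbv = tbv_variance(sigma2_aD, sigma2_aS, cov_aD_aS, n)
    den = np.sqrt(sigma2_aD * sigma2_aS)
    return {
        "n_bar": n,
        "sigma2_aD": sigma2_aD,
        "sigma2_aS": sigma2_aS,
        "cov_aD_aS": cov_aD_aS,
        "sigma2_d": sigma2_d,
        "sigma2_l": sigma2_l,
        "sigma2_e": sigma2_e,
        "sigma2_p": s2p,
        "sigma2_TBV": s2tbv,
        "h2": direct_heritability(sigma2_aD, s2p),
        "T2": total_heritability(s2tbv, s2p),
        "r_DS": cov_aD_aS / den if den > 0 else np.nan,
    }
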