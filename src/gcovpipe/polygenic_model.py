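"""Closed-form polygenic-score power and genetic-covariance model.

Implements the published polygenic-score model for a score built from a
case/control discovery GWAS and tested against a quantitative target trait
(Dudbridge-style; no simulation).  The model assumes m independent score
SNPs of which m_c are causal, with liability-scale effects gamma_i per
standardized genotype, Var(gamma) = h2_liability / m_c, and a target trait
whose per-SNP effects delta_i share genetic covariance cov12 with the
disorder liability.

Case/control designs are mapped to the observed 0/1 scale through the
liability-threshold model: with prevalence K, case fraction P and z the
normal density at the liability threshold, the regression of case status on
a standardized genotype has slope C * gamma with

    C = z P (1 - P) / (K (1 - K)),

and the estimate carries sampling variance tau^2 = P (1 - P) / n1.  A SNP
enters the score when its two-sided Wald p-value is below the threshold
P_T, i.e. |beta_hat| > tau * Phi^-1(1 - P_T / 2).  For a normal variate
with variance s^2 truncated to |x| > T, E[x^2 ; |x| > T] =
2 s^2 (u phi(u) + 1 - Phi(u)) with u = T / s; this yields the expected
score variance and score-trait covariance, hence the expected target-sample
R^2, the non-centrality of the association test, and its power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class DiscoveryDesign:
    """Discovery GWAS: case/control counts and liability-scale architecture."""

    n_cases: int
    n_controls: int
    prevalence: float
    h2_liability: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.h2_liability <= 1.0:
            raise ValueError("h2_liability must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


@dataclass
class PolygenicModelSpec:
    """Design parameters of the score-trait association experiment.

    ``n_causal`` defaults to 100,000 causal SNPs per disorder;
    ``n_score_snps`` is the number of independent (post-clumping) SNPs the
    score draws from, of which the non-causal remainder contributes only
    noise.  ``genetic_covariance`` is on the standardized
    liability x trait scale.
    """

    discovery: DiscoveryDesign
    target_n: int
    n_causal: int = 100_000
    n_score_snps: int = 150_000
    p_threshold: float = 0.5
    alpha: float = 0.05
    genetic_covariance: float | None = None
    target_quantitative: bool = True
    target_h2: float | None = None

    def __post_init__(self) -> None:
        if not 0.001 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0.001, 1]")
        if self.n_score_snps < self.n_causal:
            raise ValueError("score SNP count cannot be below the causal count")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.target_quantitative:
            raise NotImplementedError("only quantitative target traits are modelled")
        if (self.genetic_covariance is not None and self.target_h2 is not None
                and self.genetic_covariance**2 > self.discovery.h2_liability * self.target_h2 + 1e-12):
            raise ValueError("inconsistent spec: covariance^2 > h2_discovery * h2_target")


def _truncated_second_moment(s2: float, threshold: float) -> float:
    """E[x^2 ; |x| > threshold] for x ~ N(0, s2)."""
    if s2 <= 0:
        return 0.0
    u = threshold / np.sqrt(s2)
    return float(2.0 * s2 * (u * stats.norm.pdf(u) + stats.norm.sf(u)))


def _score_moments(spec: PolygenicModelSpec) -> tuple[float, float]:
    """(covariance factor, score variance): Cov(S, y2) = cov12 * factor."""
    d = spec.discovery
    P = d.case_fraction
    K = d.prevalence
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    C = z * P * (1.0 - P) / (K * (1.0 - K))
    tau2 = P * (1.0 - P) / d.n_total
    m_c = spec.n_causal
    m_0 = spec.n_score_snps - m_c
    sigma_g2 = d.h2_liability / m_c
    s2_causal = C**2 * sigma_g2 + tau2
    T = np.sqrt(tau2) * stats.norm.isf(spec.p_threshold / 2.0)
    e2_causal = _truncated_second_moment(s2_causal, T)
    e2_null = _truncated_second_moment(tau2, T)
    cov_factor = C * e2_causal / s2_causal
    var_score = m_c * e2_causal + m_0 * e2_null
    return cov_factor, var_score


def expected_r2(spec: PolygenicModelSpec) -> float:
    """Expected squared correlation between the score and the target trait.

    This is the population R^2; for a finite target sample it matches the
    expectation of the *adjusted* regression R^2 (the adjustment removes
    the 1/n noise inflation of the raw R^2).
    """
    if spec.genetic_covariance is None:
        raise ValueError("spec.genetic_covariance is required")
    cov_factor, var_score = _score_moments(spec)
    cov = spec.genetic_covariance * cov_factor
    return float(cov**2 / var_score)


def polygenic_power(spec: PolygenicModelSpec) -> float:
    """Power of the target-sample score-trait association test at spec.alpha."""
    r2 = expected_r2(spec)
    ncp = spec.target_n * r2 / (1.0 - r2)
    crit = stats.chi2.isf(spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else float(spec.alpha)


def polygenic_covariance_from_r2(spec: PolygenicModelSpec, observed_r2: float,
                                 target_n: int | None = None):
    """Invert the forward model: the genetic covariance whose expected
    target R^2 equals ``observed_r2``, with a delta-method 95% CI from the
    sampling distribution of R^2 at the target sample size.

    Because R^2 = cov12^2 * factor^2 / Var(S) with both factors free of
    cov12, the inversion is closed-form.  Returns ``(estimate, lo, hi)``.
    """
    if not 0.0 <= observed_r2 < 1.0:
        raise ValueError("observed_r2 must lie in [0, 1)")
    n2 = target_n if target_n is not None else spec.target_n
    cov_factor, var_score = _score_moments(spec)
    estimate = float(np.sqrt(observed_r2 * var_score) / cov_factor)
    # sampling variance of the adjusted R^2 around its expectation
    var_r2 = 4.0 * observed_r2 * (1.0 - observed_r2) ** 2 / n2 + 2.0 / n2**2
    se_r2 = float(np.sqrt(var_r2))
    if observed_r2 == 0.0:  # boundary: one-sided interval
        upper = float(np.sqrt(1.96 * se_r2 * var_score) / cov_factor)
        return 0.0, 0.0, upper
    if estimate > 0:
        se_cov = estimate / (2.0 * observed_r2) * se_r2
        lo = max(0.0, estimate - 1.96 * se_cov)
        hi = estimate + 1.96 * se_cov
    else:
        lo = hi = 0.0
    return estimate, float(lo), float(hi)
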