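"""GREML: SNP-heritability, genetic correlation, and gene-set partitioned
variance components on genetic relationship matrices.

For rank-normalized traits (phenotypic variance one), the genetic variance
ratio Var_g = sigma2_g / (sigma2_g + sigma2_e) equals SNP-h2, the bivariate
genetic covariance Cov_g = r_g * sqrt(h2_1 * h2_2), and the partitioned
set share var_set = sigma2_set / total.  All fits use average-information
REML with EM fallback (see :mod:`gcovpipe.reml_core`); single-GRM fits are
solved exactly in the GRM eigenbasis, which reduces each iteration to O(n).

Likelihood-ratio tests for a single variance component on its boundary use
the 50:50 chi2_0/chi2_1 mixture; the bivariate covariance (unbounded sign)
uses a plain chi2_1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grm import GRM
from .reml_core import BlockDiagModel, DenseModel, RemlFit, boundary_lrt_pvalue, fit_reml
from .transform import TransformedMeasure

logger = logging.getLogger(__name__)

#: a genetic variance is treated as "at the zero boundary" below this share
#: of total variance, making ratios such as r_g undefined
BOUNDARY_SHARE = 1e-5


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    var_g: float
    se_var_g: float
    loglik_full: float
    loglik_null: float
    lrt_p: float
    n_used: int
    converged: bool


@dataclass
class BivariateEstimate:
    h2_1: float
    h2_2: float
    cov_g: float
    r_g: float
    r_e: float
    se_r_g: float
    se_cov_g: float
    lrt_p_rg0: float
    n_overlap: int
    converged: bool
    note: str = ""


@dataclass
class PartitionedComponents:
    sigma2_set: float
    sigma2_noset: float
    sigma2_e: float
    var_set: float
    var_noset: float
    se_var_set: float
    loglik_full: float
    loglik_reduced: float
    lrt_p_set: float
    n_used: int
    converged: bool


def _delta_se(grad: np.ndarray, cov: np.ndarray) -> float:
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def _align_grm(grm: GRM, ids) -> tuple[np.ndarray, list]:
    known = set(grm.sample_ids)
    missing = [i for i in ids if i not in known]
    if missing:
        raise ValueError(f"{len(missing)} phenotyped ids absent from GRM, e.g. {missing[:3]}")
    ordered = [s for s in grm.sample_ids if s in set(ids)]
    return grm.subset(ordered).values, ordered


def reml_univariate(y: TransformedMeasure, grm: GRM) -> VarianceComponents:
    """Single-GRM REML fit of y ~ N(mu, A sigma2_g + I sigma2_e)."""
    A, ordered = _align_grm(grm, y.individual_ids)
    yv = y.reindex(ordered)
    n = yv.size
    if n < 100:
        logger.warning("univariate REML on only %d individuals; estimates will be noisy", n)
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    yr = (U.T @ yv)[:, None]
    Xr = (U.T @ np.ones(n))[:, None, None]
    ones = np.ones(n)
    vy = float(np.var(yv, ddof=1))
    model = BlockDiagModel(yr, Xr, [(np.eye(1), d), (np.eye(1), ones)], var_mask=[True, True])
    full = fit_reml(model, start=[vy / 2, vy / 2], floor_scale=vy)
    null = fit_reml(model, start=[0.0, vy], free=[False, True], floor_scale=vy)
    if not full.converged:
        logger.warning("univariate REML did not converge after %d iterations", full.n_iter)
    sg, se_ = full.theta
    tot = sg + se_
    var_g = sg / tot
    grad = np.array([se_, -sg]) / tot**2
    se_var_g = _delta_se(grad, full.ai_inv)
    lrt = max(0.0, 2.0 * (full.loglik - null.loglik))
    return VarianceComponents(
        sigma2_g=float(sg), sigma2_e=float(se_), var_g=float(var_g),
        se_var_g=se_var_g, loglik_full=full.loglik, loglik_null=null.loglik,
        lrt_p=boundary_lrt_pvalue(lrt), n_used=n, converged=full.converged,
    )


def _bivariate_fast(y1v, y2v, A):
    """Complete-overlap bivariate model in the GRM eigenbasis (2x2 blocks)."""
    n = y1v.size
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    ones = np.ones(n)
    y = np.column_stack([U.T @ y1v, U.T @ y2v])
    u1 = U.T @ np.ones(n)
    X = np.zeros((n, 2, 2))
    X[:, 0, 0] = u1
    X[:, 1, 1] = u1
    E11 = np.array([[1.0, 0.0], [0.0, 0.0]])
    E22 = np.array([[0.0, 0.0], [0.0, 1.0]])
    E12 = np.array([[0.0, 1.0], [1.0, 0.0]])
    structures = [(E11, d), (E22, d), (E12, d), (E11, ones), (E22, ones), (E12, ones)]
    var_mask = [True, True, False, True, True, False]
    return BlockDiagModel(y, X, structures, var_mask)


def _bivariate_dense(y1, y2, grm):
    """Partial-overlap bivariate model: explicit structures over the stacked
    observation vector (trait-1 block then trait-2 block)."""
    ids1 = [s for s in grm.sample_ids if s in set(y1.individual_ids)]
    ids2 = [s for s in grm.sample_ids if s in set(y2.individual_ids)]
    pos = {s: i for i, s in enumerate(grm.sample_ids)}
    i1 = np.array([pos[s] for s in ids1], int)
    i2 = np.array([pos[s] for s in ids2], int)
    n1, n2 = i1.size, i2.size
    N = n1 + n2
    A = grm.values
    Sg1 = np.zeros((N, N)); Sg1[:n1, :n1] = A[np.ix_(i1, i1)]
    Sg2 = np.zeros((N, N)); Sg2[n1:, n1:] = A[np.ix_(i2, i2)]
    Scg = np.zeros((N, N))
    Scg[:n1, n1:] = A[np.ix_(i1, i2)]
    Scg[n1:, :n1] = Scg[:n1, n1:].T
    Se1 = np.zeros((N, N)); Se1[:n1, :n1] = np.eye(n1)
    Se2 = np.zeros((N, N)); Se2[n1:, n1:] = np.eye(n2)
    Sce = np.zeros((N, N))
    pos2 = {s: j for j, s in enumerate(ids2)}
    for a, s in enumerate(ids1):
        if s in pos2:
            Sce[a, n1 + pos2[s]] = Sce[n1 + pos2[s], a] = 1.0
    X = np.zeros((N, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0
    y = np.concatenate([y1.reindex(ids1), y2.reindex(ids2)])
    model = DenseModel(y, X, [Sg1, Sg2, Scg, Se1, Se2, Sce],
                       var_mask=[True, True, False, True, True, False])
    return model, ids1, ids2


def reml_bivariate(y1: TransformedMeasure, y2: TransformedMeasure, grm: GRM) -> BivariateEstimate:
    """Bivariate REML: heritabilities, genetic covariance/correlation, and
    residual correlation for two traits sharing one GRM.

    Individuals with either trait observed enter the fit; the residual
    covariance is carried by individuals measured on both.
    """
    set1, set2 = set(y1.individual_ids), set(y2.individual_ids)
    overlap = set1 & set2
    if set1 == set2:
        A, ordered = _align_grm(grm, y1.individual_ids)
        if np.allclose(y1.reindex(ordered), y2.reindex(ordered), atol=1e-12):
            # duplicated trait: the joint covariance is singular at the
            # optimum (r_g = r_e = 1 exactly); report the degenerate result
            # instead of crawling toward an unbounded likelihood
            uni = reml_univariate(y1, grm)
            note = "traits numerically identical; exact degenerate result (r_g = r_e = 1)"
            logger.info(note)
            return BivariateEstimate(
                h2_1=uni.var_g, h2_2=uni.var_g, cov_g=uni.var_g, r_g=1.0, r_e=1.0,
                se_r_g=0.0, se_cov_g=uni.se_var_g, lrt_p_rg0=uni.lrt_p,
                n_overlap=len(overlap), converged=uni.converged, note=note,
            )
        model = _bivariate_fast(y1.reindex(ordered), y2.reindex(ordered), A)
        v1 = float(np.var(y1.reindex(ordered), ddof=1))
        v2 = float(np.var(y2.reindex(ordered), ddof=1))
        c0 = float(np.cov(y1.reindex(ordered), y2.reindex(ordered))[0, 1])
    else:
        _align_grm(grm, list(set1 | set2))
        model, ids1, ids2 = _bivariate_dense(y1, y2, grm)
        v1 = float(np.var(y1.reindex(ids1), ddof=1))
        v2 = float(np.var(y2.reindex(ids2), ddof=1))
        if overlap:
            ov = sorted(overlap)
            c0 = float(np.cov(y1.reindex(ov), y2.reindex(ov))[0, 1])
        else:
            c0 = 0.0
    scale = max(v1, v2)
    start = [v1 / 2, v2 / 2, c0 / 2, v1 / 2, v2 / 2, c0 / 2]
    full = fit_reml(model, start=start, floor_scale=scale)
    null = fit_reml(model, start=[*full.theta[:2], 0.0, *full.theta[3:]],
                    free=[True, True, False, True, True, True], floor_scale=scale)
    sg1, sg2, cg, se1, se2, ce = full.theta
    t1, t2 = sg1 + se1, sg2 + se2
    h2_1, h2_2 = sg1 / t1, sg2 / t2
    note = ""
    if sg1 <= BOUNDARY_SHARE * t1 or sg2 <= BOUNDARY_SHARE * t2:
        r_g, se_r_g = float("nan"), float("nan")
        note = "a genetic variance sits at the zero boundary; r_g undefined (division by ~0)"
        logger.warning(note)
    else:
        r_g = cg / np.sqrt(sg1 * sg2)
        gr = np.array([-r_g / (2 * sg1), -r_g / (2 * sg2), 1.0 / np.sqrt(sg1 * sg2), 0, 0, 0])
        se_r_g = _delta_se(gr, full.ai_inv)
        if abs(r_g) > 1.0:
            logger.info("clamping r_g = %.4f to [-1, 1]", r_g)
            r_g = float(np.clip(r_g, -1.0, 1.0))
    # genetic covariance on the standardized-phenotype scale
    cov_g = cg / np.sqrt(t1 * t2)
    gc = np.empty(6)
    gc[2] = 1.0 / np.sqrt(t1 * t2)
    gc[0] = gc[3] = -cov_g / (2 * t1)
    gc[1] = gc[4] = -cov_g / (2 * t2)
    gc[5] = 0.0
    se_cov_g = _delta_se(gc, full.ai_inv)
    if se1 <= BOUNDARY_SHARE * t1 or se2 <= BOUNDARY_SHARE * t2:
        r_e = float("nan")
    else:
        r_e = float(np.clip(ce / np.sqrt(se1 * se2), -1.0, 1.0))
    # keep the reported triple internally consistent: cov_g = r_g sqrt(h2_1 h2_2)
    if np.isfinite(r_g):
        cov_g = r_g * np.sqrt(h2_1 * h2_2)
    lrt = max(0.0, 2.0 * (full.loglik - null.loglik))
    return BivariateEstimate(
        h2_1=float(h2_1), h2_2=float(h2_2), cov_g=float(cov_g), r_g=float(r_g),
        r_e=float(r_e), se_r_g=se_r_g, se_cov_g=se_cov_g,
        lrt_p_rg0=float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0,
        n_overlap=len(overlap), converged=full.converged and null.converged,
        note=note,
    )


def reml_partitioned(y: TransformedMeasure, grm_set: GRM, grm_noset: GRM) -> PartitionedComponents:
    """Three-component REML (set, noset, residual) with a boundary LRT for
    the in-set genetic variance against the noset-only reduced model."""
    if grm_set.sample_ids != grm_noset.sample_ids:
        raise ValueError("set-GRM and noset-GRM must cover identical individuals in the same order")
    A_set, ordered = _align_grm(grm_set, y.individual_ids)
    A_noset, _ = _align_grm(grm_noset, y.individual_ids)
    yv = y.reindex(ordered)
    n = yv.size
    vy = float(np.var(yv, ddof=1))
    X = np.ones((n, 1))
    model = DenseModel(yv, X, [A_set, A_noset, np.eye(n)], var_mask=[True, True, True])
    full = fit_reml(model, start=[vy / 4, vy / 4, vy / 2], floor_scale=vy)
    reduced = fit_reml(model, start=[0.0, full.theta[1], full.theta[2]],
                       free=[False, True, True], floor_scale=vy)
    ss, sn, se_ = full.theta
    tot = ss + sn + se_
    var_set = ss / tot
    grad = np.array([(tot - ss), -ss, -ss]) / tot**2
    se_var_set = _delta_se(grad, full.ai_inv)
    lrt = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return PartitionedComponents(
        sigma2_set=float(ss), sigma2_noset=float(sn), sigma2_e=float(se_),
        var_set=float(var_set), var_noset=float(sn / tot), se_var_set=se_var_set,
        loglik_full=full.loglik, loglik_reduced=reduced.loglik,
        lrt_p_set=boundary_lrt_pvalue(lrt), n_used=n, converged=full.converged,
    )
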