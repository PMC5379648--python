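"""Polygenic scoring and trait-disorder association analyses.

Covers LD clumping of discovery summary statistics against a target panel,
p-value-threshold score construction with effect-allele alignment,
cross-sectional OLS association with rank-normalized traits, and
longitudinal mixed-model association with untransformed scores (Gaussian
with random intercepts and age slopes; Poisson with random intercepts via
a Laplace-approximated likelihood).  The closed-form power/covariance model
lives in :mod:`gcovpipe.polygenic_model` and is re-exported here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datatypes import GenotypePanel, PhenotypeTable, SummaryStatsTable
from .polygenic_model import (  # noqa: F401  (module surface)
    DiscoveryDesign,
    PolygenicModelSpec,
    expected_r2,
    polygenic_covariance_from_r2,
    polygenic_power,
)
from .transform import TransformedMeasure

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


@dataclass
class PolygenicScoreSet:
    sample_ids: list
    thresholds: list
    scores: np.ndarray              # (n, n_thresholds), Z-standardized
    n_snps_per_threshold: list
    usable: list                    # False where no SNP passed / zero variance

    def column(self, threshold: float) -> np.ndarray:
        j = self.thresholds.index(threshold)
        if not self.usable[j]:
            raise ValueError(f"score at threshold {threshold} is unusable (no informative SNPs)")
        return self.scores[:, j]


@dataclass
class PGSAssocResult:
    threshold: float
    beta: float
    se: float
    p: float
    adj_r2: float


@dataclass
class PGSLongitudinalResult:
    beta_pgs: float
    ci_pgs: tuple
    beta_pgs_by_age: float
    ci_pgs_by_age: tuple
    lrt_p: float
    marginal_r2: float | None
    model_family: str
    note: str = ""


def clump(sumstats: SummaryStatsTable, panel: GenotypePanel,
          r2_threshold: float = 0.25, window: int = 500_000) -> list:
    """Greedy p-value-ordered LD clumping.

    Repeatedly takes the unclaimed SNP with smallest p as index and removes
    unclaimed SNPs within +/- ``window`` bp whose squared dosage correlation
    with it exceeds ``r2_threshold``.  Ties in p break by (chrom, pos).
    Duplicated SNP ids keep the smaller p; summary SNPs absent from the
    panel are dropped with a logged count.
    """
    tab = sumstats.table.sort_values("p_value").drop_duplicates("snp_id", keep="first")
    known = set(panel.snps["snp_id"])
    n_absent = int((~tab["snp_id"].isin(known)).sum())
    if n_absent:
        logger.info("dropping %d summary SNPs absent from the panel", n_absent)
    tab = tab[tab["snp_id"].isin(known)]
    idx = panel.snp_indices(tab["snp_id"])
    meta = panel.snps.iloc[idx]
    order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].to_numpy(),
                        tab["p_value"].to_numpy()))
    idx = idx[order]
    chrom = panel.snps["chrom"].to_numpy()[idx]
    pos = panel.snps["pos"].to_numpy()[idx]
    x = panel.dosages_float(idx)
    x = np.where(np.isnan(x), np.nanmean(x, axis=0), x)
    x = x - x.mean(axis=0)
    norm = np.sqrt((x**2).sum(axis=0))
    norm[norm == 0] = 1.0
    x = x / norm
    claimed = np.zeros(idx.size, dtype=bool)
    kept = []
    for i in range(idx.size):
        if claimed[i]:
            continue
        kept.append(idx[i])
        claimed[i] = True
        near = (~claimed) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        if near.any():
            r2 = (x[:, near].T @ x[:, i]) ** 2
            hits = np.flatnonzero(near)[r2 > r2_threshold]
            claimed[hits] = True
    snp_ids = panel.snps["snp_id"].to_numpy(object)
    return [snp_ids[k] for k in kept]


def build_scores(panel: GenotypePanel, sumstats: SummaryStatsTable, clumped_ids,
                 thresholds=DEFAULT_THRESHOLDS) -> PolygenicScoreSet:
    """Per-threshold weighted allele scores, Z-standardized across individuals.

    Dosages are aligned to the summary effect allele: when the effect allele
    is the panel reference, the dosage is complemented (2 - x), which leaves
    the score invariant under allele-label flips.  Missing dosages
    contribute the frequency-expected 2 * freq * effect.
    """
    thresholds = sorted(thresholds)
    if any(not 0.001 < t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0.001, 1]")
    tab = sumstats.table.set_index("snp_id").loc[list(clumped_ids)]
    idx = panel.snp_indices(list(clumped_ids))
    x = panel.dosages_float(idx)
    panel_alt = panel.snps["allele_alt"].to_numpy(object)[idx]
    panel_ref = panel.snps["allele_ref"].to_numpy(object)[idx]
    eff_allele = tab["allele_effect"].to_numpy(object)
    flip = eff_allele == panel_ref
    bad = ~flip & (eff_allele != panel_alt)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} SNPs with effect allele matching neither panel allele")
    x[:, flip] = 2.0 - x[:, flip]
    freq = panel.snps["allele_freq"].to_numpy(float)[idx]
    freq = np.where(flip, 1.0 - freq, freq)
    x = np.where(np.isnan(x), 2.0 * freq, x)
    effect = tab["effect"].to_numpy(float)
    pvals = tab["p_value"].to_numpy(float)

    n = panel.n_individuals
    scores = np.zeros((n, len(thresholds)))
    counts, usable = [], []
    for j, pt in enumerate(thresholds):
        sel = pvals <= pt
        counts.append(int(sel.sum()))
        raw = x[:, sel] @ effect[sel]
        sd = raw.std(ddof=1) if sel.any() else 0.0
        if sd == 0:
            usable.append(False)
            logger.warning("score at P_T=%g has no informative SNPs; flagged unusable", pt)
            continue
        scores[:, j] = (raw - raw.mean()) / sd
        usable.append(True)
    return PolygenicScoreSet(list(panel.sample_ids), thresholds, scores, counts, usable)


def assoc_cross_sectional(scores: PolygenicScoreSet, y: TransformedMeasure) -> list:
    """OLS of a rank-normalized measure on each usable Z-standardized score."""
    pos = {s: i for i, s in enumerate(scores.sample_ids)}
    common = [s for s in y.individual_ids if s in pos]
    if len(common) < 30:
        raise ValueError(f"only {len(common)} overlapping individuals; need >= 30")
    yi = y.reindex(common)
    rows_i = np.array([pos[s] for s in common], int)
    out = []
    for j, pt in enumerate(scores.thresholds):
        if not scores.usable[j]:
            logger.info("skipping unusable score at P_T=%g", pt)
            continue
        s = scores.scores[rows_i, j]
        fit = sm.OLS(yi, sm.add_constant(s)).fit()
        out.append(PGSAssocResult(
            threshold=pt, beta=float(fit.params[1]), se=float(fit.bse[1]),
            p=float(fit.pvalues[1]), adj_r2=float(fit.rsquared_adj),
        ))
    return out


def _longitudinal_frame(scores, table: PhenotypeTable, trait: str, threshold: float) -> pd.DataFrame:
    s = pd.Series(scores.column(threshold), index=scores.sample_ids, name="pgs")
    rows = table.rows[table.rows["trait"] == trait].copy()
    rows = rows[rows["iid"].isin(s.index)]
    rows["pgs"] = s.loc[rows["iid"]].to_numpy()
    rows = rows.dropna(subset=["score", "pgs", "sex", "age"])
    rows["age_c"] = rows["age"] - rows["age"].mean()
    return rows.reset_index(drop=True)


def _fit_gaussian_lmm(df: pd.DataFrame, interaction: bool, reml: bool, start_params=None):
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    formula = "score ~ pgs + sex + age_c" + (" + pgs:age_c" if interaction else "")
    md = smf.mixedlm(formula, df, groups=df["iid"], re_formula="~age_c")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = md.fit(reml=reml, method="lbfgs", maxiter=200, disp=False,
                         start_params=start_params)
            if not np.all(np.isfinite(fit.cov_re.to_numpy())) or np.linalg.det(fit.cov_re) < 0:
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("random-effect covariance singular; refitting with diagonal covariance")
            free = sm.regression.mixed_linear_model.MixedLMParams.from_components(
                fe_params=np.ones(md.k_fe), cov_re=np.eye(2))
            fit = md.fit(reml=reml, free=free, method="lbfgs", maxiter=200, disp=False)
    return fit


def _marginal_r2_gaussian(fit, df: pd.DataFrame) -> float:
    """Fixed-effects share of total variance:
    var(X beta) / (var(X beta) + var(random) + var(residual))."""
    fe = fit.model.exog @ fit.fe_params
    var_f = float(np.var(fe))
    Z = np.column_stack([np.ones(len(df)), df["age_c"].to_numpy()])
    G = fit.cov_re.to_numpy()
    var_r = float(np.mean(np.einsum("ni,ij,nj->n", Z, G, Z)))
    var_e = float(fit.scale)
    return var_f / (var_f + var_r + var_e)


def assoc_longitudinal_gaussian(scores: PolygenicScoreSet, raw_scores: PhenotypeTable,
                                trait: str, threshold: float = 0.5,
                                n_boot: int = 500, seed: int = 0) -> PGSLongitudinalResult:
    """Linear mixed model of repeated raw scores on the score at one threshold.

    Fixed effects: PGS, sex, centred age; random intercepts and age slopes
    per individual; REML point estimates.  The PGS x age interaction is
    tested by a maximum-likelihood LRT between nested models.  Individual-
    level nonparametric bootstrap (individuals resampled with all their
    occasions) gives normal-approximation 95% CIs around the point
    estimates.
    """
    df = _longitudinal_frame(scores, raw_scores, trait, threshold)
    base = _fit_gaussian_lmm(df, interaction=False, reml=True)
    inter = _fit_gaussian_lmm(df, interaction=True, reml=True)
    ml0 = _fit_gaussian_lmm(df, interaction=False, reml=False)
    ml1 = _fit_gaussian_lmm(df, interaction=True, reml=False)
    lrt = max(0.0, 2.0 * (ml1.llf - ml0.llf))
    lrt_p = float(stats.chi2.sf(lrt, df=1))
    beta = float(base.fe_params["pgs"])
    beta_ia = float(inter.fe_params["pgs:age_c"])
    rng = np.random.default_rng(seed)
    ids = df["iid"].unique()
    groups = {i: sub for i, sub in df.groupby("iid")}
    warm = inter.params.to_numpy()
    bb, bi = [], []
    for _ in range(n_boot):
        take = rng.choice(ids, size=ids.size, replace=True)
        bdf = pd.concat(
            [groups[i].assign(iid=f"{i}_b{k}") for k, i in enumerate(take)],
            ignore_index=True)
        try:
            # one interaction fit per resample: with age centred its PGS main
            # effect coincides with the base model's
            bfit = _fit_gaussian_lmm(bdf, True, True, start_params=warm)
            bb.append(float(bfit.fe_params["pgs"]))
            bi.append(float(bfit.fe_params["pgs:age_c"]))
        except Exception:  # non-convergence on a resample: skip it
            continue
    note = ""
    if len(bb) < 2:
        note = "bootstrap degenerate (fewer than 2 successful resamples); CI collapsed to the point estimate"
        logger.warning(note)
        sd_b = sd_i = 0.0
    else:
        sd_b, sd_i = float(np.std(bb, ddof=1)), float(np.std(bi, ddof=1))
    r2 = _marginal_r2_gaussian(base, df)
    return PGSLongitudinalResult(
        beta_pgs=beta, ci_pgs=(beta - 1.96 * sd_b, beta + 1.96 * sd_b),
        beta_pgs_by_age=beta_ia, ci_pgs_by_age=(beta_ia - 1.96 * sd_i, beta_ia + 1.96 * sd_i),
        lrt_p=lrt_p, marginal_r2=r2, model_family="gaussian", note=note,
    )


# ---------------------------------------------------------------------------
# Poisson random-intercept GLMM via the Laplace approximation


def _poisson_laplace_loglik(beta, log_s2, X, y, group_idx, n_groups):
    """Marginal log-likelihood with per-group random intercepts integrated
    out by a one-dimensional Laplace approximation (Newton inner loop)."""
    s2 = np.exp(log_s2)
    eta0 = X @ beta
    u = np.zeros(n_groups)
    for _ in range(50):
        eta = eta0 + u[group_idx]
        mu = np.exp(np.clip(eta, -30, 30))
        g = np.bincount(group_idx, weights=y - mu, minlength=n_groups) - u / s2
        h = -np.bincount(group_idx, weights=mu, minlength=n_groups) - 1.0 / s2
        step = g / h
        u_new = u - step
        if np.max(np.abs(step)) < 1e-10:
            u = u_new
            break
        u = u_new
    eta = eta0 + u[group_idx]
    mu = np.exp(np.clip(eta, -30, 30))
    pois = np.sum(y * eta - mu - special.gammaln(y + 1.0))
    h = np.bincount(group_idx, weights=mu, minlength=n_groups) + 1.0 / s2
    ll = pois - 0.5 * np.sum(u**2) / s2 - 0.5 * n_groups * np.log(s2) - 0.5 * np.sum(np.log(h))
    return float(ll)


def _fit_poisson_glmm(df: pd.DataFrame, interaction: bool):
    cols = ["pgs", "sex", "age_c"] + (["pgs_age"] if interaction else [])
    work = df.copy()
    work["pgs_age"] = work["pgs"] * work["age_c"]
    X = np.column_stack([np.ones(len(work))] + [work[c].to_numpy(float) for c in cols])
    y = work["score"].to_numpy(float)
    codes, _ = pd.factorize(work["iid"])
    n_groups = int(codes.max()) + 1

    def negll(theta):
        return -_poisson_laplace_loglik(theta[:-1], theta[-1], X, y, codes, n_groups)

    mu0 = max(y.mean(), 0.1)
    start = np.zeros(X.shape[1] + 1)
    start[0] = np.log(mu0)
    start[-1] = np.log(0.5)
    res = optimize.minimize(negll, start, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    names = ["intercept", *cols, "log_sigma2_u"]
    params = dict(zip(names, res.x))
    return params, -res.fun, res.success


def assoc_longitudinal_poisson(scores: PolygenicScoreSet, raw_scores: PhenotypeTable,
                               trait: str, threshold: float = 0.5,
                               n_boot: int = 500, seed: int = 0) -> PGSLongitudinalResult:
    """Mixed Poisson regression of repeated raw counts on the score:
    log link, fixed PGS/sex/centred-age effects, random intercepts only,
    Laplace-approximated likelihood.  The PGS coefficient is the increase
    in natural-log scores per SD of PGS.  No marginal R^2 is reported."""
    df = _longitudinal_frame(scores, raw_scores, trait, threshold)
    p0, ll0, _ = _fit_poisson_glmm(df, interaction=False)
    p1, ll1, _ = _fit_poisson_glmm(df, interaction=True)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    lrt_p = float(stats.chi2.sf(lrt, df=1))
    beta = p0["pgs"]
    beta_ia = p1["pgs_age"]
    rng = np.random.default_rng(seed)
    ids = df["iid"].unique()
    groups = {i: sub for i, sub in df.groupby("iid")}
    bb, bi = [], []
    for _ in range(n_boot):
        take = rng.choice(ids, size=ids.size, replace=True)
        bdf = pd.concat(
            [groups[i].assign(iid=f"{i}_b{k}") for k, i in enumerate(take)],
            ignore_index=True)
        try:
            pb, _, _ = _fit_poisson_glmm(bdf, False)
            pib, _, _ = _fit_poisson_glmm(bdf, True)
            bb.append(pb["pgs"])
            bi.append(pib["pgs_age"])
        except Exception:
            continue
    note = ""
    if len(bb) < 2:
        note = "bootstrap degenerate (fewer than 2 successful resamples); CI collapsed to the point estimate"
        logger.warning(note)
        sd_b = sd_i = 0.0
    else:
        sd_b, sd_i = float(np.std(bb, ddof=1)), float(np.std(bi, ddof=1))
    return PGSLongitudinalResult(
        beta_pgs=beta, ci_pgs=(beta - 1.96 * sd_b, beta + 1.96 * sd_b),
        beta_pgs_by_age=beta_ia, ci_pgs_by_age=(beta_ia - 1.96 * sd_i, beta_ia + 1.96 * sd_i),
        lrt_p=lrt_p, marginal_r2=None, model_family="poisson", note=note,
    )
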