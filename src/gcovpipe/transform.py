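"""Phenotype pre-processing: covariate residualization, rank-based inverse
normal transformation, correlation matrices, and the effective number of
independent tests.

Raw questionnaire scores are integer-valued, right-skewed and leptokurtic;
downstream variance-component models assume multivariate normality.  Each
measure is therefore residualized on sex, exact age and two ancestry PCs by
OLS, and the residuals are mapped to normal scores via Blom's rank
transform.  Because integer scores guarantee heavy ties, ranks use the
average-rank convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PhenotypeTable, ValidationError

COVARIATES = ["sex", "age", "pc1", "pc2"]


class DegenerateInputError(ValueError):
    """Input without enough variation for the requested transform."""


@dataclass
class TransformedMeasure:
    """A residualized, rank-normalized measure aligned to individual ids."""

    individual_ids: list
    values: np.ndarray
    trait: str = ""
    age_band: object = None
    covariates: tuple = ()

    def __post_init__(self) -> None:
        self.individual_ids = list(self.individual_ids)
        self.values = np.asarray(self.values, float)
        if len(self.individual_ids) != self.values.size:
            raise ValidationError("ids and values must align")

    @property
    def label(self) -> str:
        return f"{self.trait}_{self.age_band}" if self.age_band is not None else self.trait

    def reindex(self, ids) -> np.ndarray:
        """Values for the requested ids, NaN where the measure is missing."""
        pos = {s: i for i, s in enumerate(self.individual_ids)}
        out = np.full(len(ids), np.nan)
        for k, s in enumerate(ids):
            if s in pos:
                out[k] = self.values[pos[s]]
        return out


@dataclass
class CorrelationMatrix:
    labels: list
    values: np.ndarray
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError("correlation matrix shape must match labels")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.values) > 1 + 1e-8):
            raise ValidationError("correlations must lie in [-1, 1]")


@dataclass
class EffectiveTests:
    m_observed: int
    m_effective: int
    alpha_family: float
    alpha_experimentwise: float


def residualize(table: PhenotypeTable, trait: str, age_band,
                covariates=tuple(COVARIATES)) -> TransformedMeasure:
    """OLS residuals of one measure's raw score on intercept + covariates.

    Rows with any missing score or covariate are dropped.  A rank-deficient
    design raises, naming the collinear column.
    """
    rows = table.measure(trait, age_band)
    cols = ["score", *covariates]
    complete = rows.dropna(subset=cols)
    if len(complete) < 10:
        raise ValueError(f"only {len(complete)} complete cases for {trait}@{age_band}; need >= 10")
    y = complete["score"].to_numpy(float)
    X = np.column_stack([np.ones(len(complete))] + [complete[c].to_numpy(float) for c in covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j, name in enumerate(["intercept", *covariates]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"design is rank-deficient: column {name!r} is collinear")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return TransformedMeasure(
        individual_ids=list(complete["iid"]), values=resid,
        trait=trait, age_band=age_band, covariates=tuple(covariates),
    )


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse normal scores: Phi^-1((r - 3/8) / (n + 1/4)).

    Ties receive average ranks, so tied inputs map to identical outputs.
    """
    values = np.asarray(values, float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(values) == 0:
        raise DegenerateInputError("all values identical; rank transform undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def transform_measure(table: PhenotypeTable, trait: str, age_band,
                      covariates=tuple(COVARIATES)) -> TransformedMeasure:
    """Residualize then rank-normalize one measure (the standard pipeline step)."""
    m = residualize(table, trait, age_band, covariates)
    return TransformedMeasure(m.individual_ids, rank_inverse_normal(m.values),
                              trait=m.trait, age_band=m.age_band, covariates=m.covariates)


def correlation_matrix(measures, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise-complete correlation matrix across measures.

    ``measures`` may be :class:`TransformedMeasure` objects (aligned by id)
    or plain equal-length vectors (aligned by position).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if all(isinstance(m, TransformedMeasure) for m in measures):
        labels = [m.label for m in measures]
        ids = sorted(set().union(*[m.individual_ids for m in measures]))
        data = np.column_stack([m.reindex(ids) for m in measures])
    else:
        labels = [f"v{i}" for i in range(len(measures))]
        data = np.column_stack([np.asarray(m, float) for m in measures])
    k = data.shape[1]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(data[:, i]) & ~np.isnan(data[:, j])
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 overlapping observations for pair ({labels[i]}, {labels[j]})")
            xi, xj = data[ok, i], data[ok, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                raise DegenerateInputError(f"zero-variance series in pair ({labels[i]}, {labels[j]})")
            if method == "pearson":
                r = stats.pearsonr(xi, xj).statistic
            else:
                r = stats.spearmanr(xi, xj).statistic
            out[i, j] = out[j, i] = r
    return CorrelationMatrix(labels, out, method)


def effective_tests(corr: CorrelationMatrix, alpha_family: float) -> EffectiveTests:
    """Effective number of independent measures and the Sidak-adjusted
    experiment-wise error rate.

    Uses the eigenvalue-spectrum estimator
    Meff = 1 + (M - 1) (1 - var(lambda)/M), rounded to the nearest integer,
    then alpha_e = 1 - (1 - alpha_family)^(1/Meff).
    """
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must lie in (0, 1)")
    evals = np.linalg.eigvalsh(corr.values)
    if evals.min() < -1e-6:
        raise ValidationError(f"correlation matrix not PSD (min eigenvalue {evals.min():.3g})")
    m = len(evals)
    var_l = np.var(evals, ddof=1) if m > 1 else 0.0  # sample variance of the spectrum
    meff = int(np.clip(round(1 + (m - 1) * (1 - var_l / m)), 1, m))
    alpha_e = 1.0 - (1.0 - alpha_family) ** (1.0 / meff)
    return EffectiveTests(m_observed=m, m_effective=meff,
                          alpha_family=alpha_family, alpha_experimentwise=alpha_e)
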