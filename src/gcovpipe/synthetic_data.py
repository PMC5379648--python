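"""Synthetic cohort generator with known ground truth.

Emulates the structure of a longitudinal population cohort genotyped on a
post-QC chip: Hardy-Weinberg dosages on 22 autosomes, non-overlapping gene
intervals, two correlated questionnaire traits measured at several ages
(integer scores, right-skewed via a binomial quantile map), and case/control
discovery GWAS summary statistics generated under the liability-threshold
model.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GeneAnnotation,
    GenotypePanel,
    PhenotypeTable,
    SummaryStatsTable,
    TraitSimSpec,
    TraitSpec,
    ValidationError,
)
from .grm import partition_by_geneset

_CHROMOSOMES = np.arange(1, 23)
_CHROM_LENGTH = 130_000_000  # uniform synthetic autosome length, bp

#: assessment ages of the two instruments (years), configurable per spec
DEFAULT_AGES = {"SDQ-ADHD": [7, 10, 12, 13, 17], "SCDC": [8, 11, 14, 17]}


class PlacementError(RuntimeError):
    """Gene intervals could not be placed without overlap."""


def simulate_genotypes(n_individuals: int, n_snps: int, maf_low: float,
                       maf_high: float, seed: int) -> GenotypePanel:
    """Hardy-Weinberg dosage panel: per SNP, two independent Bernoulli(p)
    allele draws with p ~ Uniform(maf_low, maf_high), SNPs spread uniformly
    over 22 autosomes at strictly increasing positions."""
    if not (0.01 <= maf_low < maf_high <= 0.5):
        raise ValueError("require 0.01 <= maf_low < maf_high <= 0.5")
    if n_individuals < 2 or n_snps < 1:
        raise ValueError("need at least 2 individuals and 1 SNP")
    rng = np.random.default_rng(seed)
    chrom = np.sort(rng.integers(1, 23, size=n_snps))
    pos = np.empty(n_snps, dtype=np.int64)
    for c in _CHROMOSOMES:
        sel = chrom == c
        k = int(sel.sum())
        if not k:
            continue
        raw = np.sort(rng.integers(1, _CHROM_LENGTH, size=k))
        # enforce strict increase under the (rare) collision
        raw = raw + np.arange(k)
        pos[sel] = raw
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    dosages = rng.binomial(2, p, size=(n_individuals, n_snps)).astype(np.int8)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "allele_ref": "A",
            "allele_alt": "G",
            "allele_freq": p,
        }
    )
    ids = [f"id{i + 1:06d}" for i in range(n_individuals)]
    return GenotypePanel(sample_ids=ids, snps=snps, dosages=dosages)


def simulate_annotation(panel: GenotypePanel, n_genes: int, mean_length: int,
                        seed: int, max_tries: int = 1000) -> GeneAnnotation:
    """Place ``n_genes`` non-overlapping gene intervals with exponentially
    distributed lengths (mean ``mean_length``) on the panel's chromosomes."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    chroms = sorted(panel.snps["chrom"].unique())
    extent = {c: max(int(panel.snps.loc[panel.snps["chrom"] == c, "pos"].max()) + 2 * mean_length,
                     10 * (mean_length + 1))
              for c in chroms}
    placed: dict[int, list] = {c: [] for c in chroms}
    records = []
    for g in range(n_genes):
        length = int(round(rng.exponential(mean_length))) if mean_length > 0 else 0
        for attempt in range(max_tries):
            c = int(rng.choice(chroms))
            hi = extent[c] - length
            if hi < 1:
                continue
            start = int(rng.integers(1, hi + 1))
            end = start + length
            if all(end < s or start > e for s, e in placed[c]):
                placed[c].append((start, end))
                records.append((f"gene{g + 1}", c, start, end))
                break
        else:
            raise PlacementError(
                f"could not place gene {g + 1} of length {length} after {max_tries} tries"
            )
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end"])
    return GeneAnnotation(genes.sort_values(["chrom", "start"]).reset_index(drop=True))


@dataclass
class TraitGroundTruth:
    """What the generator actually did - for parameter-recovery checks."""

    causal_snp_ids: list
    effects: np.ndarray          # (n_causal, K) per standardized dosage
    genetic_values: np.ndarray   # (n, K), variance h2_k per column
    latent: np.ndarray           # (n, K) genetic + covariates + residual
    measure_labels: list
    set_causal_ids: list


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def simulate_longitudinal_traits(panel: GenotypePanel, spec: TraitSimSpec,
                                 annotation: GeneAnnotation | None = None,
                                 return_truth: bool = False):
    """Generate the longitudinal phenotype table from a genotype panel.

    Per-SNP effect vectors across the K measures are multivariate normal
    with the spec's genetic correlation matrix; per-measure scales hit the
    h2 targets exactly in-sample (genetic values are rescaled to realized
    variance h2_k, which preserves all correlations).  Residual vectors
    follow the residual correlation matrix.  When an enriched gene set is
    given, the stated fraction of each measure's genetic variance is routed
    through causal SNPs inside set genes +/- flank.

    Latent values are mapped to integer raw scores through the quantile map
    of a right-skewed binomial, so the latent -> raw map is monotone.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = panel.n_individuals, panel.n_snps
    if spec.n_causal > m:
        raise ValueError("causal SNP count exceeds panel SNPs")
    K = spec.n_measures
    h2 = spec.h2_targets
    labels = spec.measure_labels
    snp_ids = panel.snps["snp_id"].to_numpy(object)

    if spec.enriched_gene_ids and spec.enrichment_fraction > 0:
        if annotation is None:
            raise ValueError("enrichment requested but no annotation supplied")
        part = partition_by_geneset(panel, annotation, spec.enriched_gene_ids,
                                    spec.enrichment_flank)
        set_pool = panel.snp_indices(part.set_snp_ids)
        noset_pool = panel.snp_indices(part.noset_snp_ids)
        if set_pool.size == 0:
            raise ValueError("enriched gene set (+flank) contains no panel SNPs")
        n_set = min(max(1, spec.n_causal // 2), set_pool.size)
        n_out = spec.n_causal - n_set
        if n_out > noset_pool.size:
            raise ValueError("not enough out-of-set SNPs for the causal draw")
        idx_set = rng.choice(set_pool, size=n_set, replace=False)
        idx_out = rng.choice(noset_pool, size=n_out, replace=False)
        causal = np.concatenate([idx_set, idx_out])
        # per-SNP variance shares: fraction f of Var(g) from set causals
        f = spec.enrichment_fraction
        w = np.concatenate([
            np.full(n_set, f / n_set),
            np.full(n_out, (1.0 - f) / max(n_out, 1)),
        ])
        set_causal_ids = list(snp_ids[idx_set])
    else:
        causal = rng.choice(m, size=spec.n_causal, replace=False)
        w = np.full(spec.n_causal, 1.0 / spec.n_causal)
        set_causal_ids = []

    z = _standardize_columns(panel.dosages_float(causal))
    # standardized effect draws with the target genetic correlation
    L = np.linalg.cholesky(spec.genetic_corr + 1e-10 * np.eye(K))
    u = rng.standard_normal((spec.n_causal, K)) @ L.T
    beta = u * np.sqrt(np.outer(w, h2))
    g = z @ beta
    # rescale realized per-measure genetic variance onto the h2 targets
    g_sd = g.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(g_sd > 0, np.sqrt(h2) / np.where(g_sd > 0, g_sd, 1.0), 0.0)
    g = g * scale
    beta = beta * scale

    Le = np.linalg.cholesky(spec.residual_corr + 1e-10 * np.eye(K))
    e = rng.standard_normal((n, K)) @ Le.T
    e = _standardize_columns(e) * np.sqrt(1.0 - h2)

    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 2))
    latent = g + e + spec.sex_effect * (sex - sex.mean())[:, None]

    rows = []
    score_ranges = {}
    col = 0
    for trait in spec.traits:
        score_ranges[trait.label] = (0, trait.max_score)
        for age in trait.ages:
            y = latent[:, col]
            u01 = stats.norm.cdf((y - y.mean()) / y.std())
            raw = stats.binom.ppf(np.clip(u01, 1e-12, 1 - 1e-12),
                                  trait.max_score, trait.skew_p).astype(int)
            exact_age = age + rng.normal(0.0, spec.age_jitter_sd, size=n)
            exact_age -= exact_age.mean() - age
            rows.append(pd.DataFrame({
                "iid": panel.sample_ids,
                "trait": trait.label,
                "age_band": age,
                "age": exact_age,
                "sex": sex.astype(int),
                "score": raw,
                "pc1": pcs[:, 0],
                "pc2": pcs[:, 1],
            }))
            col += 1
    table = PhenotypeTable(pd.concat(rows, ignore_index=True), score_ranges=score_ranges)
    if not return_truth:
        return table
    truth = TraitGroundTruth(
        causal_snp_ids=list(snp_ids[causal]), effects=beta, genetic_values=g,
        latent=latent, measure_labels=labels, set_causal_ids=set_causal_ids,
    )
    return table, truth


def default_spec(seed: int = 0, n_causal: int = 500, **overrides) -> TraitSimSpec:
    """Study-shaped default: two instruments at their assessment ages with
    age-gap-decaying genetic correlations.

    Within-trait genetic correlations follow exp(-0.06 |delta age|); the
    cross-trait factor is 0.9 (correlations across traits nearly as strong
    as within).  Residual correlations decay faster, exp(-0.15 |delta age|),
    with cross-trait factor 0.5.  Both kernels are separable products of
    positive-definite kernels, hence valid correlation matrices.
    """
    traits = [
        TraitSpec("SDQ-ADHD", DEFAULT_AGES["SDQ-ADHD"], [0.10, 0.15, 0.19, 0.18, 0.12],
                  max_score=10, skew_p=0.25),
        TraitSpec("SCDC", DEFAULT_AGES["SCDC"], [0.24, 0.16, 0.08, 0.45],
                  max_score=24, skew_p=0.12),
    ]
    ages = np.array([a for t in traits for a in t.ages], float)
    tcode = np.array([i for i, t in enumerate(traits) for _ in t.ages])
    dt = np.abs(ages[:, None] - ages[None, :])
    cross = tcode[:, None] != tcode[None, :]
    g_corr = np.exp(-0.06 * dt) * np.where(cross, 0.9, 1.0)
    e_corr = np.exp(-0.15 * dt) * np.where(cross, 0.5, 1.0)
    np.fill_diagonal(g_corr, 1.0)
    np.fill_diagonal(e_corr, 1.0)
    kwargs = dict(traits=traits, genetic_corr=g_corr, residual_corr=e_corr,
                  n_causal=n_causal, seed=seed)
    kwargs.update(overrides)
    return TraitSimSpec(**kwargs)


def liability_to_logodds_scale(prevalence: float) -> float:
    """Factor converting a liability-scale standardized-genotype effect into
    a per-standardized-genotype log-odds under the liability-threshold
    model: z / (K (1 - K)) with z the normal density at the threshold."""
    t = stats.norm.ppf(1.0 - prevalence)
    return float(stats.norm.pdf(t) / (prevalence * (1.0 - prevalence)))


def simulate_disorder_gwas(panel: GenotypePanel, h2_liability: float, prevalence: float,
                           n_cases: int, n_controls: int, shared_causal_ids,
                           seed: int, n_causal: int | None = None,
                           trait_effects: dict | None = None,
                           genetic_covariance: float = 0.0) -> SummaryStatsTable:
    """Analytic case/control discovery GWAS under the liability-threshold model.

    Liability-scale effects (per standardized genotype) are drawn for a
    causal set consisting of ``shared_causal_ids`` plus random panel SNPs up
    to ``n_causal``.  When ``genetic_covariance`` is nonzero, the shared
    SNPs' liability effects are drawn correlated with the supplied
    ``trait_effects`` so that the expected trait-disorder genetic covariance
    equals the target.  Reported statistics are per-allele log-odds:
    true effect (liability -> observed-scale conversion at the stated
    prevalence) plus Gaussian noise at the design-implied standard error,
    with Wald p-values.
    """
    if not 0.0 < prevalence < 0.5:
        raise ValueError("prevalence must lie in (0, 0.5)")
    if not 0.0 <= h2_liability <= 1.0:
        raise ValueError("h2_liability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = panel.n_snps
    snp_ids = panel.snps["snp_id"].to_numpy(object)
    shared_idx = panel.snp_indices(list(shared_causal_ids))  # raises on unknown ids
    n_causal = n_causal if n_causal is not None else max(len(shared_idx), min(m, 1000))
    if n_causal < len(shared_idx) or n_causal > m:
        raise ValueError("n_causal must lie between len(shared_causal_ids) and n_snps")
    pool = np.setdiff1d(np.arange(m), shared_idx)
    extra = rng.choice(pool, size=n_causal - len(shared_idx), replace=False)
    causal = np.concatenate([shared_idx, extra]).astype(int)

    gamma = np.zeros(m)
    per_snp_var = h2_liability / n_causal if n_causal else 0.0
    if genetic_covariance != 0.0:
        if not trait_effects:
            raise ValueError("genetic_covariance requires the trait's per-SNP effects")
        beta_sh = np.array([trait_effects[s] for s in snp_ids[shared_idx]])
        v_shared = float(np.sum(beta_sh**2))
        if v_shared <= 0:
            raise ValueError("shared trait effects carry no variance")
        a = genetic_covariance / v_shared
        resid_var = per_snp_var - a**2 * np.mean(beta_sh**2)
        if resid_var < 0:
            raise ValidationError(
                "requested genetic covariance exceeds what the liability h2 allows "
                "(covariance^2 > h2_disorder * shared trait variance)"
            )
        gamma[shared_idx] = a * beta_sh + rng.normal(0.0, np.sqrt(resid_var), size=len(shared_idx))
        gamma[extra] = rng.normal(0.0, np.sqrt(per_snp_var), size=len(extra))
    else:
        gamma[causal] = rng.normal(0.0, np.sqrt(per_snp_var), size=len(causal))

    p = panel.snps["allele_freq"].to_numpy(float)
    conv = liability_to_logodds_scale(prevalence)
    denom = np.sqrt(2.0 * p * (1.0 - p))
    true_logodds = gamma * conv / denom  # per-allele scale
    se = np.sqrt((1.0 / n_cases + 1.0 / n_controls) / (2.0 * p * (1.0 - p)))
    effect = true_logodds + rng.normal(0.0, 1.0, size=m) * se
    zstat = effect / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(zstat)), 1e-300, 1.0)
    table = pd.DataFrame({
        "snp_id": snp_ids,
        "allele_effect": panel.snps["allele_alt"],
        "allele_other": panel.snps["allele_ref"],
        "effect": effect,
        "se": se,
        "p_value": pval,
        "allele_freq": p,
    })
    return SummaryStatsTable(table)
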