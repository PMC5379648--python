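"""Core data containers shared across the pipeline.

The pipeline moves four kinds of objects around: a genotype panel
(individuals x SNPs dosage matrix with SNP metadata), a gene annotation
(1-based inclusive intervals), a longitudinal phenotype table, and a GWAS
summary-statistics table.  All are thin wrappers over pandas/numpy with
validated invariants; heavier machinery lives in the operation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing dosage in :attr:`GenotypePanel.dosages`
MISSING_DOSAGE: int = -9

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_ref", "allele_alt", "allele_freq"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end"]
SUMSTATS_COLUMNS = ["snp_id", "allele_effect", "allele_other", "effect", "se", "p_value", "allele_freq"]
PHENO_COLUMNS = ["iid", "trait", "age_band", "age", "sex", "score", "pc1", "pc2"]


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


@dataclass
class GenotypePanel:
    """Hard-called dosage panel: individuals x SNPs, coded 0/1/2 (alt-allele count).

    Parameters
    ----------
    sample_ids
        Individual identifiers, one per dosage row.
    snps
        Frame with columns ``snp_id, chrom, pos, allele_ref, allele_alt,
        allele_freq``; positions strictly increasing within chromosome,
        generating allele frequencies inside [0.01, 0.99] (post-QC panel).
    dosages
        ``(n_individuals, n_snps)`` integer matrix in {0, 1, 2} with
        :data:`MISSING_DOSAGE` marking missing calls.
    """

    sample_ids: list
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.snps = self.snps.reset_index(drop=True)
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValidationError(f"snps table lacks columns {missing_cols}")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snps):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} individuals x {len(self.snps)} SNPs"
            )
        freq = self.snps["allele_freq"].to_numpy(float)
        if np.any((freq < 0.01 - 1e-12) | (freq > 0.99 + 1e-12)):
            raise ValidationError("allele_freq outside [0.01, 0.99] for a retained SNP")
        obs = self.dosages[self.dosages != MISSING_DOSAGE]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValidationError("dosages must lie in {0, 1, 2} or be the missing marker")
        for _, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError("positions not strictly increasing within chromosome")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_indices(self, snp_ids) -> np.ndarray:
        """Column indices for the given SNP ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.snps["snp_id"])}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise KeyError(f"SNP id {exc.args[0]!r} not in panel") from None

    def dosages_float(self, snp_idx=None) -> np.ndarray:
        """Dosages as float with missing entries set to NaN."""
        x = self.dosages if snp_idx is None else self.dosages[:, snp_idx]
        out = x.astype(float)
        out[x == MISSING_DOSAGE] = np.nan
        return out


@dataclass
class GeneAnnotation:
    """Autosomal gene intervals, 1-based inclusive coordinates."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValidationError(f"gene table lacks columns {missing}")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValidationError("gene with start > end")
        chrom = self.genes["chrom"].to_numpy()
        if len(chrom) and ((chrom < 1) | (chrom > 22)).any():
            raise ValidationError("annotation restricted to autosomes 1-22")

    def __len__(self) -> int:
        return len(self.genes)

    def subset(self, gene_ids) -> "GeneAnnotation":
        known = set(self.genes["gene_id"])
        unknown = [g for g in gene_ids if g not in known]
        if unknown:
            raise KeyError(f"unknown gene ids: {unknown[:5]}")
        sel = self.genes[self.genes["gene_id"].isin(set(gene_ids))]
        return GeneAnnotation(sel.copy())


def _check_corr(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValidationError(f"{name} must have unit diagonal")
    evals = np.linalg.eigvalsh(mat)
    if evals.min() < -1e-8:
        raise ValidationError(f"{name} is not positive semi-definite (min eigenvalue {evals.min():.3g})")
    return mat


@dataclass
class TraitSpec:
    """One longitudinal trait: label, assessment ages, per-age SNP-h2 targets,
    and the discrete raw-score emulation (binomial quantile map)."""

    label: str
    ages: list
    h2: list
    max_score: int
    skew_p: float  # binomial success probability; small => right skew

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.h2):
            raise ValidationError("ages and h2 must align")
        if any(h < 0 or h > 1 for h in self.h2):
            raise ValidationError("h2 targets must lie in [0, 1]")
        if not 0 < self.skew_p < 1:
            raise ValidationError("skew_p must lie in (0, 1)")


@dataclass
class TraitSimSpec:
    """Ground-truth generative specification for two correlated longitudinal traits.

    ``genetic_corr`` / ``residual_corr`` are correlation matrices across the
    concatenated measures (trait 1 ages, then trait 2 ages).  ``n_causal``
    SNPs carry the genetic signal; when ``enriched_gene_ids`` is given,
    ``enrichment_fraction`` of each measure's genetic variance is routed
    through causal SNPs inside those genes (+/- flank, applied downstream).
    """

    traits: list  # list[TraitSpec], length 2
    genetic_corr: np.ndarray
    residual_corr: np.ndarray
    n_causal: int
    seed: int = 0
    enriched_gene_ids: list | None = None
    enrichment_fraction: float = 0.0
    enrichment_flank: int = 50_000
    sex_effect: float = 0.25     # latent-scale shift for sex = 1
    age_jitter_sd: float = 0.25  # years; exact age scatters around the band

    def __post_init__(self) -> None:
        if len(self.traits) != 2:
            raise ValidationError("exactly two traits are modelled")
        k = self.n_measures
        self.genetic_corr = _check_corr(np.asarray(self.genetic_corr, float), "genetic_corr")
        self.residual_corr = _check_corr(np.asarray(self.residual_corr, float), "residual_corr")
        if self.genetic_corr.shape != (k, k) or self.residual_corr.shape != (k, k):
            raise ValidationError(f"correlation matrices must be {k}x{k} across all measures")
        if not 0.0 <= self.enrichment_fraction <= 1.0:
            raise ValidationError("enrichment_fraction must lie in [0, 1]")
        if self.n_causal < 1:
            raise ValidationError("need at least one causal SNP")

    @property
    def n_measures(self) -> int:
        return sum(len(t.ages) for t in self.traits)

    @property
    def measure_labels(self) -> list:
        return [f"{t.label}_{age}" for t in self.traits for age in t.ages]

    @property
    def h2_targets(self) -> np.ndarray:
        return np.array([h for t in self.traits for h in t.h2], float)


@dataclass
class SummaryStatsTable:
    """Discovery GWAS summary statistics (effects as log-odds for case/control)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"summary statistics lack columns {missing}")
        p = self.table["p_value"].to_numpy(float)
        if np.any((p <= 0) | (p > 1)):
            raise ValidationError("p_value must lie in (0, 1]")
        if np.any(self.table["se"].to_numpy(float) <= 0):
            raise ValidationError("se must be positive")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PhenotypeTable:
    """Long-format longitudinal phenotypes: one row per individual x trait x age band."""

    rows: pd.DataFrame
    score_ranges: dict = field(default_factory=dict)  # trait -> (lo, hi)

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns {missing}")
        dup = self.rows.duplicated(subset=["iid", "trait", "age_band"])
        if dup.any():
            raise ValidationError("multiple rows for one individual/trait/age band")
        for trait, (lo, hi) in self.score_ranges.items():
            s = self.rows.loc[self.rows["trait"] == trait, "score"].dropna()
            if len(s) and (s.min() < lo or s.max() > hi):
                raise ValidationError(f"scores for {trait!r} outside declared range [{lo}, {hi}]")

    def measure(self, trait: str, age_band) -> pd.DataFrame:
        sel = self.rows[(self.rows["trait"] == trait) & (self.rows["age_band"] == age_band)]
        if sel.empty:
            raise KeyError(f"no rows for trait {trait!r} at age band {age_band!r}")
        return sel.reset_index(drop=True)
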