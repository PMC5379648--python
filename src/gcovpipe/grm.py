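"""Genetic relationship matrices: construction, relatedness pruning,
gene-set partitioning, and the GCTA binary on-disk dialect.

The GRM entry for individuals j, k is the average standardized-genotype
cross-product

    G_jk = (1/M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over SNPs i observed in both individuals, with p_i the in-sample
alternate-allele frequency and M_jk the per-pair count of jointly
non-missing SNPs (pairwise-complete estimation, matching the semantics of
the ``.grm.N.bin`` companion file).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation, GenotypePanel, ValidationError

logger = logging.getLogger(__name__)


class EmptyGRMError(ValueError):
    """No informative SNPs remained for GRM construction."""


class GRMFormatError(ValueError):
    """A binary GRM triplet is inconsistent on disk."""


@dataclass
class GRM:
    """Realized relationship matrix with per-pair SNP counts."""

    sample_ids: list
    values: np.ndarray
    pair_snp_counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        n = len(self.sample_ids)
        if self.values.shape != (n, n) or self.pair_snp_counts.shape != (n, n):
            raise ValidationError("GRM matrices must be n x n with n = len(sample_ids)")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValidationError("GRM must be symmetric")
        if np.any(self.pair_snp_counts < 1):
            raise ValidationError("pair_snp_counts must be >= 1 wherever a value is defined")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids) -> "GRM":
        """Restrict to the given individuals, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return GRM(list(ids), self.values[np.ix_(idx, idx)].copy(),
                   self.pair_snp_counts[np.ix_(idx, idx)].copy())


@dataclass
class SnpPartition:
    """Disjoint split of a panel's SNPs into in-set and out-of-set."""

    set_snp_ids: list
    noset_snp_ids: list
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.set_snp_ids) & set(self.noset_snp_ids):
            raise ValidationError("set and noset SNP lists overlap")


def compute_grm(panel: GenotypePanel, snp_subset=None) -> GRM:
    """Build the GRM from all panel SNPs or the named subset.

    Monomorphic SNPs (in-sample frequency 0 or 1 among non-missing calls)
    carry no relationship information and are skipped with a warning; if
    nothing remains an :class:`EmptyGRMError` is raised.
    """
    if snp_subset is not None:
        idx = panel.snp_indices(snp_subset)
        if idx.size == 0:
            raise EmptyGRMError("empty SNP subset")
    else:
        idx = np.arange(panel.n_snps)
    x = panel.dosages_float(idx)
    obs = ~np.isnan(x)
    with np.errstate(invalid="ignore"):
        p = np.nansum(x, axis=0) / (2.0 * obs.sum(axis=0))
    poly = (p > 0.0) & (p < 1.0) & np.isfinite(p)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("skipping %d monomorphic SNP(s) in GRM construction", n_mono)
    if not poly.any():
        raise EmptyGRMError("all SNPs monomorphic; GRM undefined")
    x, p, obs = x[:, poly], p[poly], obs[:, poly]
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    w[~obs] = 0.0
    values = w @ w.T
    obs_f = obs.astype(np.float64)  # float matmul hits BLAS; counts are exact below 2^53
    counts = np.round(obs_f @ obs_f.T).astype(np.int64)
    if np.any(counts < 1):
        raise EmptyGRMError("some individual pair shares no observed SNP")
    values /= counts
    values = (values + values.T) / 2.0
    return GRM(list(panel.sample_ids), values, counts)


def prune_related(grm: GRM, cutoff: float) -> list:
    """Greedily drop individuals until no off-diagonal relationship exceeds ``cutoff``.

    At each step the individual involved in the largest number of offending
    pairs is removed; ties go to the lexicographically smallest id.  Returns
    the retained sample ids in their original order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ids = np.array(grm.sample_ids, dtype=object)
    adj = grm.values > cutoff
    np.fill_diagonal(adj, False)
    active = np.ones(grm.n, dtype=bool)
    while True:
        deg = (adj & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        worst = deg == deg.max()
        drop = min(np.flatnonzero(worst), key=lambda i: str(ids[i]))
        active[drop] = False
    return [s for s, keep in zip(grm.sample_ids, active) if keep]


def partition_by_geneset(panel: GenotypePanel, annotation: GeneAnnotation,
                         gene_ids, flank: int) -> SnpPartition:
    """Split panel SNPs by membership in ``gene_ids`` intervals +/- ``flank`` bp.

    A SNP is in-set iff its position lies within [start - flank, end + flank]
    (1-based inclusive) of any listed gene on the same chromosome.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    genes = annotation.subset(gene_ids).genes if len(list(gene_ids)) else annotation.genes.iloc[:0]
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    in_set = np.zeros(panel.n_snps, dtype=bool)
    for _, g in genes.iterrows():
        in_set |= (chrom == g["chrom"]) & (pos >= g["start"] - flank) & (pos <= g["end"] + flank)
    snp_ids = panel.snps["snp_id"].to_numpy(object)
    return SnpPartition(
        set_snp_ids=list(snp_ids[in_set]),
        noset_snp_ids=list(snp_ids[~in_set]),
        provenance=f"{len(list(gene_ids))} genes, flank {flank} bp",
    )


def write_grm(grm: GRM, prefix: str) -> None:
    """Write the GCTA binary triplet ``<prefix>.grm.bin/.grm.N.bin/.grm.id``.

    Both binaries store the lower triangle (diagonal included) row by row as
    4-byte little-endian floats.
    """
    il, jl = np.tril_indices(grm.n)
    grm.values[il, jl].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.pair_snp_counts[il, jl].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix: str) -> GRM:
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)
    n = len(ids)
    expected = n * (n + 1) // 2
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    tri_n = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if tri.size != expected or tri_n.size != expected:
        raise GRMFormatError(
            f"binary GRM for {n} ids must hold {expected} lower-triangle elements; "
            f"found {tri.size} values / {tri_n.size} counts"
        )
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    il, jl = np.tril_indices(n)
    values[il, jl] = tri
    counts[il, jl] = tri_n
    values = values + np.tril(values, -1).T
    counts = counts + np.tril(counts, -1).T
    return GRM(list(ids[1].astype(str)), values, np.round(counts).astype(np.int64))
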