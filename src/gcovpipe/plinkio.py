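"""Minimal PLINK 1 bed/bim/fam and text serialization.

Implements the SNP-major 2-bit bed dialect (magic ``6C 1B 01``) for
:class:`~gcovpipe.datatypes.GenotypePanel`, plus TSV/BED writers for the
other containers.  Gene coordinates are 1-based inclusive in memory and
converted to 0-based half-open BED at the file boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    GENE_COLUMNS,
    MISSING_DOSAGE,
    GeneAnnotation,
    GenotypePanel,
    PhenotypeTable,
    SummaryStatsTable,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit codes, indexed by alt-allele dosage; 0b01 is the missing code.
_CODE_OF_DOSAGE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING_DOSAGE: 0b01}
_DOSAGE_OF_CODE = np.array([0, MISSING_DOSAGE, 1, 2], dtype=np.int8)


def write_bed(panel: GenotypePanel, prefix: str) -> None:
    """Write ``<prefix>.bed/.bim/.fam``.

    The bim A1 column holds the alternate (counted) allele, A2 the reference,
    so that dosage = A1 count, matching the in-memory coding.
    """
    n, m = panel.dosages.shape
    codes = np.empty((m, n), dtype=np.uint8)
    for dos, code in _CODE_OF_DOSAGE.items():
        codes[(panel.dosages == dos).T] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    packed[:, :n] = codes
    packed = (
        packed[:, 0::4]
        | (packed[:, 1::4] << 2)
        | (packed[:, 2::4] << 4)
        | (packed[:, 3::4] << 6)
    )
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.astype(np.uint8).tofile(fh)

    bim = pd.DataFrame(
        {
            "chrom": panel.snps["chrom"],
            "snp_id": panel.snps["snp_id"],
            "cm": 0,
            "pos": panel.snps["pos"],
            "a1": panel.snps["allele_alt"],
            "a2": panel.snps["allele_ref"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids,
            "iid": panel.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep=" ", header=False, index=False)


def read_bed(prefix: str) -> GenotypePanel:
    """Read ``<prefix>.bed/.bim/.fam`` back into a panel.

    Allele frequencies are recomputed in-sample from non-missing dosages
    (clipped into the panel's valid [0.01, 0.99] band).
    """
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK bed file (bad magic)")
        raw = np.fromfile(fh, dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if raw.size != m * n_bytes:
        raise ValueError(f"bed payload of {raw.size} bytes; expected {m * n_bytes}")
    raw = raw.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    dosages = _DOSAGE_OF_CODE[codes[:, :n]].T.copy()

    x = dosages.astype(float)
    x[dosages == MISSING_DOSAGE] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(x, axis=0) / 2.0
    freq = np.clip(np.nan_to_num(freq, nan=0.5), 0.01, 0.99)
    snps = pd.DataFrame(
        {
            "snp_id": bim[1],
            "chrom": bim[0].astype(int),
            "pos": bim[3].astype(int),
            "allele_ref": bim[5],
            "allele_alt": bim[4],
            "allele_freq": freq,
        }
    )
    return GenotypePanel(sample_ids=list(fam[1].astype(str)), snps=snps, dosages=dosages)


def write_annotation_bed(annotation: GeneAnnotation, path: str) -> None:
    """Write genes as BED (0-based half-open): start-1, end."""
    out = pd.DataFrame(
        {
            "chrom": annotation.genes["chrom"],
            "start": annotation.genes["start"] - 1,
            "end": annotation.genes["end"],
            "gene_id": annotation.genes["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path: str) -> GeneAnnotation:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"])
    genes = pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"].astype(int),
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
        }
    )[GENE_COLUMNS]
    return GeneAnnotation(genes)


def write_phenotypes(table: PhenotypeTable, path: str) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str, score_ranges: dict | None = None) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"), score_ranges=score_ranges or {})


_SUMSTATS_OUT = {
    "snp_id": "SNP",
    "allele_effect": "A1",
    "allele_other": "A2",
    "effect": "BETA",
    "se": "SE",
    "p_value": "P",
    "allele_freq": "FRQ",
}


def write_sumstats(stats: SummaryStatsTable, path: str) -> None:
    stats.table.rename(columns=_SUMSTATS_OUT)[list(_SUMSTATS_OUT.values())].to_csv(
        path, sep="\t", index=False
    )


def read_sumstats(path: str) -> SummaryStatsTable:
    raw = pd.read_csv(path, sep="\t")
    if "OR" in raw.columns and "BETA" not in raw.columns:
        raw["BETA"] = np.log(raw["OR"].astype(float))
    inv = {v: k for k, v in _SUMSTATS_OUT.items()}
    return SummaryStatsTable(raw.rename(columns=inv)[list(_SUMSTATS_OUT)])
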