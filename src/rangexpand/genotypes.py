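"""Diploid genotype container and VCF input/output.

Genotypes are stored as alt-allele dosages in {0, 1, 2} with ``-1`` marking
missing calls, in a samples x SNPs ``int8`` matrix.  Only biallelic SNPs are
represented; multiallelic records and indels are skipped on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

_SNP_COLUMNS = ["chrom", "pos", "ref", "alt"]


class GenotypeIOError(IOError):
    """Raised for missing or malformed genotype files."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid dosage matrix with per-SNP metadata.

    Attributes
    ----------
    sample_ids
        Sample names, one per matrix row.
    snps
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is 1-based
        and strictly increasing within each chromosome.
    dosage
        ``int8`` array of shape (n_samples, n_snps); entries in {0, 1, 2}
        or ``-1`` for missing.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNPs by positional index (order-preserving)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[index],
            dosage=self.dosage[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            snps=self.snps,
            dosage=self.dosage[index, :],
        )

    def snp_keys(self) -> list[tuple]:
        """(chrom, pos, ref, alt) identity keys, one per SNP."""
        return list(
            zip(self.snps["chrom"], self.snps["pos"], self.snps["ref"], self.snps["alt"])
        )


_BASES = {"A", "C", "G", "T"}


def read_vcf_genotypes(path: str) -> GenotypeMatrix:
    """Load biallelic SNP genotypes from a VCF (v4.x, GT per sample).

    Multiallelic records and indels are skipped (count logged); half-calls
    such as ``./1`` are treated as missing.
    """
    try:
        vcf = VCF(str(path))
    except OSError as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeIOError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in _BASES or var.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            row[i] = MISSING if (a < 0 or b < 0) else a + b
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosages.append(row)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    snps = pd.DataFrame(rows, columns=_SNP_COLUMNS)
    dosage = (
        np.vstack(dosages).T if dosages else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids=samples, snps=snps, dosage=dosage)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as a minimal VCFv4.2 with GT-only FORMAT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rangexpand\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(G.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, snp in enumerate(G.snps.itertuples(index=False)):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in G.dosage[:, j])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t.\t{snp.ref}\t{snp.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
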